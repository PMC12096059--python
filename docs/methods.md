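# Methods

## Mass arithmetic

All m/z values reduce to additive arithmetic over element counts with
CODATA/IUPAC monoisotopic masses (H 1.00782503, C 12, N 14.00307400,
O 15.99491462, S 31.97207100, P 30.97376163; heavy isotopes ²H, ¹³C, ¹⁵N as
separate symbols).  Ionization adds or removes one proton (1.007276 u) —
the charge carrier, not a hydrogen atom; only singly charged ±H ions are
supported.  Nominal m/z rounds to the nearest integer with ties away from
zero; this convention reproduces every transition mass in the shipped MRM
panel.  Amide-bond condensation is an elementwise formula sum minus H₂O,
so mass additivity (mass(a·b) = mass(a) + mass(b) − mass(H₂O)) holds to
floating precision by construction and is asserted to 1e−9 u in the tests.

The compound registry fixes compositions from standard chemistry: JA
C₁₂H₁₈O₃, 12-OH-JA C₁₂H₁₈O₄ (one added oxygen), OPDA C₁₈H₂₈O₃, and
4,5-didehydro-JA as C₁₂H₁₆O₃ — "didehydro" denotes one additional double
bond, i.e. JA minus H₂.  Deuterated standards are built by replacing n
light hydrogens (D5-JA, D5-OPDA, D3-JA-Leu).  The amino-acid shift table
derives Δ = mass(AA) − mass(H₂O) for the 20 proteinogenic amino acids
supplied in the ex vivo assay buffer; Leu and Ile share a molecular formula
and are the table's single ambiguous pair, always reported jointly.

## Ex vivo screen

Calls are made per feature from the active/inactive mean ratio and a
two-sample test.  Defaults: substrate if ratio ≤ 0.5, product if ≥ 2.0 —
the conventional two-fold rule, stated as configurable defaults because the
screen itself is pattern-based — gated at BH-adjusted q ≤ 0.05 using
Welch's t on log₂(x+1) (matching the multiplicative noise model; a rank-sum
alternative is available).  Low-signal features (both condition means below
the floor, or both zero) are excluded from testing.  Degenerate
zero-variance groups fall back to fold-change-only calling (p := 0 when the
constants differ, 1 when equal) so noiseless fixtures never produce NaN.  A
zero inactive mean with nonzero active signal yields ratio +∞, i.e. a
product candidate.  With n = 3 replicates, CV 10%, and BH correction across
a table with many null features, a feature depleted exactly two-fold sits
near the decision boundary; the synthetic fixture therefore plants
conversions well past the thresholds (total conversion 0.7–0.8, active/
inactive ratios 0.2–0.3, the depletion pattern the screen is meant to
flag).

## Conjugate pairing

Candidates are substrate × product combinations whose m/z difference
matches a shift within tol_ppm (default 5) referenced to the product m/z,
where the measured mass — and hence the absolute error — is larger.
Identical-delta shifts are merged before matching, so a Leu/Ile link is one
candidate with two names, never two candidates.  Pairing operates only on
called substrates × called products, mirroring the two-stage logic
(intensity pattern first, mass shift second).  MS/MS validation expects the
deprotonated free amino acid (mass(AA) − 1.007276) among the product's
fragments within fragment_tol_mz (default 0.01 u): supported / contradicted
/ untested.  Retention time is carried through but not scored — no numeric
identity criterion is defined for it.

## Targeted quantification

The default library holds the ten-transition jasmonate panel with its
declustering/entrance potentials and collision energies; every Q1 equals
the nominal [M−H]⁻ of the registered compound and every amino-acid
conjugate Q3 the nominal deprotonated amino acid (both asserted in tests).
Detection uses a blank rule: signal height ≥ k × the background height
(default k = 3), where background is the **maximum** height of that analyte
across the jasmonate-free *aos* blanks — maximum rather than mean because
the rule is a conservative noise gate and no aggregation rule is otherwise
implied.  A zero blank height means any nonzero signal counts as detected.

Amounts are (area_analyte / area_IS) × n_IS / fresh weight.  The default
standard mapping is D5-JA → JA, 12-OH-JA; D5-OPDA → OPDA; D3-JA-Leu →
JA-Ile, JA-Val, JA-Leu.  JA-Gln and 12-OH-JA-Ile have no authentic
labelled analogue and are reported as relative responses (area ratio
against D5-JA), never in nmol g⁻¹ FW.  Undetected analytes are flagged bdl
and carry the per-matrix LOD where known (JA-Ile: 0.017 nmol g⁻¹ FW in
flowers, 0.00085 in leaves, stored as fixed per-matrix constants); a zero
internal-standard area marks its dependents blank-fail.

Group statistics: one-way ANOVA and Tukey HSD on untransformed amounts
(technical replicates treated as independent observations, as in the
underlying reporting), plus a Student's t-test for two-group assay
comparisons.  The compact letter display uses the insert–absorb
construction: start from one column holding all groups; for each
significant pair, split every column containing both members into two
(each minus one member); keep only maximal columns; assign one letter per
column.  The result satisfies "share a letter iff not significantly
different", verified against the pairwise-p oracle on random instances.
Fold changes are ratios of arithmetic group means over quantified values
only; bdl observations are excluded and counted, and an all-bdl group makes
the ratio undefined (flagged, never NaN).  The DE filter is inclusive on
the fold-change boundary (log₂FC ≥ 2 counts) and strict on p (< 0.01).

## Fingerprinting (FDR filter + 1-D SOM)

The pre-filter runs a per-feature one-way ANOVA across sample groups with
BH correction over all features; the statistic behind the filter is a
package default (the threshold, not the test, is the fixed design point).
Constant features have an undefined F and are never retained, even at
threshold 1.  Profiles are z-scored vectors of per-group mean intensities,
matching group-wise display conventions; normalization is configurable.

The SOM is batch-trained on a chain of K prototypes (default 9):
each epoch assigns every profile to its nearest prototype (Euclidean) and
recomputes prototype j as the Gaussian-neighborhood-weighted mean
Σᵢ h(j, bmuᵢ) xᵢ / Σᵢ h, with h = exp(−(j−bmu)²/2σ²) and σ shrinking
geometrically between the schedule endpoints (default 2.0 → 0.05 over 30
epochs).  Batch updates were chosen over online training because they are
deterministic, order-invariant (weighted sums commute), and testable; the
`learning_rate_schedule` config field is accepted for interface
compatibility but unused — batch SOM has no learning rate.  Prototypes are
initialized at evenly spaced quantiles of the data's projection onto its
first principal axis (SVD-based, with the axis sign fixed by its
largest-magnitude component so chain order is reproducible); the seed only
drives optional jitter (default 0).  As σ → 0 the update degenerates to the
k-means centroid step, a limit equivalence checked on small instances.
Prototypes whose total neighborhood weight is numerically zero keep their
previous value.  Quantization error (mean Euclidean distance to the winning
prototype) is recorded per epoch; empty clusters are reported with count 0.

## Synthetic data

Noise is multiplicative lognormal with unit mean: σ² = ln(1 + CV²),
μ = −σ²/2, keeping signals positive and the ratio-of-means estimator
unbiased.  Default CV 0.10 — biological variance components are unknown;
this is a deliberately moderate instrument+replicate spread, exposed as a
config knob.  Replicate counts follow the study design: 3 for ex vivo and
genotype quantification, 4 technical replicates for the in vitro assay.
Baseline intensities are arbitrary (1e5 response units); only ratios are
meaningful.

* *Ex vivo*: active samples deplete each substrate by its total conversion
  fraction and create products at matched response, so mole balance holds
  exactly at zero CV; inactive controls keep substrates with zero product
  signal.  Planted m/z values are exact [M−H]⁻ from the registry; the 40
  decoys are constant across conditions with m/z rejected within 20 ppm of
  any valid shift delta relative to planted (or already accepted) features,
  making planted-pair precision a sharp property.
* *Quantification*: analyte area = baseline × genotype multiplier × noise
  plus a small background (0.5% of baseline) that also constitutes the
  *aos* blanks, so a zero multiplier leaves background only and fails the
  3× rule.  Default flower effect map: JA ×1/×1/×2/×4 and JA-Ile
  ×1/×1/×0/×0 for wild-type / gh3.10 / jar1 / gh3.10 jar1; the leaf map
  halves JA in the double mutant.  Internal-standard areas are constant ×
  noise; fresh weight 0.1 g.
* *In vitro*: product signal = baseline × relative activity × noise, with
  activities expressed relative to the JAR1 mean per substrate
  (GH3.10: 0.5 on JA, 7 on 12-OH-JA, 1/6 on ddh-JA).
* *DE table*: constructed so exactly the requested row counts pass the
  filter, with one row per direction sitting exactly on the fold-change
  boundary and null rows covering small-effect, non-significant, and
  p-exactly-at-alpha cases.

Generators are pure functions of (config, seed).  What they do **not**
emulate: retention-time drift, batch effects, isotope envelopes, missing
values, correlated features, or heavy-tailed contamination — so passing
recovery tests demonstrates the pipeline's logic under its own noise model,
not robustness to every artefact of real chromatography.

## Problem sizes and determinism

Analyses and tests run on desk-scale instances (tens of features, 3–4
replicates, hundreds of fingerprint features, 100-instance statistical
oracle sweeps) chosen so each pipeline property is sharply testable; all
stochastic steps are seeded, and the CLI derives every random stream from
its single `--seed`.  Dataset-scale observables of a real campaign (e.g.
how many features survive an FDR cut, or absolute hormone levels) depend on
the raw data and are out of scope; the corresponding machinery is tested
through its filter/oracle properties instead.

## Known limitations

Only ±H single-charge ions; no adducts, multiply charged species, or
isotope-envelope reasoning.  No chromatographic peak integration or
calibration curves — the pipeline starts at feature tables / signal
tables.  The blank rule compares heights, not areas, and assumes blanks
were measured in the same batch.  The CLD becomes wide (many letters) for
pathological significance patterns, which is inherent to letter displays.
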