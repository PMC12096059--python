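"""Seeded synthetic-data generators with ground truth for every stage.

Each generator is a pure function of its configuration (including the seed)
and emulates the statistical structure its consumer assumes:

* ``gen_exvivo_table`` — an active-vs-inactive enzyme incubation: planted
  substrate->product conversions (JA -> JA-Ile/JA-Val/JA-Met and
  12-OH-JA -> 12-OH-JA-Ile), decoy features guarded in m/z space, lognormal
  multiplicative noise, accurate [M-H]- m/z from the compound registry.
* ``gen_quant_dataset`` — per-genotype MRM signals with the study's effect
  multipliers (flowers: JA x2 in jar1, x4 in gh3.10 jar1; JA-Ile absent in
  the double mutant), jasmonate-free aos blanks carrying only background,
  and constant internal-standard signals.
* ``gen_invitro_assay`` — enzyme x substrate product-signal areas around a
  relative-activity map (GH3.10/JAR1 = 0.5 on JA, 7 on 12-OH-JA;
  JAR1/GH3.10 = 6 on ddh-JA), n = 4 technical replicates.
* ``gen_de_table`` — a differential-expression toy table with exact
  pass/fail counts, including fold-change boundary rows.

Noise is multiplicative lognormal with unit mean (sigma chosen from the CV),
which keeps signals positive and mirrors LC-MS intensity error.  Baseline
intensities are arbitrary response units; only ratios carry meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import amino_acid_compounds, build_shift_table, get_compound, ion_mz
from .errors import ConfigError
from .features import Feature, FeatureTable, SampleMeta
from .quant import QuantSample

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "gen_exvivo_table",
    "gen_quant_dataset",
    "gen_invitro_assay",
    "gen_de_table",
]

# --- study-condition defaults -------------------------------------------------

#: substrate -> list of (product compound, conversion fraction)
DEFAULT_CONVERSION_MAP = {
    "JA": (("JA-Ile", 0.50), ("JA-Val", 0.15), ("JA-Met", 0.15)),
    "12-OH-JA": (("12-OH-JA-Ile", 0.70),),
}

#: analyte -> genotype -> multiplier on the wild-type level (flower matrix)
DEFAULT_EFFECT_MAP_FLOWERS = {
    "JA": {"wild-type": 1.0, "gh3.10": 1.0, "jar1": 2.0, "gh3.10 jar1": 4.0},
    "JA-Ile": {"wild-type": 1.0, "gh3.10": 1.0, "jar1": 0.0, "gh3.10 jar1": 0.0},
    "12-OH-JA": {"wild-type": 1.0, "gh3.10": 1.0, "jar1": 1.0, "gh3.10 jar1": 2.0},
    "12-OH-JA-Ile": {"wild-type": 1.0, "gh3.10": 1.0, "jar1": 0.3, "gh3.10 jar1": 0.0},
}

#: wounded-leaf matrix: JA at 50% of wild-type in the double mutant
DEFAULT_EFFECT_MAP_LEAVES = {
    "JA": {"wild-type": 1.0, "gh3.10": 1.0, "jar1": 1.0, "gh3.10 jar1": 0.5},
    "JA-Ile": {"wild-type": 1.0, "gh3.10": 1.0, "jar1": 0.2, "gh3.10 jar1": 0.0},
}

#: (enzyme, substrate) -> product signal relative to the JAR1 mean
DEFAULT_ACTIVITY_MAP = {
    ("JAR1", "JA"): 1.0,
    ("GH3.10", "JA"): 0.5,
    ("JAR1", "12-OH-JA"): 1.0,
    ("GH3.10", "12-OH-JA"): 7.0,
    ("JAR1", "ddh-JA"): 1.0,
    ("GH3.10", "ddh-JA"): 1.0 / 6.0,
}

_INVITRO_PRODUCT = {"JA": "JA-Ile", "12-OH-JA": "12-OH-JA-Ile", "ddh-JA": "ddh-JA-Ile"}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_replicates: Mapping[str, int] = field(
        default_factory=lambda: {"exvivo": 3, "quant": 3, "invitro": 4}
    )
    noise_cv: float = 0.10
    matrix: str = "flowers"
    effect_map: Optional[Mapping] = None  # default chosen per matrix
    conversion_map: Mapping = field(default_factory=lambda: dict(DEFAULT_CONVERSION_MAP))
    activity_map: Mapping = field(default_factory=lambda: dict(DEFAULT_ACTIVITY_MAP))
    n_decoys: int = 40
    decoy_mz_guard_ppm: float = 20.0
    baseline_intensity: float = 1e5

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        for sub, prods in self.conversion_map.items():
            total = sum(f for _, f in prods)
            if not (0 <= total <= 1):
                raise ConfigError(f"conversion fractions for {sub!r} must sum to [0, 1]")
        for mult in self.activity_map.values():
            if mult < 0:
                raise ConfigError("activity multipliers must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    pairs: list = field(default_factory=list)  # (sub fid, prod fid, sub, prod, shift)
    true_group_means: dict = field(default_factory=dict)
    true_activity_ratios: dict = field(default_factory=dict)
    true_de_counts: tuple = (0, 0)
    extra: dict = field(default_factory=dict)


def _noise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-mean lognormal multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Ex vivo screen fixture
# ---------------------------------------------------------------------------


def gen_exvivo_table(config: GeneratorConfig = GeneratorConfig()):
    """Synthetic active/inactive incubation table with planted conversions.

    Active samples deplete each substrate by its total conversion fraction
    and create products at matched response (mole balance holds exactly at
    zero CV); inactive controls keep substrates and have zero product signal.
    Decoy features are constant across conditions, with m/z rejected within
    ``decoy_mz_guard_ppm`` of any valid shift delta relative to planted (or
    previously accepted decoy) features.
    """
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_replicates.get("exvivo", 3)
    base = config.baseline_intensity

    samples = [
        SampleMeta(f"active_{r+1}", "active", replicate=r + 1) for r in range(n_rep)
    ] + [
        SampleMeta(f"inactive_{r+1}", "inactive", replicate=r + 1) for r in range(n_rep)
    ]
    act_ids = [s.sample_id for s in samples if s.condition == "active"]
    inact_ids = [s.sample_id for s in samples if s.condition == "inactive"]

    # planted compounds and their true condition means
    plan: list[tuple[str, float, float]] = []  # (compound, mean_active, mean_inactive)
    truth = GroundTruth()
    for sub, prods in config.conversion_map.items():
        get_compound(sub)  # raises for unknown compounds
        total = sum(f for _, f in prods)
        plan.append((sub, base * (1.0 - total), base))
        for prod, frac in prods:
            get_compound(prod)
            plan.append((prod, base * frac, 0.0))

    features = []
    planted_mz = {}
    for name, mean_a, mean_i in plan:
        mz = ion_mz(get_compound(name).formula, "negative")
        planted_mz[name] = mz
        fid = f"F_{name}"
        intens = {}
        for sid in act_ids:
            intens[sid] = mean_a * float(_noise(rng, config.noise_cv))
        for sid in inact_ids:
            intens[sid] = mean_i * float(_noise(rng, config.noise_cv))
        features.append(
            Feature(fid, mz=mz, rt=float(rng.uniform(60, 600)), intensities=intens)
        )

    for sub, prods in config.conversion_map.items():
        for prod, frac in prods:
            aa = get_compound(prod).parents[1]
            truth.pairs.append((f"F_{sub}", f"F_{prod}", sub, prod, aa))
    truth.extra["conversion_map"] = {k: list(v) for k, v in config.conversion_map.items()}

    # decoys: constant across conditions, m/z guarded against valid deltas
    shifts = build_shift_table(amino_acid_compounds(), include_hydroxylation=True)
    deltas = sorted({s.delta_mass for s in shifts})
    taken = list(planted_mz.values())

    def clashes(mz: float) -> bool:
        guard = config.decoy_mz_guard_ppm * mz * 1e-6
        for other in taken:
            d = abs(mz - other)
            for delta in deltas:
                if abs(d - delta) <= guard:
                    return True
        return False

    n_made = 0
    while n_made < config.n_decoys:
        mz = float(rng.uniform(150.0, 600.0))
        if clashes(mz):
            continue
        taken.append(mz)
        level = base * float(rng.uniform(0.1, 10.0))
        intens = {
            sid: level * float(_noise(rng, config.noise_cv))
            for sid in act_ids + inact_ids
        }
        features.append(
            Feature(
                f"D_{n_made+1:03d}",
                mz=mz,
                rt=float(rng.uniform(60, 600)),
                intensities=intens,
            )
        )
        n_made += 1

    return FeatureTable(samples=samples, features=features), truth


# ---------------------------------------------------------------------------
# Targeted quantification fixture
# ---------------------------------------------------------------------------

_IS_BASE_AREA = 1.0e5
_BACKGROUND_FRACTION = 0.005  # blank background relative to the wild-type level
_HEIGHT_PER_AREA = 0.1  # peak height proportional to area


def gen_quant_dataset(config: GeneratorConfig = GeneratorConfig()):
    """Per-genotype MRM signal samples plus jasmonate-free aos blanks.

    Analyte areas are baseline x genotype multiplier x lognormal noise, on
    top of a small background also present in the blanks; internal-standard
    areas are constant x noise.  A zero multiplier leaves only background,
    so the analyte fails the 3x blank-height rule (bdl) — e.g. JA-Ile in
    the gh3.10 jar1 double mutant.
    """
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_replicates.get("quant", 3)
    effect = config.effect_map
    if effect is None:
        effect = (
            DEFAULT_EFFECT_MAP_FLOWERS
            if config.matrix == "flowers"
            else DEFAULT_EFFECT_MAP_LEAVES
        )
    genotypes = list(next(iter(effect.values())).keys())
    base = config.baseline_intensity

    truth = GroundTruth()
    truth.extra["effect_map"] = {a: dict(m) for a, m in effect.items()}

    def sample_signals(mult_of: Mapping[str, float]) -> dict:
        signals = {}
        for analyte, mult in mult_of.items():
            bg = base * _BACKGROUND_FRACTION * float(_noise(rng, config.noise_cv))
            area = base * mult * float(_noise(rng, config.noise_cv)) + bg
            signals[analyte] = (area, area * _HEIGHT_PER_AREA)
        for std in ("D5-JA", "D5-OPDA", "D3-JA-Leu"):
            area = _IS_BASE_AREA * float(_noise(rng, config.noise_cv))
            signals[std] = (area, area * _HEIGHT_PER_AREA)
        return signals

    samples = []
    for geno in genotypes:
        mult_of = {a: effect[a].get(geno, 0.0) for a in effect}
        truth.true_group_means[geno] = dict(mult_of)
        for r in range(n_rep):
            samples.append(
                QuantSample(
                    sample_id=f"{geno.replace(' ', '_')}_{r+1}",
                    genotype=geno,
                    signals=sample_signals(mult_of),
                    fresh_weight=0.1,
                    matrix=config.matrix,
                )
            )
    blanks = []
    for r in range(n_rep):
        blanks.append(
            QuantSample(
                sample_id=f"aos_{r+1}",
                genotype="aos",
                signals=sample_signals({a: 0.0 for a in effect}),
                fresh_weight=0.1,
                matrix=config.matrix,
            )
        )
    return samples, blanks, truth


# ---------------------------------------------------------------------------
# In vitro relative-activity assay fixture
# ---------------------------------------------------------------------------


def gen_invitro_assay(config: GeneratorConfig = GeneratorConfig()):
    """Replicated product-signal areas per enzyme x substrate.

    Signal area = baseline x relative activity x lognormal noise, n
    technical replicates per combination.  The ratio-of-means estimator on
    the product signals recovers the configured activity ratios.
    """
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_replicates.get("invitro", 4)
    base = config.baseline_intensity

    known_enzymes = {e for e, _ in DEFAULT_ACTIVITY_MAP}
    rows = []
    truth = GroundTruth()
    for (enzyme, substrate), activity in config.activity_map.items():
        if substrate not in _INVITRO_PRODUCT:
            raise ConfigError(f"unknown in vitro substrate {substrate!r}")
        if config.activity_map is DEFAULT_ACTIVITY_MAP and enzyme not in known_enzymes:
            raise ConfigError(f"unknown enzyme {enzyme!r}")
        product = _INVITRO_PRODUCT[substrate]
        for r in range(n_rep):
            rows.append(
                {
                    "enzyme": enzyme,
                    "substrate": substrate,
                    "product": product,
                    "replicate": r + 1,
                    "area": base * activity * float(_noise(rng, config.noise_cv)),
                }
            )
    for substrate in sorted({s for _, s in config.activity_map}):
        for e1 in sorted({e for e, s in config.activity_map if s == substrate}):
            for e2 in sorted({e for e, s in config.activity_map if s == substrate}):
                if e1 != e2:
                    truth.true_activity_ratios[(e1, e2, substrate)] = (
                        config.activity_map[(e1, substrate)]
                        / config.activity_map[(e2, substrate)]
                    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Differential-expression toy table
# ---------------------------------------------------------------------------


def gen_de_table(
    n_up: int = 5,
    n_down: int = 7,
    n_null: int = 100,
    seed: int = 0,
    up_lfc: float = 2.0,
    down_lfc: float = -2.0,
    alpha: float = 0.01,
):
    """Toy DE table with exactly the requested pass/fail counts.

    The first up and down rows sit exactly on the fold-change boundary
    (log2fc = up_lfc / down_lfc) with p just under alpha, exercising the
    inclusive-fold / strict-p rule.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(gene, lfc, p):
        rows.append({"gene": gene, "log2fc": lfc, "p": p})

    for i in range(n_up):
        lfc = up_lfc if i == 0 else float(up_lfc + rng.uniform(0.1, 4.0))
        add(f"up_{i+1}", lfc, float(rng.uniform(0, alpha * 0.99)))
    for i in range(n_down):
        lfc = down_lfc if i == 0 else float(down_lfc - rng.uniform(0.1, 4.0))
        add(f"down_{i+1}", lfc, float(rng.uniform(0, alpha * 0.99)))
    for i in range(n_null):
        mode = i % 3
        if mode == 0:  # small fold change, any p
            add(f"null_{i+1}", float(rng.uniform(down_lfc + 0.1, up_lfc - 0.1)),
                float(rng.uniform(0, 1)))
        elif mode == 1:  # big fold change, non-significant p
            sign = 1 if rng.random() < 0.5 else -1
            add(f"null_{i+1}", float(sign * rng.uniform(abs(up_lfc), 6.0)),
                float(rng.uniform(alpha, 1.0)))
        else:  # boundary p exactly alpha (strict cut excludes it)
            add(f"null_{i+1}", float(rng.uniform(abs(up_lfc), 6.0)), alpha)

    truth = GroundTruth(true_de_counts=(n_up, n_down))
    return pd.DataFrame(rows), truth
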