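"""MRM-style targeted quantification of jasmonates and group statistics.

The transition library ships the ten scheduled-MRM transitions of the
jasmonate panel (nominal Q1/Q3 of the [M-H]- precursor and its dominant
fragment, with declustering/entrance potential and collision energy).
Quantification normalizes analyte peak areas to a stable-isotope internal
standard and fresh weight; analytes without an authentic labelled analogue
(JA-Gln, 12-OH-JA-Ile) are reported as relative responses against D5-JA.

Detection is gated by a blank rule: a signal counts as detected only if its
peak height is at least k-fold (default 3) above the background height seen
in jasmonate-free blank samples (extracts of the aos mutant, which cannot
make jasmonates).  Undetected analytes are flagged *bdl* and carry the
per-matrix detection limit where one is known.

Group statistics mirror the study's reporting: one-way ANOVA with Tukey's
post-hoc test and a compact letter display at alpha = 0.05, a plain
two-sample t-test for pairwise assay comparisons, group-mean fold changes,
and the |log2FC| >= 2 & p < 0.01 differential-expression filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .chem import get_compound, ion_mz, nominal_mz
from .errors import ConfigError, SchemaError

__all__ = [
    "TransitionDef",
    "QuantSample",
    "QuantResult",
    "default_library",
    "load_transition_library",
    "blank_correct",
    "quantify",
    "GroupStats",
    "group_stats",
    "compact_letter_display",
    "two_sample_test",
    "fold_change",
    "ratio_of_means",
    "filter_de_table",
    "results_to_frame",
]


@dataclass(frozen=True)
class TransitionDef:
    """One scheduled-MRM transition (Q1/Q3 nominal m/z plus source settings)."""

    analyte: str
    q1_nominal: int
    q3_nominal: int
    dp_volts: float
    ep_volts: float
    ce_volts: float
    internal_standard: str
    polarity: str = "negative"
    relative: bool = False  # surrogate-IS analytes: report area ratio only
    lod: Mapping[str, float] = field(default_factory=dict)  # matrix -> nmol/g FW

    def __post_init__(self):
        if not (self.q1_nominal > self.q3_nominal > 0):
            raise ConfigError(
                f"{self.analyte}: need Q1 > Q3 > 0, got {self.q1_nominal}/{self.q3_nominal}"
            )


def _default_transitions() -> list[TransitionDef]:
    t = TransitionDef
    return [
        t("JA", 209, 59, -30, -4.5, -24, "D5-JA"),
        t("D5-JA", 214, 62, -35, -8.5, -24, "D5-JA"),
        t("12-OH-JA", 225, 59, -35, -9, -28, "D5-JA"),
        t("OPDA", 291, 165, -50, -5, -26, "D5-OPDA"),
        t("D5-OPDA", 296, 170, -65, -4, -28, "D5-OPDA"),
        t("JA-Val", 308, 116, -45, -5, -28, "D3-JA-Leu"),
        t(
            "JA-Ile", 322, 130, -45, -5, -28, "D3-JA-Leu",
            lod={"flowers": 0.017, "leaves": 0.00085},
        ),
        t("D3-JA-Leu", 325, 133, -65, -4, -30, "D3-JA-Leu"),
        t("JA-Gln", 337, 145, -45, -5, -28, "D5-JA", relative=True),
        t("12-OH-JA-Ile", 338, 130, -45, -10, -30, "D5-JA", relative=True),
    ]


def default_library() -> dict[str, TransitionDef]:
    """The built-in ten-transition jasmonate panel, keyed by analyte."""
    return {t.analyte: t for t in _default_transitions()}


def load_transition_library(config: Optional[Iterable[Mapping]] = None) -> dict[str, TransitionDef]:
    """Build a transition library from config entries (default panel if None)."""
    if config is None:
        return default_library()
    lib: dict[str, TransitionDef] = {}
    for entry in config:
        t = TransitionDef(
            analyte=entry["analyte"],
            q1_nominal=int(entry["q1_nominal"]),
            q3_nominal=int(entry["q3_nominal"]),
            dp_volts=float(entry.get("dp_volts", 0.0)),
            ep_volts=float(entry.get("ep_volts", 0.0)),
            ce_volts=float(entry.get("ce_volts", 0.0)),
            internal_standard=entry["internal_standard"],
            polarity=entry.get("polarity", "negative"),
            relative=bool(entry.get("relative", False)),
            lod=dict(entry.get("lod", {})),
        )
        if t.analyte in lib:
            raise ConfigError(f"duplicate analyte {t.analyte!r} in transition library")
        lib[t.analyte] = t
    for t in lib.values():
        if t.internal_standard not in lib:
            raise ConfigError(
                f"{t.analyte}: internal standard {t.internal_standard!r} not in library"
            )
    return lib


def library_q1_from_formula(analyte: str) -> int:
    """Cross-check helper: nominal [M-H]- of the registered compound."""
    return nominal_mz(ion_mz(get_compound(analyte).formula, "negative"))


@dataclass(frozen=True)
class QuantSample:
    """Per-sample signals: analyte -> (peak area, peak height)."""

    sample_id: str
    genotype: str
    signals: Mapping[str, tuple]
    fresh_weight: float = 1.0
    treatment: str = ""
    matrix: str = "flowers"

    def __post_init__(self):
        if not self.fresh_weight > 0:
            raise SchemaError(f"{self.sample_id}: fresh_weight must be > 0")
        for a, (area, height) in self.signals.items():
            if area < 0 or height < 0:
                raise SchemaError(f"{self.sample_id}: negative signal for {a!r}")

    def area(self, analyte: str) -> float:
        return self.signals.get(analyte, (0.0, 0.0))[0]

    def height(self, analyte: str) -> float:
        return self.signals.get(analyte, (0.0, 0.0))[1]


@dataclass(frozen=True)
class QuantResult:
    analyte: str
    sample_id: str
    amount: Optional[float]  # None when bdl / blank-fail
    unit: str  # "nmol/gFW" or "relative-response"
    flag: str  # quantified | bdl | blank-fail
    lod: Optional[float] = None  # matrix LOD attached to bdl results


def blank_correct(
    sample: QuantSample, blanks: Sequence[QuantSample], k: float = 3.0
) -> dict[str, bool]:
    """Per-analyte detection flags from the k-fold blank-height rule.

    An analyte counts as detected iff its peak height is at least ``k`` times
    the maximum height observed for it across the blank samples.  A zero
    blank height means any nonzero signal is detected.
    """
    if not k > 0:
        raise ConfigError(f"blank factor k must be > 0, got {k}")
    if not blanks:
        raise SchemaError("need at least one blank sample")
    analytes = set(sample.signals)
    detected = {}
    for a in analytes:
        background = max(b.height(a) for b in blanks)
        h = sample.height(a)
        detected[a] = h >= k * background and h > 0
    return detected


def quantify(
    sample: QuantSample,
    library: Mapping[str, TransitionDef],
    is_amounts: Mapping[str, float],
    detected: Optional[Mapping[str, bool]] = None,
    blanks: Optional[Sequence[QuantSample]] = None,
    k: float = 3.0,
) -> list[QuantResult]:
    """Internal-standard-normalized amounts for every non-standard analyte.

    amount = (area_analyte / area_IS) * n_IS / fresh_weight for analytes with
    an authentic labelled standard (``is_amounts``: standard -> nmol spiked);
    surrogate-normalized analytes report the plain area ratio
    (unit "relative-response").  Undetected analytes are flagged *bdl* with
    the matrix LOD attached; a zero IS area fails its dependents (*blank-fail*).
    """
    if detected is None:
        if blanks is None:
            raise SchemaError("quantify needs detection flags or blank samples")
        detected = blank_correct(sample, blanks, k=k)
    results = []
    for analyte, t in library.items():
        if analyte == t.internal_standard:  # the standards themselves
            continue
        if analyte not in sample.signals:
            continue
        lod = t.lod.get(sample.matrix)
        unit = "relative-response" if t.relative else "nmol/gFW"
        if not detected.get(analyte, False):
            results.append(QuantResult(analyte, sample.sample_id, None, unit, "bdl", lod))
            continue
        is_area = sample.area(t.internal_standard)
        if is_area <= 0:
            results.append(
                QuantResult(analyte, sample.sample_id, None, unit, "blank-fail", lod)
            )
            continue
        ratio = sample.area(analyte) / is_area
        if t.relative:
            results.append(QuantResult(analyte, sample.sample_id, ratio, unit, "quantified"))
        else:
            n_is = is_amounts.get(t.internal_standard)
            if n_is is None:
                raise ConfigError(
                    f"no spiked amount for internal standard {t.internal_standard!r}"
                )
            amount = ratio * n_is / sample.fresh_weight
            results.append(
                QuantResult(analyte, sample.sample_id, amount, unit, "quantified")
            )
    return results


def results_to_frame(results: Sequence[QuantResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "analyte": [r.analyte for r in results],
            "sample_id": [r.sample_id for r in results],
            "amount": [r.amount for r in results],
            "unit": [r.unit for r in results],
            "flag": [r.flag for r in results],
            "lod": [r.lod for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupStats:
    groups: tuple
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, p_value, reject
    letters: Mapping[str, str]
    alpha: float


def compact_letter_display(
    groups: Sequence[str], significant: set, alpha_order: Optional[Sequence[str]] = None
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    ``significant`` holds frozensets {g1, g2} of significantly different
    pairs.  The returned letters satisfy: two groups share at least one
    letter iff their pair is NOT in ``significant``.
    """
    order = list(alpha_order) if alpha_order is not None else list(groups)
    columns: list[set] = [set(order)]
    for g1, g2 in sorted(tuple(sorted(p)) for p in significant):
        split: list[set] = []
        for col in columns:
            if g1 in col and g2 in col:  # insert: duplicate minus each member
                split.append(col - {g1})
                split.append(col - {g2})
            else:
                split.append(col)
        # absorb: keep only maximal, distinct, non-empty columns
        columns = []
        for col in split:
            if col and not any(col < other for other in split) and col not in columns:
                columns.append(col)
    # deterministic letter order: by first member in group order
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for i, col in enumerate(columns):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in order:
            if g in col:
                letters[g] += ch
    return letters


def group_stats(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupStats:
    """One-way ANOVA + Tukey HSD + compact letter display over named groups."""
    groups = [g for g in values]
    if len(groups) < 2:
        raise SchemaError("need at least two groups")
    arrays = {g: np.asarray(list(values[g]), dtype=float) for g in groups}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise SchemaError(f"group {g!r} needs >= 2 observations")

    anova_p = float(_stats.f_oneway(*[arrays[g] for g in groups]).pvalue)
    flat = np.concatenate([arrays[g] for g in groups])
    labels = np.concatenate([[g] * arrays[g].size for g in groups])
    res = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    summary = np.asarray(res.summary().data[1:], dtype=object)
    tk = pd.DataFrame(
        {
            "group1": summary[:, 0],
            "group2": summary[:, 1],
            "p_value": res.pvalues,
            "reject": res.reject,
        }
    )
    significant = {
        frozenset((r.group1, r.group2)) for r in tk.itertuples() if r.p_value < alpha
    }
    letters = compact_letter_display(groups, significant)
    return GroupStats(tuple(groups), anova_p, tk, letters, alpha)


def two_sample_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Student's t-test p-value (equal variances) for pairwise comparisons."""
    return float(_stats.ttest_ind(np.asarray(a, float), np.asarray(b, float)).pvalue)


def ratio_of_means(numerator: Sequence[float], denominator: Sequence[float]) -> float:
    """Ratio of arithmetic group means (the relative-activity estimator)."""
    num = np.asarray(list(numerator), dtype=float)
    den = np.asarray(list(denominator), dtype=float)
    if num.size == 0 or den.size == 0:
        raise SchemaError("empty group in ratio_of_means")
    dmean = den.mean()
    if not dmean > 0:
        raise SchemaError("denominator group mean must be > 0")
    return float(num.mean() / dmean)


@dataclass(frozen=True)
class FoldChange:
    ratio: Optional[float]
    n_numerator: int
    n_denominator: int
    n_bdl_numerator: int
    n_bdl_denominator: int
    defined: bool


def fold_change(
    results: Sequence[QuantResult],
    group_of: Mapping[str, str],
    analyte: str,
    numerator_group: str,
    denominator_group: str,
) -> FoldChange:
    """Fold change of group-mean quantified amounts; bdl values excluded.

    Undefined (flagged) when either group has no quantified observations or
    the denominator mean is zero.
    """
    num, den, bdl_num, bdl_den = [], [], 0, 0
    for r in results:
        if r.analyte != analyte:
            continue
        g = group_of.get(r.sample_id)
        if g == numerator_group:
            if r.flag == "quantified":
                num.append(r.amount)
            elif r.flag == "bdl":
                bdl_num += 1
        elif g == denominator_group:
            if r.flag == "quantified":
                den.append(r.amount)
            elif r.flag == "bdl":
                bdl_den += 1
    if not num or not den or not (np.mean(den) > 0):
        return FoldChange(None, len(num), len(den), bdl_num, bdl_den, False)
    return FoldChange(
        float(np.mean(num) / np.mean(den)), len(num), len(den), bdl_num, bdl_den, True
    )


def filter_de_table(
    table: pd.DataFrame,
    up_lfc: float = 2.0,
    down_lfc: float = -2.0,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a differential-expression table into up/down lists.

    Up iff log2fc >= up_lfc and p < alpha; down iff log2fc <= down_lfc and
    p < alpha.  Fold-change boundaries are inclusive, the p cut-off strict.
    """
    for col in ("gene", "log2fc", "p"):
        if col not in table.columns:
            raise SchemaError(f"DE table missing column {col!r}")
    bad = table.index[table["log2fc"].isna() | table["p"].isna()].tolist()
    if bad:
        raise SchemaError(f"malformed DE row(s) at index {bad}")
    up = table[(table["log2fc"] >= up_lfc) & (table["p"] < alpha)]
    down = table[(table["log2fc"] <= down_lfc) & (table["p"] < alpha)]
    return up.reset_index(drop=True), down.reset_index(drop=True)
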