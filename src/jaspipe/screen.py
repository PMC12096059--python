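"""Ex vivo screen: call features substrate / product / unchanged / low-signal.

An ex vivo incubation compares a total metabolite extract incubated with
active enzyme against inactivated-enzyme controls.  Features depleted in the
active samples are substrate candidates, features enriched are product
candidates — the intensity pattern characteristic of an enzymatic
substrate-product pair.

Calls combine a fold-change rule (default two-fold either way) with a
per-feature two-sample test (Welch t on log2(x+1), or rank-sum) and
Benjamini-Hochberg correction across features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, SchemaError
from .features import FeatureTable

__all__ = ["ScreenConfig", "FeatureCall", "classify_features", "calls_to_frame"]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the substrate/product classification.

    The two-fold cut-offs (0.5 / 2.0) and alpha = 0.05 are conventional
    defaults; the screen is pattern-based and the thresholds configurable.
    """

    substrate_max_ratio: float = 0.5
    product_min_ratio: float = 2.0
    alpha: float = 0.05
    mt_method: str = "BH"  # "BH" or "none"
    min_mean_intensity: float = 0.0
    test: str = "welch-t"  # "welch-t" or "rank-sum"

    def __post_init__(self):
        if not (0 < self.substrate_max_ratio < 1 < self.product_min_ratio):
            raise ConfigError(
                "need 0 < substrate_max_ratio < 1 < product_min_ratio, got "
                f"{self.substrate_max_ratio} / {self.product_min_ratio}"
            )
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mt_method not in ("BH", "none"):
            raise ConfigError(f"mt_method must be 'BH' or 'none', got {self.mt_method!r}")
        if self.test not in ("welch-t", "rank-sum"):
            raise ConfigError(f"test must be 'welch-t' or 'rank-sum', got {self.test!r}")


@dataclass(frozen=True)
class FeatureCall:
    feature_id: str
    mean_active: float
    mean_inactive: float
    log2_ratio: float  # active / inactive
    p_value: float
    q_value: float
    call: str  # substrate | product | unchanged | low-signal


def _pvalue(a: np.ndarray, b: np.ndarray, test: str) -> float:
    """Two-sample p; degenerate (zero-variance) groups fall back to 0/1.

    When both groups are constant the test statistic is undefined: equal
    constants give p = 1, unequal constants p = 0 (fold-change-only calling),
    so noiseless synthetic data never produces NaN.
    """
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if test == "welch-t":
        stat = _stats.ttest_ind(np.log2(a + 1), np.log2(b + 1), equal_var=False)
        p = float(stat.pvalue)
    else:
        p = float(_stats.ranksums(a, b).pvalue)
    if math.isnan(p):
        return 1.0 if a.mean() == b.mean() else 0.0
    return p


def classify_features(
    table: FeatureTable,
    config: ScreenConfig = ScreenConfig(),
    active_condition: str = "active",
    inactive_condition: str = "inactive",
) -> list[FeatureCall]:
    """Classify every feature from active vs. inactive intensity patterns.

    A feature is *low-signal* if both condition means fall below the floor
    (or both are zero); *substrate* if active/inactive <= substrate_max_ratio
    and q <= alpha; *product* if the ratio >= product_min_ratio and
    q <= alpha; otherwise *unchanged*.  A zero inactive mean with nonzero
    active mean gives ratio +inf (product candidate).
    """
    act = table.samples_in_condition(active_condition)
    inact = table.samples_in_condition(inactive_condition)
    if not act or not inact:
        raise SchemaError(
            f"need both conditions {active_condition!r} and {inactive_condition!r}"
        )
    if len(act) < 2 or len(inact) < 2:
        raise SchemaError("need >= 2 replicates per condition")

    mat = table.intensity_matrix()
    a_mat = mat[act].to_numpy()
    b_mat = mat[inact].to_numpy()
    fids = list(mat.index)

    means_a = a_mat.mean(axis=1)
    means_b = b_mat.mean(axis=1)
    floor = config.min_mean_intensity
    low = ((means_a < floor) & (means_b < floor)) | ((means_a == 0) & (means_b == 0))

    pvals = np.full(len(fids), np.nan)
    for i in range(len(fids)):
        if not low[i]:
            pvals[i] = _pvalue(a_mat[i], b_mat[i], config.test)

    qvals = np.full(len(fids), np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        if config.mt_method == "BH":
            qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
        else:
            qvals[tested] = pvals[tested]

    calls = []
    for i, fid in enumerate(fids):
        ma, mb = float(means_a[i]), float(means_b[i])
        if low[i]:
            calls.append(FeatureCall(fid, ma, mb, math.nan, math.nan, math.nan, "low-signal"))
            continue
        ratio = math.inf if mb == 0 else ma / mb
        log2_ratio = (
            math.inf if ratio == math.inf
            else (-math.inf if ratio == 0 else math.log2(ratio))
        )
        p, q = float(pvals[i]), float(qvals[i])
        if ratio <= config.substrate_max_ratio and q <= config.alpha:
            call = "substrate"
        elif ratio >= config.product_min_ratio and q <= config.alpha:
            call = "product"
        else:
            call = "unchanged"
        calls.append(FeatureCall(fid, ma, mb, log2_ratio, p, q, call))
    return calls


def calls_to_frame(calls) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "mean_active": [c.mean_active for c in calls],
            "mean_inactive": [c.mean_inactive for c in calls],
            "log2_ratio": [c.log2_ratio for c in calls],
            "p_value": [c.p_value for c in calls],
            "q_value": [c.q_value for c in calls],
            "call": [c.call for c in calls],
        }
    )
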