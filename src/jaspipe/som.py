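"""Metabolite fingerprinting: FDR pre-filter and 1-D self-organizing map.

The fingerprinting stage reduces an untargeted feature table to the features
whose intensity differs across experimental groups (per-feature one-way
ANOVA, Benjamini-Hochberg FDR across features, default q < 1e-5), builds a
per-feature profile of z-scored group means, and orders the profiles into a
small number of clusters along a one-dimensional self-organizing map.

The SOM is trained in *batch* mode: every epoch assigns each profile to its
nearest prototype and recomputes all prototypes as neighborhood-weighted
means (Gaussian neighborhood on the chain index, width shrinking on a
geometric schedule).  Batch training is deterministic and invariant to the
order of the input rows, which makes the model reproducible and testable;
there is no learning rate.  Prototypes are initialized at evenly spaced
quantiles along the first principal axis, so the chain is ordered from the
start; the seed only drives optional jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, SchemaError
from .features import FeatureTable

__all__ = [
    "FingerprintConfig",
    "SomModel",
    "fdr_filter",
    "profile_matrix",
    "train_som_1d",
    "cluster_summary",
    "fingerprint",
]


@dataclass(frozen=True)
class FingerprintConfig:
    fdr_threshold: float = 1e-5
    n_clusters: int = 9
    epochs: int = 30
    neighborhood_sigma_schedule: tuple = (2.0, 0.05)
    learning_rate_schedule: Optional[tuple] = None  # unused: batch training
    seed: int = 0
    init_jitter: float = 0.0
    normalization: str = "feature-zscore-of-group-means"

    def __post_init__(self):
        if not (0 < self.fdr_threshold <= 1):
            raise ConfigError(f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}")
        if self.n_clusters < 1:
            raise ConfigError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if self.epochs < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        s0, s1 = self.neighborhood_sigma_schedule
        if not (s0 > 0 and s1 > 0):
            raise ConfigError("neighborhood sigmas must be > 0")
        if self.normalization not in ("feature-zscore-of-group-means", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")


@dataclass
class SomModel:
    """Ordered 1-D prototype chain with feature assignments."""

    prototypes: np.ndarray  # (K, D)
    assignments: np.ndarray  # (n,) cluster index per feature
    quantization_error: float  # mean Euclidean distance to the winning prototype
    cluster_sizes: np.ndarray  # (K,)
    qe_history: list = field(default_factory=list)  # per-epoch QE
    feature_ids: Optional[list] = None


def fdr_filter(
    table: FeatureTable,
    groups: Mapping[str, str],
    threshold: float = 1e-5,
) -> pd.DataFrame:
    """Per-feature one-way ANOVA across groups with BH correction.

    ``groups`` maps sample_id -> group label.  Returns a frame with columns
    feature_id, p_value, q_value, retained.  Features that are constant
    across all samples have an undefined F statistic and are never retained.
    """
    mat = table.intensity_matrix()
    by_group: dict[str, list[str]] = {}
    for sid in mat.columns:
        g = groups.get(sid)
        if g is not None:
            by_group.setdefault(g, []).append(sid)
    if len(by_group) < 2:
        raise SchemaError("need >= 2 groups for the FDR filter")
    for g, sids in by_group.items():
        if len(sids) < 2:
            raise SchemaError(f"group {g!r} needs >= 2 replicates")

    arrays = [mat[sids].to_numpy() for sids in by_group.values()]
    n = len(mat.index)
    pvals = np.full(n, np.nan)
    for i in range(n):
        rows = [a[i] for a in arrays]
        flat = np.concatenate(rows)
        if np.allclose(flat, flat[0]):
            continue  # constant feature: F undefined
        with np.errstate(invalid="ignore", divide="ignore"):
            p = _stats.f_oneway(*rows).pvalue
        if np.isfinite(p):
            pvals[i] = p

    qvals = np.full(n, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    retained = ok & (qvals < threshold)
    return pd.DataFrame(
        {
            "feature_id": list(mat.index),
            "p_value": pvals,
            "q_value": qvals,
            "retained": retained,
        }
    )


def profile_matrix(
    table: FeatureTable,
    groups: Mapping[str, str],
    feature_ids: Optional[Sequence[str]] = None,
    normalization: str = "feature-zscore-of-group-means",
) -> tuple[np.ndarray, list, list]:
    """Per-feature profile of group-mean intensities, optionally z-scored.

    Returns (matrix of shape n_features x n_groups, feature ids, group names).
    Group order follows first appearance in the sample list.
    """
    mat = table.intensity_matrix()
    if feature_ids is not None:
        mat = mat.loc[list(feature_ids)]
    group_names: list[str] = []
    cols: dict[str, list[str]] = {}
    for s in table.samples:
        g = groups.get(s.sample_id)
        if g is None:
            continue
        if g not in cols:
            group_names.append(g)
            cols[g] = []
        cols[g].append(s.sample_id)
    means = np.column_stack([mat[cols[g]].to_numpy().mean(axis=1) for g in group_names])
    if normalization == "feature-zscore-of-group-means":
        mu = means.mean(axis=1, keepdims=True)
        sd = means.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        means = (means - mu) / sd
    return means, list(mat.index), group_names


def _init_prototypes(X: np.ndarray, k: int, rng, jitter: float) -> np.ndarray:
    """Evenly spaced quantiles along the first principal axis of the data."""
    center = X.mean(axis=0)
    Xc = X - center
    # first right singular vector = first principal axis
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    axis = vt[0]
    # fix the SVD sign ambiguity so the chain order is permutation-invariant
    pivot = int(np.argmax(np.abs(axis)))
    if axis[pivot] < 0:
        axis = -axis
    proj = Xc @ axis
    if k == 1:
        q = np.array([np.median(proj)])
    else:
        q = np.quantile(proj, np.linspace(0.0, 1.0, k))
    protos = center[None, :] + q[:, None] * axis[None, :]
    if jitter > 0:
        protos = protos + rng.normal(scale=jitter, size=protos.shape)
    return protos


def _assign(X: np.ndarray, protos: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - protos[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _qe(X: np.ndarray, protos: np.ndarray, assign: np.ndarray) -> float:
    diff = X - protos[assign]
    return float(np.sqrt((diff**2).sum(axis=1)).mean())


def train_som_1d(
    X: np.ndarray, config: FingerprintConfig = FingerprintConfig(), feature_ids=None
) -> SomModel:
    """Batch-train a 1-D SOM chain on a features x dimensions matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise SchemaError("profile matrix must be 2-D (features x dimensions)")
    n, _ = X.shape
    k = config.n_clusters
    if k > n:
        raise SchemaError(f"n_clusters ({k}) exceeds number of features ({n})")

    rng = np.random.default_rng(config.seed)
    protos = _init_prototypes(X, k, rng, config.init_jitter)
    s0, s1 = config.neighborhood_sigma_schedule
    idx = np.arange(k, dtype=float)

    qe_history = []
    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        sigma = s0 * (s1 / s0) ** frac  # geometric shrink
        bmu = _assign(X, protos)
        # Gaussian neighborhood weight of each prototype for each sample's bmu
        h = np.exp(-((idx[None, :] - bmu[:, None]) ** 2) / (2.0 * sigma**2))  # (n, K)
        denom = h.sum(axis=0)  # (K,)
        numer = h.T @ X  # (K, D)
        update = denom > 1e-12
        protos[update] = numer[update] / denom[update, None]
        qe_history.append(_qe(X, protos, _assign(X, protos)))

    assign = _assign(X, protos)
    sizes = np.bincount(assign, minlength=k)
    return SomModel(
        prototypes=protos,
        assignments=assign,
        quantization_error=_qe(X, protos, assign),
        cluster_sizes=sizes,
        qe_history=qe_history,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
    )


def cluster_summary(
    model: SomModel, X: np.ndarray, dim_names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-cluster mean profile and membership count, chain order preserved."""
    X = np.asarray(X, dtype=float)
    k = model.prototypes.shape[0]
    names = list(dim_names) if dim_names is not None else [
        f"dim{j}" for j in range(X.shape[1])
    ]
    rows = []
    for c in range(k):
        members = model.assignments == c
        count = int(members.sum())
        mean = X[members].mean(axis=0) if count else np.full(X.shape[1], np.nan)
        rows.append({"cluster": c, "count": count, **dict(zip(names, mean))})
    return pd.DataFrame(rows)


def fingerprint(
    table: FeatureTable,
    groups: Mapping[str, str],
    config: FingerprintConfig = FingerprintConfig(),
) -> tuple[pd.DataFrame, SomModel, pd.DataFrame]:
    """Full fingerprinting stage: FDR filter -> profiles -> 1-D SOM.

    Returns (filter frame, trained model, cluster summary).
    """
    filt = fdr_filter(table, groups, threshold=config.fdr_threshold)
    kept = filt.loc[filt["retained"], "feature_id"].tolist()
    if len(kept) < config.n_clusters:
        raise SchemaError(
            f"only {len(kept)} features pass the FDR filter; "
            f"fewer than n_clusters ({config.n_clusters})"
        )
    X, fids, group_names = profile_matrix(
        table, groups, feature_ids=kept, normalization=config.normalization
    )
    model = train_som_1d(X, config, feature_ids=fids)
    summary = cluster_summary(model, X, dim_names=group_names)
    return filt, model, summary
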