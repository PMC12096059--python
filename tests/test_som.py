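"""FDR filter and 1-D batch SOM: oracle ANOVA, convergence, invariances."""

import numpy as np
import pytest
from scipy import stats as sps

from jaspipe.errors import ConfigError, SchemaError
from jaspipe.features import Feature, FeatureTable, SampleMeta
from jaspipe.som import (
    FingerprintConfig,
    cluster_summary,
    fdr_filter,
    fingerprint,
    profile_matrix,
    train_som_1d,
)


def _group_table(n_planted=10, n_flat=30, n_groups=3, n_rep=3, effect=10.0, seed=0):
    rng = np.random.default_rng(seed)
    samples, groups = [], {}
    for g in range(n_groups):
        for r in range(n_rep):
            sid = f"g{g}_r{r}"
            samples.append(SampleMeta(sid, condition=f"group{g}", replicate=r + 1))
            groups[sid] = f"group{g}"
    features = []
    for i in range(n_planted):
        hot = i % n_groups
        intens = {}
        for s in samples:
            base = effect * 100 if groups[s.sample_id] == f"group{hot}" else 100.0
            intens[s.sample_id] = base * (1 + rng.normal(0, 0.02))
        features.append(Feature(f"P{i}", mz=200 + i, rt=1.0, intensities=intens))
    for i in range(n_flat):
        intens = {s.sample_id: 100.0 * (1 + rng.normal(0, 0.02)) for s in samples}
        features.append(Feature(f"N{i}", mz=400 + i, rt=1.0, intensities=intens))
    return FeatureTable(samples=samples, features=features), groups


def test_fdr_filter_retains_planted_removes_decoys():
    table, groups = _group_table()
    res = fdr_filter(table, groups, threshold=1e-3)
    retained = set(res.loc[res["retained"], "feature_id"])
    assert retained == {f"P{i}" for i in range(10)}


def test_fdr_filter_oracle_anova_p():
    table, groups = _group_table(n_planted=3, n_flat=3)
    res = fdr_filter(table, groups, threshold=1.0).set_index("feature_id")
    mat = table.intensity_matrix()
    sids_by_group = {}
    for sid, g in groups.items():
        sids_by_group.setdefault(g, []).append(sid)
    for fid in mat.index:
        rows = [mat.loc[fid, sids].to_numpy() for sids in sids_by_group.values()]
        assert res.loc[fid, "p_value"] == pytest.approx(
            sps.f_oneway(*rows).pvalue, rel=1e-9
        )


def test_constant_feature_removed_even_at_threshold_one():
    table, groups = _group_table(n_planted=2, n_flat=2)
    const = Feature("CONST", mz=500.0, rt=1.0,
                    intensities={s.sample_id: 7.0 for s in table.samples})
    table = FeatureTable(samples=table.samples, features=table.features + [const])
    res = fdr_filter(table, groups, threshold=1.0).set_index("feature_id")
    assert not res.loc["CONST", "retained"]
    assert res.drop("CONST")["retained"].all()


def test_fdr_filter_rejects_degenerate_grouping():
    table, groups = _group_table()
    with pytest.raises(SchemaError):
        fdr_filter(table, {sid: "one" for sid in groups})


def test_profile_matrix_zscore():
    table, groups = _group_table(n_planted=4, n_flat=0)
    X, fids, names = profile_matrix(table, groups)
    assert X.shape == (4, 3) and len(names) == 3
    assert np.allclose(X.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(X.std(axis=1), 1, atol=1e-12)


def test_k1_prototype_is_data_mean():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 6))
    m = train_som_1d(X, FingerprintConfig(n_clusters=1, epochs=5))
    assert np.allclose(m.prototypes[0], X.mean(axis=0), atol=1e-12)


def test_two_blob_recovery():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(0, 0.05, (25, 4)), rng.normal(10, 0.05, (15, 4))])
    labels = np.array([0] * 25 + [1] * 15)
    m = train_som_1d(X, FingerprintConfig(n_clusters=2, epochs=20,
                                          neighborhood_sigma_schedule=(1.0, 0.05)))
    assign = m.assignments
    if assign[0] == 1:
        assign = 1 - assign
    assert np.array_equal(assign, labels)


def test_qe_non_increasing_fixed_sigma():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(120, 5))
    for sigma in (0.3, 1.0):
        cfg = FingerprintConfig(n_clusters=5, epochs=25,
                                neighborhood_sigma_schedule=(sigma, sigma))
        m = train_som_1d(X, cfg)
        qe = m.qe_history
        assert all(b <= a + 1e-9 for a, b in zip(qe, qe[1:]))


def test_zero_width_limit_equals_kmeans_fixed_point():
    """With a vanishing neighborhood the update is the k-means centroid step."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 3))
    cfg = FingerprintConfig(n_clusters=3, epochs=40,
                            neighborhood_sigma_schedule=(1e-3, 1e-3))
    m = train_som_1d(X, cfg)
    for c in range(3):
        members = m.assignments == c
        if members.any():
            assert np.allclose(m.prototypes[c], X[members].mean(axis=0), atol=1e-6)


def test_determinism_and_permutation_invariance():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(50, 4))
    cfg = FingerprintConfig(n_clusters=4, epochs=15, seed=7)
    m1 = train_som_1d(X, cfg)
    m2 = train_som_1d(X, cfg)
    assert np.array_equal(m1.prototypes, m2.prototypes)
    perm = rng.permutation(50)
    m3 = train_som_1d(X[perm], cfg)
    assert np.allclose(m1.prototypes, m3.prototypes, atol=1e-8)
    assert np.array_equal(m1.assignments[perm], m3.assignments)


def test_k_exceeding_features_rejected():
    with pytest.raises(SchemaError):
        train_som_1d(np.zeros((3, 2)), FingerprintConfig(n_clusters=9))
    with pytest.raises(ConfigError):
        FingerprintConfig(n_clusters=0)


def test_cluster_summary_counts_and_means():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 3))
    m = train_som_1d(X, FingerprintConfig(n_clusters=3, epochs=10))
    summary = cluster_summary(m, X, dim_names=["a", "b", "c"])
    assert summary["count"].sum() == 30
    assert list(summary["cluster"]) == [0, 1, 2]
    m1 = train_som_1d(X, FingerprintConfig(n_clusters=1, epochs=5))
    s1 = cluster_summary(m1, X)
    assert np.allclose(s1.iloc[0, 2:].to_numpy(dtype=float), X.mean(axis=0))


def test_fingerprint_end_to_end():
    table, groups = _group_table(n_planted=12, n_flat=20)
    cfg = FingerprintConfig(fdr_threshold=1e-3, n_clusters=3, epochs=15)
    filt, model, summary = fingerprint(table, groups, cfg)
    assert int(filt["retained"].sum()) == 12
    assert summary["count"].sum() == 12
    assert model.cluster_sizes.sum() == 12
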