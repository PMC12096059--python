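import numpy as np
import pytest

from jaspipe.features import Feature, FeatureTable, SampleMeta


@pytest.fixture
def small_table():
    """3 features x 6 samples (3 active / 3 inactive) with simple patterns."""
    samples = [SampleMeta(f"a{i}", "active", replicate=i) for i in (1, 2, 3)] + [
        SampleMeta(f"i{i}", "inactive", replicate=i) for i in (1, 2, 3)
    ]

    def feat(fid, mz, act, inact):
        intens = {f"a{i}": act[i - 1] for i in (1, 2, 3)}
        intens.update({f"i{i}": inact[i - 1] for i in (1, 2, 3)})
        return Feature(fid, mz=mz, rt=100.0, intensities=intens)

    features = [
        feat("sub", 209.1183, [20.0, 21.0, 19.0], [100.0, 99.0, 101.0]),
        feat("prod", 322.2024, [80.0, 79.0, 81.0], [0.0, 0.0, 0.0]),
        feat("flat", 400.0, [50.0, 51.0, 49.0], [50.0, 49.0, 51.0]),
    ]
    return FeatureTable(samples=samples, features=features)


def bh_bruteforce(pvals):
    """Textbook step-up Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
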