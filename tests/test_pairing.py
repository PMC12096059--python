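"""Mass-shift pairing: candidates, brute-force equivalence, MS/MS support."""

import numpy as np
import pytest

from jaspipe.chem import amino_acid_compounds, build_shift_table
from jaspipe.errors import ConfigError
from jaspipe.features import Feature, FeatureTable, MsmsSpectrum, SampleMeta
from jaspipe.pairing import (
    PairingConfig,
    annotate_msms,
    expected_aa_fragment,
    find_pairs,
    msms_support,
)
from jaspipe.screen import FeatureCall, classify_features
from jaspipe.synth import GeneratorConfig, gen_exvivo_table

SHIFTS = tuple(build_shift_table(amino_acid_compounds(), include_hydroxylation=True))


def _table(mzs):
    samples = [SampleMeta("a1", "active"), SampleMeta("i1", "inactive")]
    feats = [
        Feature(f"f{i}", mz=mz, rt=1.0, intensities={"a1": 1.0, "i1": 1.0})
        for i, mz in enumerate(mzs)
    ]
    return FeatureTable(samples=samples, features=feats)


def _calls(table, subs, prods):
    out = []
    for f in table.features:
        call = "substrate" if f.feature_id in subs else (
            "product" if f.feature_id in prods else "unchanged"
        )
        out.append(FeatureCall(f.feature_id, 1, 1, 0.0, 0.01, 0.01, call))
    return out


def test_ile_leu_merged_single_candidate():
    table = _table([209.11832, 322.20237])
    pairs = find_pairs(_calls(table, {"f0"}, {"f1"}), table, PairingConfig(shifts=SHIFTS))
    assert len(pairs) == 1
    assert pairs[0].shift_names == ("Ile", "Leu")
    # input m/z printed to 5 decimals, so the residual error is < 0.1 ppm
    assert abs(pairs[0].mass_error_ppm) < 0.1


def test_hydroxylation_shift():
    table = _table([209.11832, 225.11323])
    pairs = find_pairs(_calls(table, {"f0"}, {"f1"}), table, PairingConfig(shifts=SHIFTS))
    assert [p.shift_names for p in pairs] == [("hydroxylation",)]


def test_outside_tolerance_no_candidate():
    table = _table([209.11832, 322.20237 + 0.05])
    pairs = find_pairs(_calls(table, {"f0"}, {"f1"}), table, PairingConfig(shifts=SHIFTS))
    assert pairs == []


def test_empty_shift_table_rejected():
    with pytest.raises(ConfigError):
        PairingConfig(shifts=())


def brute_force_pairs(calls, table, config):
    """Oracle: exhaustive scan over all feature pairs x merged shifts."""
    call_of = {c.feature_id: c.call for c in calls}
    merged = {}
    for s in config.shifts:
        key = s.delta_formula if s.delta_formula is not None else round(s.delta_mass, 6)
        names, _ = merged.get(key, ((), s.delta_mass))
        merged[key] = (tuple(sorted(set(names) | {s.name})), s.delta_mass)
    found = set()
    for fs in table.features:
        for fp in table.features:
            if call_of.get(fs.feature_id) != "substrate":
                continue
            if call_of.get(fp.feature_id) != "product":
                continue
            if config.require_same_ion_mode and fs.ion_mode != fp.ion_mode:
                continue
            for names, delta in merged.values():
                if abs((fp.mz - fs.mz) - delta) <= config.tol_ppm * fp.mz * 1e-6:
                    found.add((fs.feature_id, fp.feature_id, names))
    return found


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_bruteforce_on_random_tables(seed):
    """On <= 50-feature tables find_pairs equals the exhaustive oracle."""
    rng = np.random.default_rng(seed)
    n = 50
    mzs = rng.uniform(150, 600, n)
    table = _table(mzs)
    fids = [f.feature_id for f in table.features]
    subs = set(rng.choice(fids, size=15, replace=False))
    prods = set(rng.choice([f for f in fids if f not in subs], size=15, replace=False))
    # plant a handful of exact-shift products so the oracle has hits
    sub_list = sorted(subs)
    for i, s in enumerate(sub_list[:5]):
        delta = SHIFTS[i * 3].delta_mass
        fid = f"planted{i}"
        table.features.append(
            Feature(fid, mz=table.feature(s).mz + delta, rt=1.0,
                    intensities={"a1": 1.0, "i1": 1.0})
        )
        prods.add(fid)
    table = FeatureTable(samples=table.samples, features=table.features)
    cfg = PairingConfig(tol_ppm=10.0, shifts=SHIFTS)
    calls = _calls(table, subs, prods)
    got = {(p.substrate_feature_id, p.product_feature_id, p.shift_names)
           for p in find_pairs(calls, table, cfg)}
    assert got == brute_force_pairs(calls, table, cfg)


def test_tolerance_monotonicity():
    table, _ = gen_exvivo_table(GeneratorConfig(seed=5))
    calls = classify_features(table)
    sets = []
    for tol in (1.0, 5.0, 20.0, 100.0):
        pairs = find_pairs(calls, table, PairingConfig(tol_ppm=tol, shifts=SHIFTS))
        sets.append({(p.substrate_feature_id, p.product_feature_id, p.shift_names)
                     for p in pairs})
    for smaller, larger in zip(sets, sets[1:]):
        assert smaller <= larger


def test_candidates_sorted_by_abs_ppm_error():
    table, _ = gen_exvivo_table(GeneratorConfig(seed=4))
    calls = classify_features(table)
    pairs = find_pairs(calls, table, PairingConfig(shifts=SHIFTS))
    errs = [abs(p.mass_error_ppm) for p in pairs]
    assert errs == sorted(errs)


@pytest.mark.parametrize(
    "aa,frag",
    [("Ile", 130.08735), ("Gln", 145.06186), ("Val", 116.07170)],
)
def test_expected_aa_fragment_matches_q3(aa, frag):
    shift = next(s for s in SHIFTS if s.name == aa)
    assert expected_aa_fragment(shift) == pytest.approx(frag, abs=1e-5)


def test_expected_fragment_rejects_hydroxylation():
    hydrox = next(s for s in SHIFTS if s.name == "hydroxylation")
    with pytest.raises(ConfigError):
        expected_aa_fragment(hydrox)


def test_msms_tristate():
    table = _table([209.11832, 322.20237])
    cfg = PairingConfig(shifts=SHIFTS)
    [pair] = find_pairs(_calls(table, {"f0"}, {"f1"}), table, cfg)
    with_frag = MsmsSpectrum(322.2024, ((59.0139, 40.0), (130.0874, 100.0)))
    without = MsmsSpectrum(322.2024, ((59.0139, 40.0),))
    assert msms_support(pair, with_frag, cfg, table) == "supported"
    assert msms_support(pair, without, cfg, table) == "contradicted"
    assert msms_support(pair, None, cfg, table) == "untested"
    [ann] = annotate_msms([pair], [with_frag], cfg, table)
    assert ann.msms_support == "supported"
    [ann] = annotate_msms([pair], [], cfg, table)
    assert ann.msms_support == "untested"
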