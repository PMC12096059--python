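"""Transition library, blank rule, quantification, and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from jaspipe.chem import PROTON_MASS, get_compound, ion_mz, monoisotopic_mass, nominal_mz
from jaspipe.errors import ConfigError, SchemaError
from jaspipe.quant import (
    QuantSample,
    blank_correct,
    compact_letter_display,
    default_library,
    filter_de_table,
    fold_change,
    group_stats,
    load_transition_library,
    quantify,
    ratio_of_means,
    two_sample_test,
)

IS_AMOUNTS = {"D5-JA": 1.0, "D5-OPDA": 1.0, "D3-JA-Leu": 1.0}


def test_default_library_contents():
    lib = default_library()
    assert len(lib) == 10
    assert (lib["JA-Ile"].q1_nominal, lib["JA-Ile"].q3_nominal) == (322, 130)
    assert (lib["JA"].q1_nominal, lib["JA"].q3_nominal) == (209, 59)
    assert lib["JA-Gln"].relative and lib["12-OH-JA-Ile"].relative
    assert lib["JA-Ile"].lod == {"flowers": 0.017, "leaves": 0.00085}


def test_library_q1_consistent_with_mass_core():
    """Every default Q1 equals the nominal [M-H]- of the registered compound."""
    for analyte, t in default_library().items():
        assert t.q1_nominal == nominal_mz(ion_mz(get_compound(analyte).formula))


def test_conjugate_q3_is_deprotonated_amino_acid():
    for analyte, aa in [("JA-Val", "Val"), ("JA-Ile", "Ile"), ("JA-Gln", "Gln"),
                        ("12-OH-JA-Ile", "Ile")]:
        frag = monoisotopic_mass(get_compound(aa).formula) - PROTON_MASS
        assert default_library()[analyte].q3_nominal == nominal_mz(frag)


def test_load_library_rejects_duplicates_and_missing_is():
    entry = {"analyte": "X", "q1_nominal": 200, "q3_nominal": 100,
             "internal_standard": "X"}
    with pytest.raises(ConfigError):
        load_transition_library([entry, entry])
    with pytest.raises(ConfigError):
        load_transition_library([{**entry, "internal_standard": "missing"}])


def _qs(sid, geno, signals, fw=0.1, matrix="flowers"):
    return QuantSample(sample_id=sid, genotype=geno, signals=signals,
                       fresh_weight=fw, matrix=matrix)


def test_blank_rule_arithmetic():
    blank = _qs("b", "aos", {"JA": (30.0, 3.0)})
    assert blank_correct(_qs("s", "wt", {"JA": (100.0, 10.0)}), [blank])["JA"]
    assert not blank_correct(_qs("s", "wt", {"JA": (80.0, 8.0)}), [blank])["JA"]
    zero_blank = _qs("b", "aos", {"JA": (0.0, 0.0)})
    assert blank_correct(_qs("s", "wt", {"JA": (1.0, 0.1)}), [zero_blank])["JA"]
    with pytest.raises(ConfigError):
        blank_correct(_qs("s", "wt", {}), [blank], k=0)
    with pytest.raises(SchemaError):
        blank_correct(_qs("s", "wt", {}), [])


def test_quantify_arithmetic_and_flags():
    lib = default_library()
    sample = _qs("s", "wt", {
        "JA": (1000.0, 100.0), "D5-JA": (1000.0, 100.0),
        "JA-Ile": (10.0, 1.0), "D3-JA-Leu": (500.0, 50.0),
        "JA-Gln": (250.0, 25.0),
    })
    blank = _qs("b", "aos", {"JA": (10.0, 1.0), "JA-Ile": (10.0, 1.0),
                             "JA-Gln": (10.0, 1.0)})
    results = {r.analyte: r for r in quantify(sample, lib, IS_AMOUNTS, blanks=[blank])}
    # area ratio 1.0 x 1 nmol / 0.1 g = 10 nmol/gFW
    assert results["JA"].amount == pytest.approx(10.0)
    assert results["JA"].flag == "quantified"
    # surrogate-normalized analyte: plain area ratio
    assert results["JA-Gln"].unit == "relative-response"
    assert results["JA-Gln"].amount == pytest.approx(0.25)
    # JA-Ile below the 3x blank height -> bdl with the flower-matrix LOD
    assert results["JA-Ile"].flag == "bdl"
    assert results["JA-Ile"].lod == 0.017


def test_bdl_lod_per_matrix():
    lib = default_library()
    sample = _qs("s", "wt", {"JA-Ile": (1.0, 0.1), "D3-JA-Leu": (500.0, 50.0)},
                 matrix="leaves")
    blank = _qs("b", "aos", {"JA-Ile": (10.0, 1.0)}, matrix="leaves")
    [r] = [x for x in quantify(sample, lib, IS_AMOUNTS, blanks=[blank])
           if x.analyte == "JA-Ile"]
    assert r.flag == "bdl" and r.lod == 0.00085


def test_zero_is_area_blank_fail():
    lib = default_library()
    sample = _qs("s", "wt", {"JA": (1000.0, 100.0), "D5-JA": (0.0, 0.0)})
    blank = _qs("b", "aos", {"JA": (1.0, 0.1)})
    [r] = [x for x in quantify(sample, lib, IS_AMOUNTS, blanks=[blank])
           if x.analyte == "JA"]
    assert r.flag == "blank-fail" and r.amount is None


def test_quantification_linearity():
    """Scaling areas by c scales amounts by c; scaling FW by c divides them."""
    lib = default_library()
    blank = _qs("b", "aos", {"JA": (1.0, 0.1)})

    def amount(scale_area=1.0, fw=0.1):
        s = _qs("s", "wt", {"JA": (scale_area * 1000.0, scale_area * 100.0),
                            "D5-JA": (1000.0, 100.0)}, fw=fw)
        return [r for r in quantify(s, lib, IS_AMOUNTS, blanks=[blank])
                if r.analyte == "JA"][0].amount

    base = amount()
    assert amount(scale_area=3.0) == pytest.approx(3 * base)
    assert amount(fw=0.3) == pytest.approx(base / 3)


# --- group statistics -------------------------------------------------------


def tukey_oracle_p(groups, i, j):
    """Direct studentized-range Tukey p for balanced one-way data."""
    k = len(groups)
    n = len(groups[0])
    df = sum(len(g) - 1 for g in groups)
    msw = np.mean([np.var(g, ddof=1) for g in groups])
    q = abs(np.mean(groups[i]) - np.mean(groups[j])) / np.sqrt(msw / n)
    return sps.studentized_range.sf(q, k, df)


def test_tukey_matches_studentized_range_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        k = rng.integers(3, 7)
        data = {f"g{i}": rng.normal(rng.uniform(0, 3), 1.0, 5) for i in range(k)}
        gs = group_stats(data)
        arrays = [data[g] for g in gs.groups]
        name_idx = {g: i for i, g in enumerate(gs.groups)}
        for row in gs.tukey.itertuples():
            oracle = tukey_oracle_p(arrays, name_idx[row.group1], name_idx[row.group2])
            assert row.p_value == pytest.approx(oracle, abs=2e-4)


def test_letters_three_separated_groups():
    rng = np.random.default_rng(1)
    data = {"low": rng.normal(0, 1, 4), "mid": rng.normal(100, 1, 4),
            "high": rng.normal(200, 1, 4)}
    gs = group_stats(data)
    letters = set(gs.letters.values())
    assert len(letters) == 3 and all(len(v) == 1 for v in gs.letters.values())


def test_letters_identical_groups_share():
    data = {"a": [5.0, 5.1, 4.9], "b": [5.0, 4.9, 5.1]}
    gs = group_stats(data)
    assert set(gs.letters["a"]) & set(gs.letters["b"])


def test_cld_property_random_instances():
    """Groups share a letter iff their pair is not significant (100 instances)."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        k = int(rng.integers(3, 7))
        names = [f"g{i}" for i in range(k)]
        sig = {frozenset(p) for p in
               [(names[i], names[j]) for i in range(k) for j in range(i + 1, k)
                if rng.random() < 0.4]}
        letters = compact_letter_display(names, sig)
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(set(letters[names[i]]) & set(letters[names[j]]))
                assert share == (frozenset((names[i], names[j])) not in sig)
        assert all(letters[n] for n in names)


def test_all_pairs_significant_distinct_letters():
    names = ["a", "b", "c", "d"]
    sig = {frozenset((x, y)) for x in names for y in names if x < y}
    letters = compact_letter_display(names, sig)
    assert len(set(letters.values())) == 4


def test_group_stats_rejects_degenerate():
    with pytest.raises(SchemaError):
        group_stats({"only": [1.0, 2.0]})
    with pytest.raises(SchemaError):
        group_stats({"a": [1.0], "b": [2.0, 3.0]})


def test_two_sample_is_students_t():
    a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 6.0]
    assert two_sample_test(a, b) == pytest.approx(
        sps.ttest_ind(a, b, equal_var=True).pvalue
    )


# --- fold change and DE filter ----------------------------------------------


def test_ratio_of_means_trivial():
    assert ratio_of_means([2.0, 2.0, 2.0], [1.0, 1.0, 1.0]) == pytest.approx(2.0)
    with pytest.raises(SchemaError):
        ratio_of_means([1.0], [0.0, 0.0])


def test_fold_change_excludes_bdl_and_flags_undefined():
    from jaspipe.quant import QuantResult

    results = [
        QuantResult("JA", "n1", 4.0, "nmol/gFW", "quantified"),
        QuantResult("JA", "n2", None, "nmol/gFW", "bdl"),
        QuantResult("JA", "d1", 2.0, "nmol/gFW", "quantified"),
        QuantResult("JA", "d2", 2.0, "nmol/gFW", "quantified"),
    ]
    group_of = {"n1": "mut", "n2": "mut", "d1": "wt", "d2": "wt"}
    fc = fold_change(results, group_of, "JA", "mut", "wt")
    assert fc.defined and fc.ratio == pytest.approx(2.0)
    assert fc.n_bdl_numerator == 1
    all_bdl = [QuantResult("JA", "d1", None, "nmol/gFW", "bdl")] + results[:2]
    fc2 = fold_change(all_bdl, group_of, "JA", "mut", "wt")
    assert not fc2.defined and fc2.ratio is None


def test_filter_de_table_boundaries():
    df = pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "log2fc": [2.0, 1.99, -2.0, 5.0],
        "p": [0.009, 0.001, 0.0099, 0.01],
    })
    up, down = filter_de_table(df)
    assert list(up["gene"]) == ["a"]  # inclusive >= 2, strict p < 0.01
    assert list(down["gene"]) == ["c"]
    empty_up, empty_down = filter_de_table(df.iloc[:0])
    assert len(empty_up) == 0 and len(empty_down) == 0


def test_filter_de_table_matches_bruteforce():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "gene": [f"g{i}" for i in range(500)],
        "log2fc": rng.uniform(-6, 6, 500),
        "p": rng.uniform(0, 0.05, 500),
    })
    up, down = filter_de_table(df)
    n_up = sum(1 for _, r in df.iterrows() if r.log2fc >= 2 and r.p < 0.01)
    n_down = sum(1 for _, r in df.iterrows() if r.log2fc <= -2 and r.p < 0.01)
    assert (len(up), len(down)) == (n_up, n_down)


def test_filter_de_table_rejects_malformed():
    df = pd.DataFrame({"gene": ["a"], "log2fc": [np.nan], "p": [0.5]})
    with pytest.raises(SchemaError, match="0"):
        filter_de_table(df)
    with pytest.raises(SchemaError):
        filter_de_table(pd.DataFrame({"gene": ["a"]}))
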