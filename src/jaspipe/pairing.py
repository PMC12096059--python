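"""Link substrate- and product-called features through amino-acid mass shifts.

A conjugation event shifts the precursor mass by mass(amino acid) - mass(H2O);
an optional +O shift covers hydroxylation (JA <-> 12-OH-JA).  Candidate pairs
are substrate x product feature combinations whose m/z difference matches a
shift within a ppm tolerance referenced to the product m/z.  Shifts with
identical delta formulas (Leu/Ile) are indistinguishable by mass and are
reported as one candidate carrying both names.

MS/MS validation checks product spectra for the deprotonated free amino acid,
which is the dominant negative-mode fragment of jasmonoyl-amido conjugates
(and the printed Q3 mass of the targeted transitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .chem import (
    PROTON_MASS,
    MassShift,
    WATER,
    amino_acid_compounds,
    build_shift_table,
    monoisotopic_mass,
)
from .errors import ConfigError, SchemaError
from .features import FeatureTable, MsmsSpectrum
from .screen import FeatureCall

__all__ = [
    "PairingConfig",
    "PairCandidate",
    "find_pairs",
    "expected_aa_fragment",
    "msms_support",
    "pairs_to_frame",
]


def _default_shifts() -> tuple:
    return tuple(build_shift_table(amino_acid_compounds(), include_hydroxylation=True))


@dataclass(frozen=True)
class PairingConfig:
    tol_ppm: float = 5.0
    shifts: tuple = field(default_factory=_default_shifts)
    require_same_ion_mode: bool = True
    fragment_tol_mz: float = 0.01

    def __post_init__(self):
        if not self.tol_ppm > 0:
            raise ConfigError(f"tol_ppm must be > 0, got {self.tol_ppm}")
        if not self.shifts:
            raise ConfigError("shift table must be non-empty")


@dataclass(frozen=True)
class PairCandidate:
    substrate_feature_id: str
    product_feature_id: str
    shift_names: tuple  # ambiguity preserved, e.g. ("Ile", "Leu")
    observed_delta: float
    expected_delta: float
    mass_error_ppm: float
    msms_support: str = "untested"  # supported | contradicted | untested


def _merged_shifts(shifts: Sequence[MassShift]) -> list[tuple[tuple, float]]:
    """Collapse identical-delta shifts into (sorted-name-tuple, delta) entries."""
    groups: dict = {}
    for s in shifts:
        key = s.delta_formula if s.delta_formula is not None else round(s.delta_mass, 6)
        names, _ = groups.get(key, ((), s.delta_mass))
        groups[key] = (tuple(sorted(set(names) | {s.name})), s.delta_mass)
    return sorted(groups.values(), key=lambda t: t[1])


def find_pairs(
    calls: Sequence[FeatureCall],
    table: FeatureTable,
    config: PairingConfig = PairingConfig(),
) -> list[PairCandidate]:
    """Candidate substrate->product links for every configured mass shift.

    For each substrate-called feature s and product-called feature p, a
    candidate is emitted iff |(mz_p - mz_s) - delta| <= tol_ppm * mz_p * 1e-6
    for some shift delta (and, by default, matching ion modes).  Candidates
    are sorted by absolute ppm error.
    """
    call_of = {c.feature_id: c.call for c in calls}
    unknown = set(call_of) - {f.feature_id for f in table.features}
    if unknown:
        raise SchemaError(f"calls reference unknown feature(s): {sorted(unknown)}")
    subs = [table.feature(fid) for fid, c in call_of.items() if c == "substrate"]
    prods = [table.feature(fid) for fid, c in call_of.items() if c == "product"]

    merged = _merged_shifts(config.shifts)
    out = []
    for s in subs:
        for p in prods:
            if config.require_same_ion_mode and s.ion_mode != p.ion_mode:
                continue
            observed = p.mz - s.mz
            tol = config.tol_ppm * p.mz * 1e-6
            for names, delta in merged:
                err = observed - delta
                if abs(err) <= tol:
                    out.append(
                        PairCandidate(
                            substrate_feature_id=s.feature_id,
                            product_feature_id=p.feature_id,
                            shift_names=names,
                            observed_delta=observed,
                            expected_delta=delta,
                            mass_error_ppm=err / p.mz * 1e6,
                        )
                    )
    out.sort(key=lambda c: (abs(c.mass_error_ppm), c.substrate_feature_id, c.product_feature_id))
    return out


def expected_aa_fragment(shift: MassShift) -> float:
    """Negative-mode m/z of the free deprotonated amino acid behind a shift."""
    if shift.delta_formula is None or shift.name == "hydroxylation":
        raise ConfigError(f"shift {shift.name!r} has no amino-acid fragment")
    aa_mass = monoisotopic_mass(shift.delta_formula + WATER)
    return aa_mass - PROTON_MASS


def msms_support(
    pair: PairCandidate,
    spectrum: Optional[MsmsSpectrum],
    config: PairingConfig,
    table: Optional[FeatureTable] = None,
) -> str:
    """Tri-state MS/MS check of a candidate against a product-ion spectrum.

    *supported* iff any peak lies within ``fragment_tol_mz`` of the expected
    deprotonated amino acid for any shift name of the pair; *contradicted* if
    a spectrum is present but no peak matches; *untested* with no spectrum.
    The spectrum precursor must match the product feature m/z (ppm tolerance).
    """
    if spectrum is None:
        return "untested"
    if table is not None:
        pmz = table.feature(pair.product_feature_id).mz
        if abs(spectrum.precursor_mz - pmz) > config.tol_ppm * pmz * 1e-6:
            raise SchemaError(
                f"spectrum precursor {spectrum.precursor_mz} does not match "
                f"product feature {pair.product_feature_id!r} at m/z {pmz}"
            )
    shift_by_name = {s.name: s for s in config.shifts}
    expected = []
    for name in pair.shift_names:
        shift = shift_by_name.get(name)
        if shift is None or shift.name == "hydroxylation" or shift.delta_formula is None:
            continue
        expected.append(expected_aa_fragment(shift))
    if not expected:
        return "untested"
    for frag_mz, _ in spectrum.peaks:
        if any(abs(frag_mz - e) <= config.fragment_tol_mz for e in expected):
            return "supported"
    return "contradicted"


def annotate_msms(
    pairs: Sequence[PairCandidate],
    spectra: Sequence[MsmsSpectrum],
    config: PairingConfig,
    table: FeatureTable,
) -> list[PairCandidate]:
    """Attach MS/MS support to each pair using the best-matching spectrum."""
    out = []
    for pair in pairs:
        pmz = table.feature(pair.product_feature_id).mz
        tol = config.tol_ppm * pmz * 1e-6
        matches = [sp for sp in spectra if abs(sp.precursor_mz - pmz) <= tol]
        if not matches:
            out.append(replace(pair, msms_support="untested"))
            continue
        best = min(matches, key=lambda sp: abs(sp.precursor_mz - pmz))
        out.append(replace(pair, msms_support=msms_support(pair, best, config, table)))
    return out


def pairs_to_frame(pairs) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "substrate_feature_id": [p.substrate_feature_id for p in pairs],
            "product_feature_id": [p.product_feature_id for p in pairs],
            "shift_names": ["|".join(p.shift_names) for p in pairs],
            "observed_delta": [p.observed_delta for p in pairs],
            "expected_delta": [p.expected_delta for p in pairs],
            "mass_error_ppm": [p.mass_error_ppm for p in pairs],
            "msms_support": [p.msms_support for p in pairs],
        }
    )
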