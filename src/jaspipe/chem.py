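"""Exact monoisotopic mass arithmetic for jasmonates and their amino-acid conjugates.

All m/z values downstream of this module — MRM transition masses, conjugate
pairing deltas, expected amino-acid fragments — reduce to additive arithmetic
over element counts.  Compound compositions are fixed once here, in a small
registry covering jasmonic acid (JA), its hydroxylated and didehydro
derivatives, OPDA, the 20 proteinogenic amino acids, the jasmonoyl-amido
conjugates, and the deuterated internal standards.

Conventions
-----------
* Masses are monoisotopic, in unified atomic mass units (u).
* Heavy isotopes are separate symbols: ``2H`` (deuterium), ``13C``, ``15N``.
* Ionization is restricted to singly (de)protonated ions; the charge carrier
  mass is the proton (1.007276 u), so ``[M-H]-`` = M - 1.007276.
* Nominal m/z rounds to the nearest integer, ties away from zero, which
  reproduces every printed MRM transition mass.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "PROTON_MASS",
    "HYDROXYLATION_DELTA",
    "ElementMassTable",
    "DEFAULT_MASS_TABLE",
    "MolecularFormula",
    "CompoundDef",
    "MassShift",
    "monoisotopic_mass",
    "condense",
    "ion_mz",
    "nominal_mz",
    "apply_isotope_label",
    "build_shift_table",
    "default_registry",
    "get_compound",
    "amino_acid_compounds",
    "WATER",
    "registry_to_json",
    "registry_from_json",
    "shift_table_to_json",
    "shift_table_from_json",
]

#: Mass of the charge carrier (proton) used for +/-H ionization.
PROTON_MASS = 1.007276

#: Mass added by a single hydroxylation (+O).
HYDROXYLATION_DELTA = 15.9949146196

# Light isotope behind each supported heavy-isotope label.
_LIGHT_OF = {"2H": "H", "13C": "C", "15N": "N"}


class ElementMassTable:
    """Immutable map from element/isotope symbol to monoisotopic mass (u)."""

    def __init__(self, entries: Mapping[str, float]):
        for sym, m in entries.items():
            if not (m > 0):
                raise ValueError(f"non-positive mass for symbol {sym!r}")
        if "H" in entries and "2H" in entries and not entries["2H"] > entries["H"]:
            raise ValueError("2H mass must exceed H mass")
        self._entries = MappingProxyType(dict(entries))

    @property
    def entries(self) -> Mapping[str, float]:
        return self._entries

    def mass(self, symbol: str) -> float:
        try:
            return self._entries[symbol]
        except KeyError:
            raise KeyError(f"unknown element or isotope symbol: {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._entries


#: CODATA/IUPAC monoisotopic masses for the elements and isotopes in play.
DEFAULT_MASS_TABLE = ElementMassTable(
    {
        "H": 1.00782503207,
        "C": 12.0,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "S": 31.97207100,
        "P": 30.97376163,
        "2H": 2.01410177785,
        "13C": 13.00335483507,
        "15N": 15.00010889888,
    }
)

_FORMULA_TOKEN = re.compile(r"\[(\d+[A-Z][a-z]?)\](\d*)|([A-Z][a-z]?)(\d*)|(\S)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element-count map; the sole argument of all mass arithmetic.

    Counts must be non-negative with at least one atom, and every symbol must
    exist in the mass table.  Instances are value objects: hashable, comparable
    by composition, and combinable with ``+`` and ``-`` (elementwise).
    """

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {s: int(c) for s, c in self.counts.items() if c != 0}
        for sym, c in clean.items():
            if c < 0:
                raise ValueError(f"negative count for {sym!r}")
            if sym not in DEFAULT_MASS_TABLE:
                raise KeyError(f"unknown element or isotope symbol: {sym!r}")
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", MappingProxyType(clean))

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse e.g. ``C12H18O3`` or ``C12H13[2H]5O3`` into a formula."""
        counts: dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(text.strip()):
            iso, iso_n, sym, sym_n, bad = m.groups()
            if bad is not None:
                raise ValueError(f"cannot parse formula {text!r} at {bad!r}")
            symbol = iso if iso is not None else sym
            n = int((iso_n if iso is not None else sym_n) or 1)
            counts[symbol] = counts.get(symbol, 0) + n
        return cls(counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for s, c in other.counts.items():
            counts[s] = counts.get(s, 0) + c
        return MolecularFormula(counts)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for s, c in other.counts.items():
            new = counts.get(s, 0) - c
            if new < 0:
                raise ValueError(
                    f"subtraction would give negative {s!r} count ({new})"
                )
            counts[s] = new
        return MolecularFormula(counts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __str__(self) -> str:
        def key(sym):  # Hill-ish deterministic order
            return (sym not in ("C", "13C"), sym not in ("H", "2H"), sym)

        parts = []
        for sym in sorted(self.counts, key=key):
            n = self.counts[sym]
            s = f"[{sym}]" if sym in _LIGHT_OF else sym
            parts.append(f"{s}{n if n != 1 else ''}")
        return "".join(parts)


WATER = MolecularFormula({"H": 2, "O": 1})


def monoisotopic_mass(
    formula: MolecularFormula, table: ElementMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Sum of count x element monoisotopic mass, exact additive arithmetic."""
    return sum(c * table.mass(s) for s, c in formula.counts.items())


def condense(
    substrate: MolecularFormula, amino_acid: MolecularFormula
) -> MolecularFormula:
    """Amide-bond condensation: elementwise sum minus one water.

    This is the reaction GH3 enzymes catalyse — conjugation of an acyl
    substrate (e.g. JA) to an amino acid with loss of H2O.
    """
    return (substrate + amino_acid) - WATER


def ion_mz(formula: MolecularFormula, mode: str = "negative") -> float:
    """Accurate m/z of the singly (de)protonated ion ([M-H]- or [M+H]+)."""
    m = monoisotopic_mass(formula)
    if mode == "negative":
        return m - PROTON_MASS
    if mode == "positive":
        return m + PROTON_MASS
    raise ValueError(f"ion mode must be 'negative' or 'positive', got {mode!r}")


def nominal_mz(accurate: float) -> int:
    """Nearest integer m/z, ties away from zero (matches printed transitions)."""
    if not accurate > 0:
        raise ValueError(f"m/z must be positive, got {accurate}")
    return int(math.floor(accurate + 0.5))


def apply_isotope_label(
    formula: MolecularFormula, count: int, isotope: str
) -> MolecularFormula:
    """Replace ``count`` light atoms by the heavy ``isotope`` (e.g. 5 x 2H)."""
    if isotope not in _LIGHT_OF:
        raise ValueError(f"unsupported isotope label {isotope!r}")
    light = _LIGHT_OF[isotope]
    available = formula.counts.get(light, 0)
    if count > available:
        raise ValueError(
            f"cannot label {count} x {isotope}: only {available} {light} available"
        )
    counts = dict(formula.counts)
    counts[light] = available - count
    counts[isotope] = counts.get(isotope, 0) + count
    return MolecularFormula(counts)


@dataclass(frozen=True)
class CompoundDef:
    """A named compound: formula, role, and optional isotope label.

    ``label`` is a (count, isotope) pair for internal standards; ``parents``
    records the constituent names for conjugates (acyl substrate, amino acid).
    """

    name: str
    formula: MolecularFormula
    role: str = "other"
    label: Optional[tuple[int, str]] = None
    parents: tuple[str, ...] = ()

    _ROLES = (
        "substrate-jasmonate",
        "amino-acid",
        "conjugate",
        "internal-standard",
        "other",
    )

    def __post_init__(self):
        if self.role not in self._ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "internal-standard" and self.label is None:
            raise ValueError(f"internal standard {self.name!r} must carry a label")
        if self.role == "conjugate" and not self.parents:
            raise ValueError(f"conjugate {self.name!r} must record parent names")


@dataclass(frozen=True)
class MassShift:
    """A mass delta linking substrate and product features.

    For an amino acid the delta is mass(amino acid) - mass(H2O), the
    condensation shift; ``ambiguous_with`` lists other shifts with an
    identical delta formula (Leu/Ile).  ``delta_formula`` is None only for
    shifts that are not a formula difference of the light kind (not used here).
    """

    name: str
    delta_mass: float
    delta_formula: Optional[MolecularFormula]
    ambiguous_with: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Compound registry
# ---------------------------------------------------------------------------

# Free proteinogenic amino acids (neutral molecules, not residues).
_AMINO_ACID_FORMULAS = {
    "Ala": "C3H7NO2",
    "Arg": "C6H14N4O2",
    "Asn": "C4H8N2O3",
    "Asp": "C4H7NO4",
    "Cys": "C3H7NO2S",
    "Glu": "C5H9NO4",
    "Gln": "C5H10N2O3",
    "Gly": "C2H5NO2",
    "His": "C6H9N3O2",
    "Ile": "C6H13NO2",
    "Leu": "C6H13NO2",
    "Lys": "C6H14N2O2",
    "Met": "C5H11NO2S",
    "Phe": "C9H11NO2",
    "Pro": "C5H9NO2",
    "Ser": "C3H7NO3",
    "Thr": "C4H9NO3",
    "Trp": "C11H12N2O2",
    "Tyr": "C9H11NO3",
    "Val": "C5H11NO2",
}

# Acyl substrates.  4,5-ddh-JA carries one additional double bond (JA - H2).
_JASMONATE_FORMULAS = {
    "JA": "C12H18O3",
    "12-OH-JA": "C12H18O4",
    "ddh-JA": "C12H16O3",
    "OPDA": "C18H28O3",
}

# Conjugates named in the study, as (acyl parent, amino acid).
_CONJUGATES = [
    ("JA", "Ile"),
    ("JA", "Leu"),
    ("JA", "Val"),
    ("JA", "Met"),
    ("JA", "Gln"),
    ("JA", "Asn"),
    ("JA", "Glu"),
    ("12-OH-JA", "Ile"),
    ("12-OH-JA", "Val"),
    ("ddh-JA", "Ile"),
]

# Deuterated internal standards: (base compound, n deuteriums).
_STANDARDS = {
    "D5-JA": ("JA", 5),
    "D5-OPDA": ("OPDA", 5),
    "D3-JA-Leu": ("JA-Leu", 3),
}


def _build_default_registry() -> dict[str, CompoundDef]:
    reg: dict[str, CompoundDef] = {}
    for name, f in _JASMONATE_FORMULAS.items():
        reg[name] = CompoundDef(name, MolecularFormula.parse(f), "substrate-jasmonate")
    for name, f in _AMINO_ACID_FORMULAS.items():
        reg[name] = CompoundDef(name, MolecularFormula.parse(f), "amino-acid")
    for parent, aa in _CONJUGATES:
        name = f"{parent}-{aa}"
        reg[name] = CompoundDef(
            name,
            condense(reg[parent].formula, reg[aa].formula),
            "conjugate",
            parents=(parent, aa),
        )
    for name, (base, n) in _STANDARDS.items():
        reg[name] = CompoundDef(
            name,
            apply_isotope_label(reg[base].formula, n, "2H"),
            "internal-standard",
            label=(n, "2H"),
            parents=(base,),
        )
    return reg


_DEFAULT_REGISTRY = _build_default_registry()


def default_registry() -> dict[str, CompoundDef]:
    """A fresh copy of the built-in compound registry."""
    return dict(_DEFAULT_REGISTRY)


def get_compound(name: str) -> CompoundDef:
    try:
        return _DEFAULT_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown compound {name!r}") from None


def amino_acid_compounds() -> list[CompoundDef]:
    """The 20 proteinogenic amino acids as supplied in the ex vivo buffer."""
    return [c for c in _DEFAULT_REGISTRY.values() if c.role == "amino-acid"]


def build_shift_table(
    amino_acids: Sequence[CompoundDef], include_hydroxylation: bool = False
) -> list[MassShift]:
    """One condensation shift per amino acid, cross-referenced for ambiguity.

    The delta of each shift is mass(amino acid) - mass(H2O); amino acids with
    identical molecular formulas (Leu and Ile) are mutually listed in
    ``ambiguous_with``.  With ``include_hydroxylation``, a +O shift is added,
    linking e.g. JA to 12-OH-JA and JA-Ile to 12-OH-JA-Ile.
    """
    if not amino_acids:
        raise ValueError("amino-acid set must be non-empty")
    names = [c.name for c in amino_acids]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate amino-acid names: {dupes}")

    by_formula: dict[MolecularFormula, list[str]] = {}
    for c in amino_acids:
        by_formula.setdefault(c.formula - WATER, []).append(c.name)

    shifts = []
    for c in amino_acids:
        delta_formula = c.formula - WATER
        twins = tuple(n for n in by_formula[delta_formula] if n != c.name)
        shifts.append(
            MassShift(
                name=c.name,
                delta_mass=monoisotopic_mass(c.formula) - monoisotopic_mass(WATER),
                delta_formula=delta_formula,
                ambiguous_with=twins,
            )
        )
    if include_hydroxylation:
        shifts.append(
            MassShift(
                name="hydroxylation",
                delta_mass=HYDROXYLATION_DELTA,
                delta_formula=MolecularFormula({"O": 1}),
            )
        )
    return shifts


# ---------------------------------------------------------------------------
# Serialization (JSON-compatible key-value config)
# ---------------------------------------------------------------------------


def registry_to_json(registry: Mapping[str, CompoundDef]) -> str:
    out = {}
    for name, c in registry.items():
        entry = {"formula": dict(c.formula.counts), "role": c.role}
        if c.label is not None:
            entry["label"] = {"count": c.label[0], "isotope": c.label[1]}
        if c.parents:
            entry["parents"] = list(c.parents)
        out[name] = entry
    return json.dumps(out, indent=1, sort_keys=True)


def registry_from_json(text: str) -> dict[str, CompoundDef]:
    raw = json.loads(text)
    reg = {}
    for name, entry in raw.items():
        label = entry.get("label")
        reg[name] = CompoundDef(
            name=name,
            formula=MolecularFormula(entry["formula"]),
            role=entry.get("role", "other"),
            label=(label["count"], label["isotope"]) if label else None,
            parents=tuple(entry.get("parents", ())),
        )
    return reg


def shift_table_to_json(shifts: Iterable[MassShift]) -> str:
    out = []
    for s in shifts:
        out.append(
            {
                "name": s.name,
                "delta_mass": s.delta_mass,
                "delta_formula": dict(s.delta_formula.counts)
                if s.delta_formula is not None
                else None,
                "ambiguous_with": list(s.ambiguous_with),
            }
        )
    return json.dumps(out, indent=1)


def shift_table_from_json(text: str) -> list[MassShift]:
    return [
        MassShift(
            name=e["name"],
            delta_mass=e["delta_mass"],
            delta_formula=MolecularFormula(e["delta_formula"])
            if e.get("delta_formula")
            else None,
            ambiguous_with=tuple(e.get("ambiguous_with", ())),
        )
        for e in json.loads(text)
    ]
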