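"""Data model and I/O for LC-MS feature tables, sample metadata, and MS/MS spectra.

The pipeline starts at an aligned feature table: one row per feature
(id, m/z, retention time, ion mode) and one intensity column per sample,
with sample annotations (condition, replicate, organ) in a separate
metadata table keyed by sample id.  Spectra are read from MGF.

Intensities are peak areas by default (``FeatureTable.intensity_kind``);
missing cells read as 0 and are flagged so downstream low-signal handling
can distinguish absent from measured-zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .errors import SchemaError

__all__ = [
    "SampleMeta",
    "Feature",
    "FeatureTable",
    "MsmsSpectrum",
    "read_feature_table",
    "write_feature_table",
    "read_sample_meta",
    "write_sample_meta",
    "read_msms",
]

_META_COLUMNS = ("feature_id", "mz", "rt", "ion_mode")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    replicate: int = 1
    organ: str = ""
    ion_mode: str = "negative"

    def __post_init__(self):
        if self.replicate < 1:
            raise SchemaError(f"replicate must be >= 1 for {self.sample_id!r}")


@dataclass(frozen=True)
class Feature:
    """One aligned LC-MS feature with per-sample intensities.

    ``missing`` lists sample ids whose cell was absent in the source file
    (stored as 0 in ``intensities``).
    """

    feature_id: str
    mz: float
    rt: float
    ion_mode: str = "negative"
    intensities: dict = field(default_factory=dict)
    missing: frozenset = frozenset()

    def __post_init__(self):
        if not self.mz > 0:
            raise SchemaError(f"feature {self.feature_id!r}: mz must be > 0")
        for sid, v in self.intensities.items():
            if v < 0:
                raise SchemaError(
                    f"feature {self.feature_id!r}: negative intensity in sample {sid!r}"
                )


@dataclass
class FeatureTable:
    samples: list[SampleMeta]
    features: list[Feature]
    intensity_kind: str = "area"  # "area" or "height"

    def __post_init__(self):
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise SchemaError("duplicate sample ids in metadata")
        fids = [f.feature_id for f in self.features]
        dupes = sorted({x for x in fids if fids.count(x) > 1})
        if dupes:
            raise SchemaError(f"duplicate feature id(s): {dupes}")
        sid_set = set(sids)
        for f in self.features:
            extra = set(f.intensities) - sid_set
            if extra:
                raise SchemaError(
                    f"feature {f.feature_id!r}: intensities for unknown sample(s) {sorted(extra)}"
                )
            gaps = sid_set - set(f.intensities)
            if gaps:  # pad with zeros, flagged as missing
                intens = dict(f.intensities)
                intens.update({s: 0.0 for s in gaps})
                object.__setattr__(f, "intensities", intens)
                object.__setattr__(f, "missing", f.missing | frozenset(gaps))

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_in_condition(self, condition: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition == condition]

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def intensity_matrix(self) -> pd.DataFrame:
        """Features x samples intensity matrix (index: feature_id)."""
        sids = self.sample_ids
        return pd.DataFrame(
            [[f.intensities[s] for s in sids] for f in self.features],
            index=[f.feature_id for f in self.features],
            columns=sids,
            dtype=float,
        )

    def feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(f"unknown feature {feature_id!r}")


@dataclass(frozen=True)
class MsmsSpectrum:
    precursor_mz: float
    peaks: tuple  # ((fragment m/z, relative intensity), ...) sorted by m/z

    def __post_init__(self):
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise SchemaError("negative peak intensity")
        object.__setattr__(self, "peaks", pk)


def _sniff_sep(path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"sample_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"sample metadata missing column(s): {sorted(missing)}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                condition=str(row["condition"]),
                replicate=int(row["replicate"]) if "replicate" in df.columns else 1,
                organ=str(row["organ"]) if "organ" in df.columns else "",
                ion_mode=str(row["ion_mode"]) if "ion_mode" in df.columns else "negative",
            )
        )
    return metas


def write_sample_meta(samples: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "condition": [s.condition for s in samples],
            "replicate": [s.replicate for s in samples],
            "organ": [s.organ for s in samples],
            "ion_mode": [s.ion_mode for s in samples],
        }
    ).to_csv(path, index=False)


def read_feature_table(
    path,
    samples: Optional[Sequence[SampleMeta]] = None,
    meta_path=None,
    intensity_kind: str = "area",
) -> FeatureTable:
    """Read a delimited (CSV/TSV, auto-detected) feature table.

    Columns ``feature_id``, ``mz``, ``rt`` are required (``ion_mode``
    optional); every remaining column is a sample and must be covered by the
    supplied sample metadata (``samples`` or ``meta_path``).  Row order is
    preserved.
    """
    if samples is None:
        if meta_path is None:
            raise SchemaError("sample metadata required (samples= or meta_path=)")
        samples = read_sample_meta(meta_path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise SchemaError(f"feature table missing required column {col!r}")
    known = set(_META_COLUMNS)
    sample_cols = [c for c in df.columns if c not in known]
    meta_ids = {s.sample_id for s in samples}
    unknown = set(sample_cols) - meta_ids
    if unknown:
        raise SchemaError(f"intensity column(s) without sample metadata: {sorted(unknown)}")

    features = []
    for i, row in df.iterrows():
        intens, missing = {}, set()
        for sid in sample_cols:
            v = row[sid]
            if pd.isna(v):
                intens[sid] = 0.0
                missing.add(sid)
            else:
                v = float(v)
                if v < 0:
                    raise SchemaError(
                        f"negative intensity at row {i}, column {sid!r}"
                    )
                intens[sid] = v
        features.append(
            Feature(
                feature_id=str(row["feature_id"]),
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                ion_mode=str(row["ion_mode"]) if "ion_mode" in df.columns else "negative",
                intensities=intens,
                missing=frozenset(missing),
            )
        )
    used = [s for s in samples if s.sample_id in sample_cols] or list(samples)
    return FeatureTable(samples=used, features=features, intensity_kind=intensity_kind)


def write_feature_table(table: FeatureTable, path) -> None:
    """Lossless inverse of :func:`read_feature_table`; deterministic columns."""
    sids = table.sample_ids
    rows = []
    for f in table.features:
        row = {
            "feature_id": f.feature_id,
            "mz": repr(f.mz),
            "rt": repr(f.rt),
            "ion_mode": f.ion_mode,
        }
        for s in sids:
            row[s] = repr(f.intensities[s])
        rows.append(row)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(_META_COLUMNS) + sids)
        writer.writeheader()
        writer.writerows(rows)


def read_msms(path) -> list[MsmsSpectrum]:
    """Read MGF spectra (BEGIN/END IONS blocks with PEPMASS), peaks sorted."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec.get("params", {})
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise SchemaError(f"MGF block {i}: missing PEPMASS")
            peaks = tuple(zip(spec["m/z array"], spec["intensity array"]))
            spectra.append(
                MsmsSpectrum(precursor_mz=float(params["pepmass"][0]), peaks=peaks)
            )
    return spectra
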