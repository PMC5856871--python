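"""Tabular readers/writers for deconvolution exports and sample metadata.

Feature tables on disk follow the common deconvolution-export layout:
one row per feature, m/z and retention-time columns plus one intensity
column per sample. Internally the matrix is transposed to samples x
features. Column names are configurable through :class:`ColumnMapping`
because vendor exports disagree on header vocabulary.
"""

from __future__ import annotations

import fnmatch
import io as _io
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .model import FeatureMatrix, FeatureRecord, SampleRecord, SampleType, validate_samples

#: Strings treated as MISSING when reading intensity cells.
DEFAULT_MISSING_SENTINELS = ("", "NA", "N/A", "NaN", "nan", "NULL")

#: Default vocabulary for parsing sample_type values (lower-cased keys).
DEFAULT_TYPE_VOCABULARY = {
    "qc": SampleType.QC,
    "pool": SampleType.QC,
    "pooled": SampleType.QC,
    "blank": SampleType.BLANK,
}


@dataclass
class ColumnMapping:
    """Maps a feature-table file's columns onto the data model.

    ``intensity_columns`` may be an explicit list of column names, a glob
    pattern (e.g. ``"sample_*"``), or None meaning "every column not used
    as feature metadata".

    ``zeros_as_missing`` controls whether a literal 0 intensity is read as
    MISSING (the default: most deconvolution tools emit 0 for undetected
    features) or kept as a measured zero.
    """

    mz: str = "mz"
    rt: str = "rt"
    drift: str | None = None
    id: str | None = None
    intensity_columns: Sequence[str] | str | None = None
    missing_sentinels: Sequence[str] = field(default=DEFAULT_MISSING_SENTINELS)
    zeros_as_missing: bool = True

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ColumnMapping":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown column-mapping keys: {sorted(unknown)}")
        return cls(**raw)


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read CSV/TSV keeping cells as strings (missingness handled by us)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"duplicate column names: {dups}")
    return df


def _synthesize_feature_id(mz: float, rt: float, used: set[str]) -> str:
    base = f"M{mz:.4f}T{rt:.1f}"
    fid, k = base, 1
    while fid in used:
        k += 1
        fid = f"{base}_{k}"
    return fid


def read_feature_table(
    path: str | os.PathLike, mapping: ColumnMapping | None = None
) -> tuple[FeatureMatrix, list[FeatureRecord]]:
    """Read a features x samples CSV/TSV into a samples x features matrix.

    Empty cells and configured sentinel strings become MISSING; zeros become
    MISSING too when ``mapping.zeros_as_missing`` is set. When no id column
    is mapped, feature ids are synthesized as ``M<mz>T<rt>``.
    """
    mapping = mapping or ColumnMapping()
    df = _read_table(path)
    if mapping.id is None and "feature_id" in df.columns:
        # our own export layout: pick the id column up automatically
        mapping = replace(mapping, id="feature_id")
    if mapping.drift is None and "drift_time" in df.columns:
        mapping = replace(mapping, drift="drift_time")

    meta_cols = [mapping.mz, mapping.rt]
    if mapping.drift:
        meta_cols.append(mapping.drift)
    if mapping.id:
        meta_cols.append(mapping.id)
    for col in meta_cols:
        if col not in df.columns:
            raise FormatError(f"mapped column {col!r} not found in {path}")

    if mapping.intensity_columns is None:
        sample_cols = [c for c in df.columns if c not in meta_cols]
    elif isinstance(mapping.intensity_columns, str):
        sample_cols = [
            c for c in df.columns
            if c not in meta_cols and fnmatch.fnmatch(c, mapping.intensity_columns)
        ]
    else:
        sample_cols = list(mapping.intensity_columns)
        absent = [c for c in sample_cols if c not in df.columns]
        if absent:
            raise FormatError(f"intensity columns not found: {absent}")
    if not sample_cols:
        raise FormatError("no intensity columns identified by the mapping")

    sentinels = set(mapping.missing_sentinels)
    n_feat = len(df)
    intensities = np.full((len(sample_cols), n_feat), np.nan)
    for j, col in enumerate(sample_cols):
        raw = df[col].to_numpy()
        for i, cell in enumerate(raw):
            cell = cell.strip()
            if cell in sentinels:
                continue
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric intensity {cell!r} in column {col!r}, row {i}"
                ) from None
            if np.isnan(v):
                continue
            if v < 0:
                raise ValidationError(
                    f"negative intensity {v} in column {col!r}, row {i}"
                )
            if v == 0 and mapping.zeros_as_missing:
                continue
            intensities[j, i] = v

    features: list[FeatureRecord] = []
    used: set[str] = set()
    for i in range(n_feat):
        try:
            mz = float(df[mapping.mz].iloc[i])
            rt = float(df[mapping.rt].iloc[i])
        except ValueError as exc:
            raise FormatError(f"non-numeric m/z or RT in row {i}: {exc}") from None
        drift = None
        if mapping.drift:
            cell = df[mapping.drift].iloc[i].strip()
            drift = float(cell) if cell not in sentinels else None
        if mapping.id:
            fid = df[mapping.id].iloc[i]
            if fid in used:
                raise ValidationError(f"duplicate feature id {fid!r}")
        else:
            fid = _synthesize_feature_id(mz, rt, used)
        used.add(fid)
        features.append(FeatureRecord(feature_id=fid, mz=mz, rt=rt, drift_time=drift))

    matrix = FeatureMatrix(
        pd.DataFrame(
            intensities, index=sample_cols, columns=[f.feature_id for f in features]
        )
    )
    return matrix, features


def write_feature_table(
    matrix: FeatureMatrix,
    features: Sequence[FeatureRecord],
    path: str | os.PathLike,
) -> None:
    """Write features as rows (id, mz, rt[, drift], one column per sample).

    MISSING cells are written as empty fields. Float formatting uses
    ``repr`` so a read→write→read round trip is exact.
    """
    by_id = {f.feature_id: f for f in features}
    absent = [fid for fid in matrix.feature_ids if fid not in by_id]
    if absent:
        raise ValidationError(f"no FeatureRecord for features: {absent[:5]}")
    has_drift = any(by_id[fid].drift_time is not None for fid in matrix.feature_ids)

    sep = "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","
    vals = matrix.values  # samples x features
    buf = _io.StringIO()
    header = ["feature_id", "mz", "rt"] + (["drift_time"] if has_drift else [])
    header += matrix.sample_ids
    buf.write(sep.join(header) + "\n")
    for j, fid in enumerate(matrix.feature_ids):
        rec = by_id[fid]
        row = [fid, repr(float(rec.mz)), repr(float(rec.rt))]
        if has_drift:
            row.append("" if rec.drift_time is None else repr(float(rec.drift_time)))
        for i in range(len(matrix.sample_ids)):
            v = float(vals[i, j])
            row.append("" if np.isnan(v) else repr(v))
        buf.write(sep.join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_sample_metadata(
    path: str | os.PathLike,
    type_vocabulary: dict[str, SampleType] | None = None,
) -> list[SampleRecord]:
    """Read sample metadata (sample_id, sample_type, batch, injection_order
    [, class]).

    ``sample_type`` is parsed case-insensitively: qc/pool(ed) → QC,
    blank → BLANK, anything else → STUDY. The vocabulary can be extended or
    overridden (keys lower-case).
    """
    vocab = dict(DEFAULT_TYPE_VOCABULARY)
    if type_vocabulary:
        vocab.update({k.lower(): v for k, v in type_vocabulary.items()})
    df = _read_table(path)
    required = ["sample_id", "sample_type", "batch", "injection_order"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"sample metadata is missing column {col!r}")
    records = []
    for i, row in df.iterrows():
        stype = vocab.get(row["sample_type"].strip().lower(), SampleType.STUDY)
        try:
            order = int(row["injection_order"])
        except ValueError:
            raise FormatError(
                f"non-integer injection_order {row['injection_order']!r} in row {i}"
            ) from None
        label = row.get("class", "") or None
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                sample_type=stype,
                batch=row["batch"],
                injection_order=order,
                class_label=label,
            )
        )
    validate_samples(records)
    return records


def write_sample_metadata(
    samples: Sequence[SampleRecord], path: str | os.PathLike
) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","
    with open(path, "w") as fh:
        fh.write(sep.join(["sample_id", "sample_type", "batch", "injection_order", "class"]) + "\n")
        for s in samples:
            fh.write(
                sep.join(
                    [
                        s.sample_id,
                        s.sample_type.value,
                        str(s.batch),
                        str(s.injection_order),
                        s.class_label or "",
                    ]
                )
                + "\n"
            )
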