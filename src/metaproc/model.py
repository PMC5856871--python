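"""Shared data model: the intensity matrix, sample/feature metadata and
per-stage reports.

The central object is :class:`FeatureMatrix`, a samples x features table of
non-negative intensities with an explicit missing-value marker (NaN in
memory, an empty field on disk). A stored zero is a real measured zero and
is distinct from MISSING. All pipeline stages consume a matrix and return a
*new* one; nothing mutates its input.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: In-memory missing-value marker. Distinguishable from a stored 0.
MISSING = float("nan")


class SampleType(Enum):
    """Role a sample plays in the run."""

    STUDY = "study"
    QC = "qc"
    BLANK = "blank"


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata driving filtering, PQN references and drift
    correction.

    Parameters
    ----------
    sample_id
        Unique identifier, matching a row of the :class:`FeatureMatrix`.
    sample_type
        STUDY, QC (pooled quality control) or BLANK.
    batch
        Analytical block identifier.
    injection_order
        1-based position in the acquisition sequence; unique within a run.
    class_label
        Optional biological class (free text).
    """

    sample_id: str
    sample_type: SampleType
    batch: str = "1"
    injection_order: int = 0
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.injection_order < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: injection_order must be positive, "
                f"got {self.injection_order}"
            )


@dataclass(frozen=True)
class FeatureRecord:
    """Per-feature descriptors: the key for accurate-mass annotation.

    ``mz`` is the mass-to-charge ratio in Da/charge, ``rt`` the retention
    time in seconds, ``drift_time`` an optional ion-mobility drift time in
    milliseconds.
    """

    feature_id: str
    mz: float
    rt: float = 0.0
    drift_time: float | None = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(
                f"feature {self.feature_id!r}: mz must be > 0, got {self.mz}"
            )
        if self.rt < 0:
            raise ValidationError(
                f"feature {self.feature_id!r}: rt must be >= 0, got {self.rt}"
            )


def validate_samples(samples: Sequence[SampleRecord]) -> None:
    """Check run-level invariants: unique sample ids and injection orders."""
    seen_ids: set[str] = set()
    seen_orders: set[int] = set()
    for rec in samples:
        if rec.sample_id in seen_ids:
            raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
        seen_ids.add(rec.sample_id)
        if rec.injection_order in seen_orders:
            raise ValidationError(
                f"duplicate injection_order {rec.injection_order} "
                f"(sample {rec.sample_id!r})"
            )
        seen_orders.add(rec.injection_order)


def sample_ids_of_type(
    samples: Iterable[SampleRecord], sample_type: SampleType
) -> list[str]:
    return [s.sample_id for s in samples if s.sample_type is sample_type]


class FeatureMatrix:
    """Samples x features intensity matrix with NaN as the missing marker.

    Wraps a float :class:`pandas.DataFrame` (rows = samples, columns =
    features). The object is treated as immutable: every transformation
    returns a new matrix. Construction validates uniqueness of ids and that
    every non-missing intensity is finite and >= 0.
    """

    def __init__(self, data: pd.DataFrame, *, copy: bool = True):
        if data.shape[0] == 0:
            raise ValidationError("feature matrix must have at least one sample")
        # zero features is permitted: a filter may legitimately remove them all
        if data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in feature matrix")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate feature ids in feature matrix")
        values = data.to_numpy(dtype=float, copy=copy)
        with np.errstate(invalid="ignore"):
            bad = np.isinf(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "intensities must be finite and >= 0; offending cell "
                f"(sample {data.index[i]!r}, feature {data.columns[j]!r}) = "
                f"{values[i, j]}"
            )
        self._data = pd.DataFrame(
            values, index=data.index.astype(str), columns=data.columns.astype(str)
        )

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """The underlying DataFrame. Treat as read-only."""
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def values(self) -> np.ndarray:
        """A *copy* of the intensity array (samples x features)."""
        return self._data.to_numpy(dtype=float, copy=True)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the cell is MISSING."""
        return self._data.isna().to_numpy()

    def n_missing(self) -> int:
        return int(self._data.isna().to_numpy().sum())

    # -- derivation helpers (all return new matrices) ----------------------
    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """New matrix with the same ids and the given intensity array."""
        if values.shape != self._data.shape:
            raise ValidationError(
                f"shape mismatch: {values.shape} vs {self._data.shape}"
            )
        return FeatureMatrix(
            pd.DataFrame(values, index=self._data.index, columns=self._data.columns)
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        missing = [s for s in sample_ids if s not in self._data.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return FeatureMatrix(self._data.loc[list(sample_ids)])

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        missing = [f for f in feature_ids if f not in self._data.columns]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing}")
        return FeatureMatrix(self._data[list(feature_ids)])

    def drop_features(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        drop = set(feature_ids)
        keep = [f for f in self.feature_ids if f not in drop]
        return self.select_features(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        if self.sample_ids != other.sample_ids or self.feature_ids != other.feature_ids:
            return False
        a, b = self.values, other.values
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())

    def __repr__(self) -> str:
        n_s, n_f = self.shape
        return f"FeatureMatrix({n_s} samples x {n_f} features, {self.n_missing()} missing)"


@dataclass
class StageReport:
    """Machine-readable record of what one stage did.

    For filtering stages ``n_features_out`` always equals
    ``n_features_in - len(removed_feature_ids)``.
    """

    stage_name: str
    parameters: dict = field(default_factory=dict)
    n_features_in: int = 0
    n_features_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed_feature_ids: list = field(default_factory=list)
    per_feature_metrics: dict | None = None
    per_sample_metrics: dict | None = None
    extra: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def __post_init__(self) -> None:
        if self.removed_feature_ids and (
            self.n_features_out != self.n_features_in - len(self.removed_feature_ids)
        ):
            raise ValidationError(
                f"stage {self.stage_name!r}: feature counts inconsistent with "
                "removed_feature_ids"
            )

    def to_dict(self, *, include_timestamp: bool = True) -> dict:
        d: dict = {
            "stage_name": self.stage_name,
            "parameters": _jsonable(self.parameters),
            "n_features_in": self.n_features_in,
            "n_features_out": self.n_features_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "removed_feature_ids": list(self.removed_feature_ids),
        }
        if self.per_feature_metrics is not None:
            d["per_feature_metrics"] = _jsonable(self.per_feature_metrics)
        if self.per_sample_metrics is not None:
            d["per_sample_metrics"] = _jsonable(self.per_sample_metrics)
        if self.extra:
            d["extra"] = _jsonable(self.extra)
        if include_timestamp:
            d["timestamp"] = self.timestamp
        return d


def _jsonable(obj):
    """Convert numpy scalars / NaN to JSON-safe plain Python values."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj
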