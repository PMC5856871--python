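"""Sample-wise normalization: probabilistic quotient (PQN) and sum.

PQN estimates a per-sample dilution factor as the median of the quotients
between the sample's intensities and a reference spectrum (the per-feature
median over the QCs or over all samples), then divides the sample by that
factor. Sum normalization rescales each sample so its non-missing
intensities total 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ComputationError, ConfigurationError
from .model import (
    FeatureMatrix,
    SampleRecord,
    SampleType,
    StageReport,
    sample_ids_of_type,
)


@dataclass
class ReferenceSpectrum:
    """Per-feature median intensity over the reference sample set."""

    feature_ids: list[str]
    values: np.ndarray
    source: Literal["qc", "all"]

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.values):
            raise ComputationError("reference spectrum length mismatch")

    @property
    def zero_feature_ids(self) -> list[str]:
        """Features whose reference value is 0 (carry no dilution signal)."""
        return [f for f, v in zip(self.feature_ids, self.values) if v == 0]


def compute_reference_spectrum(
    matrix: FeatureMatrix,
    samples: Sequence[SampleRecord] | None = None,
    source: Literal["qc", "all"] = "all",
) -> ReferenceSpectrum:
    """Median of each feature over the QCs (``source="qc"``) or all samples.

    Medians are taken over non-missing values; an even count uses the mean
    of the two middle order statistics. A feature missing in every reference
    sample gets reference value 0 (and is excluded from quotient lists).
    """
    if source == "qc":
        if samples is None:
            raise ConfigurationError("QC reference requires sample metadata")
        qc_ids = [
            s for s in sample_ids_of_type(samples, SampleType.QC)
            if s in set(matrix.sample_ids)
        ]
        if not qc_ids:
            raise ConfigurationError(
                "QC-based reference requested but the run has no QC samples"
            )
        ref_matrix = matrix.select_samples(qc_ids)
    else:
        ref_matrix = matrix
    vals = ref_matrix.values
    with np.errstate(all="ignore"):
        med = np.nanmedian(vals, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    return ReferenceSpectrum(
        feature_ids=list(matrix.feature_ids), values=med, source=source
    )


def normalize_pqn(
    matrix: FeatureMatrix, reference: ReferenceSpectrum
) -> tuple[FeatureMatrix, StageReport]:
    """Probabilistic quotient normalization against a reference spectrum.

    For each sample, quotients q_f = x_f / ref_f over features with
    ref_f > 0 and x_f observed; the dilution factor d is median(q_f) and the
    whole sample (including zero-reference features) is divided by d.
    MISSING cells stay MISSING.
    """
    if reference.feature_ids != matrix.feature_ids:
        raise ComputationError("reference spectrum is not aligned to the matrix features")
    ref = np.asarray(reference.values, dtype=float)
    if not (ref > 0).any():
        raise ComputationError("all reference values are 0; PQN is undefined")
    vals = matrix.values
    usable = ref > 0
    dilution: dict[str, float] = {}
    out = vals.copy()
    for i, sid in enumerate(matrix.sample_ids):
        row = vals[i, :]
        q_mask = usable & ~np.isnan(row)
        if not q_mask.any():
            raise ComputationError(
                f"sample {sid!r} has no usable quotients (all features missing "
                "or zero-reference)"
            )
        d = float(np.median(row[q_mask] / ref[q_mask]))
        if d <= 0:
            raise ComputationError(f"sample {sid!r} has non-positive dilution factor {d}")
        out[i, :] = row / d
        dilution[sid] = d
    report = StageReport(
        stage_name="normalize_pqn",
        parameters={"reference_source": reference.source},
        n_features_in=matrix.shape[1],
        n_features_out=matrix.shape[1],
        n_samples_in=matrix.shape[0],
        n_samples_out=matrix.shape[0],
        per_sample_metrics={s: {"dilution_factor": d} for s, d in dilution.items()},
        extra={"n_zero_reference_features": len(reference.zero_feature_ids)},
    )
    return matrix.with_values(out), report


def normalize_sum(matrix: FeatureMatrix) -> tuple[FeatureMatrix, StageReport]:
    """Divide each sample by its non-missing total and multiply by 100."""
    vals = matrix.values
    totals = np.nansum(vals, axis=1)
    zero = [sid for sid, t in zip(matrix.sample_ids, totals) if t <= 0]
    if zero:
        raise ComputationError(
            f"samples with non-positive total intensity cannot be sum-normalized: {zero}"
        )
    out = 100.0 * vals / totals[:, None]
    report = StageReport(
        stage_name="normalize_sum",
        parameters={},
        n_features_in=matrix.shape[1],
        n_features_out=matrix.shape[1],
        n_samples_in=matrix.shape[0],
        n_samples_out=matrix.shape[0],
        per_sample_metrics={
            s: {"total_intensity": float(t)} for s, t in zip(matrix.sample_ids, totals)
        },
    )
    return matrix.with_values(out), report
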