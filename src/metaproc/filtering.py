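"""Feature filtering on QC stability, blank background and missingness.

Pooled QC samples are injected periodically and, under stable instrument
performance, should contain every signal present in the study samples.
Features that are missing in more than a threshold percentage of QCs, or
whose relative standard deviation (RSD) across the QCs exceeds a threshold,
are therefore inconsistently detected — unstable metabolites or
contaminants — and are deleted. When no QCs are available, blanks provide
an alternative: a feature is kept only when its average study intensity
exceeds its average blank intensity by a user-chosen fold factor, and when
it is not missing in too many study samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, ParameterError
from .model import (
    FeatureMatrix,
    SampleRecord,
    SampleType,
    StageReport,
    sample_ids_of_type,
)

#: Marker for an RSD that cannot be computed (< 2 observations or mean 0).
RSD_UNDEFINED = float("nan")


@dataclass
class QcFilterParams:
    """Thresholds for QC-based filtering.

    A feature is deleted when its missing fraction across QCs is strictly
    above ``max_qc_missing_pct`` (default 50) or its QC RSD is strictly
    above ``max_qc_rsd_pct`` (default 20); boundary values are retained.
    ``qc_rule`` switches between treating the two criteria as independent
    deletion rules ("or", the default) or as a conjunction ("and").
    """

    max_qc_missing_pct: float = 50.0
    max_qc_rsd_pct: float = 20.0
    qc_rule: Literal["or", "and"] = "or"

    def __post_init__(self) -> None:
        if not 0 <= self.max_qc_missing_pct <= 100:
            raise ParameterError("max_qc_missing_pct must be in [0, 100]")
        if not self.max_qc_rsd_pct > 0:
            raise ParameterError("max_qc_rsd_pct must be > 0")
        if self.qc_rule not in ("or", "and"):
            raise ParameterError("qc_rule must be 'or' or 'and'")


@dataclass
class BlankFilterParams:
    """Thresholds for blank-based filtering.

    Retain a feature iff mean(study) > ``fold_factor`` x mean(blank) and its
    missing percentage among study samples is <= ``max_sample_missing_pct``.
    ``scope`` controls which samples count for the missingness rule.
    """

    fold_factor: float = 3.0
    max_sample_missing_pct: float = 50.0
    scope: Literal["study", "study+qc"] = "study"

    def __post_init__(self) -> None:
        if not self.fold_factor > 0:
            raise ParameterError("fold_factor must be > 0")
        if not 0 <= self.max_sample_missing_pct <= 100:
            raise ParameterError("max_sample_missing_pct must be in [0, 100]")


def feature_rsd(matrix: FeatureMatrix, subset: Sequence[str]) -> dict[str, float]:
    """Per-feature RSD% over a subset of samples, ignoring MISSING cells.

    RSD% = 100 * sample standard deviation / mean (ddof=1). Features with
    fewer than two observations or zero mean map to :data:`RSD_UNDEFINED`.
    """
    if len(subset) == 0:
        raise ParameterError("feature_rsd: subset of samples must be non-empty")
    sub = matrix.select_samples(list(subset))
    vals = sub.values
    out: dict[str, float] = {}
    for j, fid in enumerate(sub.feature_ids):
        col = vals[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            out[fid] = RSD_UNDEFINED
            continue
        mean = obs.mean()
        if mean == 0:
            out[fid] = RSD_UNDEFINED
            continue
        out[fid] = float(100.0 * obs.std(ddof=1) / mean)
    return out


def filter_by_qc(
    matrix: FeatureMatrix,
    samples: Sequence[SampleRecord],
    params: QcFilterParams | None = None,
) -> tuple[FeatureMatrix, StageReport]:
    """Delete features that are inconsistently detected across the QCs.

    Deletion criteria (strict inequalities; see :class:`QcFilterParams`):
    missing in more than ``max_qc_missing_pct`` % of QCs; QC RSD above
    ``max_qc_rsd_pct`` % (an undefined RSD counts as failing — a feature
    observed in at most one QC is by construction inconsistently detected).
    """
    params = params or QcFilterParams()
    qc_ids = sample_ids_of_type(samples, SampleType.QC)
    qc_ids = [s for s in qc_ids if s in set(matrix.sample_ids)]
    if not qc_ids:
        raise ConfigurationError(
            "QC-based filtering needs at least one QC sample; for runs without "
            "QCs use blank-based filtering (filter_by_blank)"
        )
    qc = matrix.select_samples(qc_ids)
    n_qc = len(qc_ids)
    miss_pct = 100.0 * qc.missing_mask.sum(axis=0) / n_qc
    rsd = feature_rsd(matrix, qc_ids)

    removed: list[str] = []
    metrics: dict[str, dict] = {}
    for j, fid in enumerate(matrix.feature_ids):
        r = rsd[fid]
        fail_missing = miss_pct[j] > params.max_qc_missing_pct
        fail_rsd = np.isnan(r) or r > params.max_qc_rsd_pct
        delete = (fail_missing and fail_rsd) if params.qc_rule == "and" \
            else (fail_missing or fail_rsd)
        if delete:
            removed.append(fid)
        metrics[fid] = {"qc_missing_pct": float(miss_pct[j]), "qc_rsd_pct": r}

    out = matrix.drop_features(removed) if removed else matrix
    report = StageReport(
        stage_name="qc_filter",
        parameters={
            "max_qc_missing_pct": params.max_qc_missing_pct,
            "max_qc_rsd_pct": params.max_qc_rsd_pct,
            "qc_rule": params.qc_rule,
            "n_qc_samples": n_qc,
        },
        n_features_in=len(matrix.feature_ids),
        n_features_out=len(out.feature_ids),
        n_samples_in=len(matrix.sample_ids),
        n_samples_out=len(out.sample_ids),
        removed_feature_ids=removed,
        per_feature_metrics=metrics,
    )
    return out, report


def filter_by_blank(
    matrix: FeatureMatrix,
    samples: Sequence[SampleRecord],
    params: BlankFilterParams | None = None,
) -> tuple[FeatureMatrix, StageReport]:
    """Retain features above blank background and detected in enough samples.

    A feature is retained iff mean(study, non-missing) is strictly greater
    than ``fold_factor`` x mean(blank, non-missing) AND its missing
    percentage among the scoped samples is <= ``max_sample_missing_pct``.
    A feature entirely missing in blanks has blank mean 0 and always passes
    the fold test (provided it is observed in at least one study sample).
    """
    params = params or BlankFilterParams()
    present = set(matrix.sample_ids)
    blank_ids = [s for s in sample_ids_of_type(samples, SampleType.BLANK) if s in present]
    study_ids = [s for s in sample_ids_of_type(samples, SampleType.STUDY) if s in present]
    if not blank_ids:
        raise ConfigurationError("blank-based filtering needs at least one BLANK sample")
    if not study_ids:
        raise ConfigurationError("blank-based filtering needs at least one STUDY sample")
    scope_ids = list(study_ids)
    if params.scope == "study+qc":
        scope_ids += [s for s in sample_ids_of_type(samples, SampleType.QC) if s in present]

    study = matrix.select_samples(study_ids).values
    blank = matrix.select_samples(blank_ids).values
    scoped = matrix.select_samples(scope_ids).values

    removed: list[str] = []
    metrics: dict[str, dict] = {}
    for j, fid in enumerate(matrix.feature_ids):
        s_obs = study[:, j][~np.isnan(study[:, j])]
        b_obs = blank[:, j][~np.isnan(blank[:, j])]
        study_mean = float(s_obs.mean()) if s_obs.size else 0.0
        blank_mean = float(b_obs.mean()) if b_obs.size else 0.0
        miss_pct = 100.0 * np.isnan(scoped[:, j]).sum() / scoped.shape[0]
        keep = (study_mean > params.fold_factor * blank_mean) and (
            miss_pct <= params.max_sample_missing_pct
        )
        if not keep:
            removed.append(fid)
        metrics[fid] = {
            "study_mean": study_mean,
            "blank_mean": blank_mean,
            "sample_missing_pct": float(miss_pct),
        }

    out = matrix.drop_features(removed) if removed else matrix
    report = StageReport(
        stage_name="blank_filter",
        parameters={
            "fold_factor": params.fold_factor,
            "max_sample_missing_pct": params.max_sample_missing_pct,
            "scope": params.scope,
        },
        n_features_in=len(matrix.feature_ids),
        n_features_out=len(out.feature_ids),
        n_samples_in=len(matrix.sample_ids),
        n_samples_out=len(out.sample_ids),
        removed_feature_ids=removed,
        per_feature_metrics=metrics,
    )
    return out, report
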