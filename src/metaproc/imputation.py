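"""Missing-value imputation: small-value replacement, feature-wise KNN and
iterative random-forest imputation.

Missing intensities arise from class-specific absence, censoring below the
limit of detection, or deconvolution failures. Three imputers are offered:

* **SV** — replace each missing cell of a feature by half the feature's
  minimum observed value (a limit-of-detection surrogate).
* **KNN** — features are the objects being matched: the k features nearest
  in Euclidean distance (over co-observed samples, rescaled by co-observation
  count) donate their value in the missing cell, averaged unweighted.
* **RF** — iterative random-forest imputation in the missForest style:
  initialize with feature means, repeatedly regress each incomplete feature
  on all others, and stop when the normalized squared difference between
  successive imputations first increases, returning the previous iterate.

All imputers leave originally observed cells untouched and are no-ops on
complete matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .errors import ParameterError, ValidationError
from .model import FeatureMatrix, StageReport


@dataclass
class ImputationParams:
    method: Literal["sv", "knn", "rf"] = "knn"
    k: int = 10
    rf_trees: int = 100
    rf_max_iter: int = 10
    seed: int = 0
    #: SV variant: half the per-feature minimum across all samples
    #: ("feature", standard) or per feature within each sample's batch is not
    #: meaningful — the alternative reading is the global per-sample minimum.
    sv_scope: Literal["feature", "sample"] = "feature"
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.rf_trees < 1:
            raise ParameterError("rf_trees must be >= 1")
        if self.rf_max_iter < 1:
            raise ParameterError("rf_max_iter must be >= 1")


def _check_no_all_missing(matrix: FeatureMatrix) -> None:
    mask = matrix.missing_mask
    dead = [fid for j, fid in enumerate(matrix.feature_ids) if mask[:, j].all()]
    if dead:
        raise ValidationError(
            f"features with no observed values cannot be imputed: {dead[:10]}"
            + ("..." if len(dead) > 10 else "")
        )


def impute_small_value(
    matrix: FeatureMatrix, params: ImputationParams | None = None
) -> tuple[FeatureMatrix, StageReport]:
    """Replace each MISSING cell by half the minimum observed value.

    The minimum is taken per feature across all samples (``sv_scope
    ="feature"``, the default) or per sample across all features
    (``sv_scope="sample"``).
    """
    params = params or ImputationParams(method="sv")
    _check_no_all_missing(matrix)
    vals = matrix.values
    mask = np.isnan(vals)
    if params.sv_scope == "feature":
        mins = np.nanmin(vals, axis=0)  # per feature
        fill = np.broadcast_to(mins / 2.0, vals.shape)
    else:
        mins = np.nanmin(vals, axis=1)  # per sample
        fill = np.broadcast_to((mins / 2.0)[:, None], vals.shape)
    out = np.where(mask, fill, vals)
    report = StageReport(
        stage_name="impute_sv",
        parameters={"method": "sv", "sv_scope": params.sv_scope},
        n_features_in=matrix.shape[1],
        n_features_out=matrix.shape[1],
        n_samples_in=matrix.shape[0],
        n_samples_out=matrix.shape[0],
        extra={"n_imputed_cells": int(mask.sum())},
    )
    return matrix.with_values(out), report


def _knn_feature_distances(vals: np.ndarray, j: int) -> np.ndarray:
    """Distances from feature j to every feature (inf where not computable).

    Euclidean over co-observed samples, rescaled by
    (total samples / co-observed samples) so sparsely co-observed pairs are
    penalized: d^2 = (N / n_co) * sum_co (x - y)^2.
    """
    n_samples, n_features = vals.shape
    x = vals[:, j]
    d2 = np.full(n_features, np.inf)
    for g in range(n_features):
        if g == j:
            continue
        y = vals[:, g]
        co = ~np.isnan(x) & ~np.isnan(y)
        n_co = int(co.sum())
        if n_co == 0:
            continue
        d2[g] = (n_samples / n_co) * float(((x[co] - y[co]) ** 2).sum())
    return np.sqrt(d2)


def impute_knn(
    matrix: FeatureMatrix, params: ImputationParams | None = None
) -> tuple[FeatureMatrix, StageReport]:
    """Feature-wise k-nearest-neighbour imputation.

    For each feature with missing cells, the k nearest features donate their
    value in the missing sample, averaged unweighted; neighbours missing in
    that sample are skipped, and when all k are missing there the feature's
    own observed mean is used. Ties in distance break by feature index, so
    the result is deterministic.
    """
    params = params or ImputationParams(method="knn")
    if params.k >= matrix.shape[1]:
        raise ParameterError(
            f"k={params.k} must be smaller than the number of features "
            f"({matrix.shape[1]})"
        )
    _check_no_all_missing(matrix)
    vals = matrix.values
    if params.log_transform:
        work = np.log1p(vals)
    else:
        work = vals.copy()
    mask = np.isnan(work)
    out = work.copy()
    n_fallback = 0
    for j in range(work.shape[1]):
        mis_rows = np.where(mask[:, j])[0]
        if mis_rows.size == 0:
            continue
        d = _knn_feature_distances(work, j)
        finite = np.where(np.isfinite(d))[0]
        # stable sort on distance; index order breaks ties
        neighbours = finite[np.argsort(d[finite], kind="stable")][: params.k]
        feat_mean = float(np.nanmean(work[:, j]))
        for i in mis_rows:
            donor = work[i, neighbours]
            donor = donor[~np.isnan(donor)]
            if donor.size:
                out[i, j] = float(donor.mean())
            else:
                out[i, j] = feat_mean
                n_fallback += 1
    if params.log_transform:
        out = np.where(mask, np.expm1(out), vals)
    report = StageReport(
        stage_name="impute_knn",
        parameters={"method": "knn", "k": params.k, "log_transform": params.log_transform},
        n_features_in=matrix.shape[1],
        n_features_out=matrix.shape[1],
        n_samples_in=matrix.shape[0],
        n_samples_out=matrix.shape[0],
        extra={"n_imputed_cells": int(mask.sum()), "n_mean_fallbacks": n_fallback},
    )
    return matrix.with_values(out), report


def impute_random_forest(
    matrix: FeatureMatrix, params: ImputationParams | None = None
) -> tuple[FeatureMatrix, StageReport]:
    """missForest-style iterative random-forest imputation.

    Missing cells are initialized with feature means; features are visited
    in order of ascending missingness, each regressed on all others with a
    random forest fit on its originally observed rows. Iteration stops when
    the convergence statistic — sum of squared changes between successive
    imputations divided by the sum of squared current imputed values —
    first increases (the previous iterate is returned) or after
    ``rf_max_iter`` rounds.
    """
    params = params or ImputationParams(method="rf")
    if matrix.shape[1] < 2:
        raise ParameterError("random-forest imputation needs at least 2 features")
    _check_no_all_missing(matrix)
    vals = matrix.values
    if params.log_transform:
        work = np.log1p(vals)
    else:
        work = vals.copy()
    mask = np.isnan(work)
    if not mask.any():
        report = StageReport(
            stage_name="impute_rf",
            parameters={"method": "rf", "rf_trees": params.rf_trees, "seed": params.seed},
            n_features_in=matrix.shape[1],
            n_features_out=matrix.shape[1],
            n_samples_in=matrix.shape[0],
            n_samples_out=matrix.shape[0],
            extra={"n_imputed_cells": 0, "iterations": 0, "convergence_trace": []},
        )
        return matrix.with_values(vals.copy()), report

    n_samples, n_features = work.shape
    col_means = np.nanmean(work, axis=0)
    cur = np.where(mask, col_means[None, :], work)

    miss_counts = mask.sum(axis=0)
    visit = [j for j in np.argsort(miss_counts, kind="stable") if miss_counts[j] > 0]

    trace: list[float] = []
    prev_diff = np.inf
    best = cur.copy()
    iterations = 0
    for it in range(params.rf_max_iter):
        old = cur.copy()
        for rank, j in enumerate(visit):
            obs = ~mask[:, j]
            mis = mask[:, j]
            others = [g for g in range(n_features) if g != j]
            rf = RandomForestRegressor(
                n_estimators=params.rf_trees,
                random_state=(params.seed + 7919 * it + rank) % (2**31 - 1),
                n_jobs=1,
            )
            rf.fit(cur[np.ix_(obs, others)], work[obs, j])
            cur[mis, j] = rf.predict(cur[np.ix_(mis, others)])
        diff = float(((cur - old) ** 2).sum() / (cur**2).sum())
        trace.append(diff)
        iterations = it + 1
        if diff > prev_diff:
            cur = old  # return the last iterate before the increase
            break
        best = cur.copy()
        prev_diff = diff
    else:
        cur = best

    if params.log_transform:
        out = np.where(mask, np.expm1(cur), vals)
    else:
        out = np.where(mask, cur, vals)
    out = np.clip(out, 0.0, None)  # forests can't extrapolate below 0 anyway
    report = StageReport(
        stage_name="impute_rf",
        parameters={
            "method": "rf",
            "rf_trees": params.rf_trees,
            "rf_max_iter": params.rf_max_iter,
            "seed": params.seed,
            "log_transform": params.log_transform,
        },
        n_features_in=matrix.shape[1],
        n_features_out=matrix.shape[1],
        n_samples_in=matrix.shape[0],
        n_samples_out=matrix.shape[0],
        extra={
            "n_imputed_cells": int(mask.sum()),
            "iterations": iterations,
            "convergence_trace": trace,
        },
    )
    return matrix.with_values(out), report


def impute(
    matrix: FeatureMatrix, params: ImputationParams
) -> tuple[FeatureMatrix, StageReport]:
    """Dispatch on ``params.method``."""
    if params.method == "sv":
        return impute_small_value(matrix, params)
    if params.method == "knn":
        return impute_knn(matrix, params)
    if params.method == "rf":
        return impute_random_forest(matrix, params)
    raise ParameterError(f"unknown imputation method {params.method!r}")
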