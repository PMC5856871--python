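"""Injection-order signal-drift correction and batch merging (RLSC).

LC–MS intensities drift smoothly with injection order. Anchored on the
pooled QCs (or on all non-blank samples), a robust LOESS curve is fitted
per feature and per batch to intensity versus injection order; every
sample's intensity is divided by the fitted curve at its own injection
order and rescaled by the feature's anchor median over the whole run. The
rescaling restores a common scale across analytical blocks, which is what
merges batches. Drift is treated as multiplicative, hence the ratio-based
correction.

The LOESS here is the conventional robust configuration: tricube
neighbourhood weights, local polynomial of degree 2, and bisquare
robustness reweighting passes on the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, ParameterError, ValidationError
from .model import FeatureMatrix, SampleRecord, SampleType, StageReport
from .filtering import feature_rsd


@dataclass
class RlscParams:
    anchor: Literal["qc", "all"] = "qc"
    span: float = 0.75
    degree: int = 2
    robust_iterations: int = 4
    per_batch: bool = True
    seed: int = 0  # reserved; LOESS itself is deterministic

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ParameterError("span must be in (0, 1]")
        if self.degree not in (1, 2):
            raise ParameterError("degree must be 1 or 2")
        if self.robust_iterations < 0:
            raise ParameterError("robust_iterations must be >= 0")


@dataclass
class DriftFit:
    """Fitted drift curve for one feature in one batch.

    ``fitted_values`` are the robust-LOESS fits at the anchor injection
    orders; :meth:`predict` interpolates linearly between anchors and
    clamps (constant extrapolation) beyond the first/last anchor.
    """

    feature_id: str
    batch: str
    anchor_orders: np.ndarray
    fitted_values: np.ndarray

    def predict(self, orders: np.ndarray | Sequence[float]) -> np.ndarray:
        return np.interp(np.asarray(orders, dtype=float),
                         self.anchor_orders, self.fitted_values)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _wls_poly(x: np.ndarray, y: np.ndarray, w: np.ndarray, degree: int, x0: float) -> float:
    """Weighted least-squares polynomial fit evaluated at x0.

    Centering at x0 keeps the design well-conditioned; the intercept is the
    prediction. Degrades the degree when too few distinct points carry
    weight.
    """
    keep = w > 0
    xs, ys, ws = x[keep], y[keep], w[keep]
    deg = min(degree, max(0, len(np.unique(xs)) - 1))
    t = xs - x0
    design = np.vander(t, deg + 1, increasing=True)
    sw = np.sqrt(ws)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], ys * sw, rcond=None)
    return float(coef[0])


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    robust_iterations: int = 4,
) -> np.ndarray:
    """Robust LOESS fitted values at the input points.

    Tricube weights over the ``ceil(span * n)`` nearest points, local
    polynomial of the given degree, then ``robust_iterations`` bisquare
    reweighting passes on the residuals (weights ``(1-(r/6s)^2)^2`` with
    ``s`` the median absolute residual).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    rob = np.ones(n)
    fitted = np.empty(n)
    for _pass in range(robust_iterations + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argsort(d, kind="stable")[:q]
            dmax = d[idx].max()
            if dmax == 0:
                w = np.zeros(n)
                w[idx] = 1.0
            else:
                w = np.zeros(n)
                w[idx] = _tricube(d[idx] / dmax)
            w *= rob
            if not (w > 0).any():  # all local points down-weighted to zero
                w[idx] = 1.0
            fitted[i] = _wls_poly(x, y, w, degree, x[i])
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        rob = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return fitted


def fit_loess_drift(
    values: np.ndarray,
    orders: np.ndarray,
    params: RlscParams | None = None,
    feature_id: str = "",
    batch: str = "",
) -> DriftFit:
    """Fit the robust drift curve of one feature on its anchor injections.

    ``values``/``orders`` are the anchor samples' non-missing intensities
    and injection orders; at least ``degree + 2`` anchors are required.
    """
    params = params or RlscParams()
    values = np.asarray(values, dtype=float)
    orders = np.asarray(orders, dtype=float)
    keep = ~np.isnan(values)
    values, orders = values[keep], orders[keep]
    if len(values) < params.degree + 2:
        raise ParameterError(
            f"need at least degree+2={params.degree + 2} anchor points, got {len(values)}"
        )
    sort = np.argsort(orders, kind="stable")
    orders, values = orders[sort], values[sort]
    fitted = loess_fit(orders, values, params.span, params.degree, params.robust_iterations)
    return DriftFit(
        feature_id=feature_id, batch=batch, anchor_orders=orders, fitted_values=fitted
    )


def correct_rlsc(
    matrix: FeatureMatrix,
    samples: Sequence[SampleRecord],
    params: RlscParams | None = None,
) -> tuple[FeatureMatrix, StageReport]:
    """QC-anchored (or all-sample) robust LOESS drift/batch correction.

    Per feature and per batch the corrected intensity is
    ``x / fitted_curve(order) * m_f`` with ``m_f`` the feature's median over
    all anchor samples of the run. Cells whose fitted value is non-positive
    become MISSING and are counted in the report. Batches with too few
    usable anchors for a feature fall back to median scaling for that
    feature (recorded).
    """
    params = params or RlscParams()
    by_id = {s.sample_id: s for s in samples}
    absent = [sid for sid in matrix.sample_ids if sid not in by_id]
    if absent:
        raise ValidationError(f"samples without metadata: {absent[:5]}")
    recs = [by_id[sid] for sid in matrix.sample_ids]
    if any(r.injection_order is None for r in recs):
        raise ValidationError("injection orders are required for drift correction")

    if params.anchor == "qc":
        anchor_rows = [i for i, r in enumerate(recs) if r.sample_type is SampleType.QC]
        if not anchor_rows:
            raise ConfigurationError("QC-anchored correction requires QC samples")
    else:
        anchor_rows = [
            i for i, r in enumerate(recs) if r.sample_type is not SampleType.BLANK
        ]

    orders = np.array([r.injection_order for r in recs], dtype=float)
    batches = [r.batch for r in recs] if params.per_batch else ["__run__"] * len(recs)
    batch_names = sorted(set(batches), key=str)

    vals = matrix.values
    out = vals.copy()
    anchor_set = set(anchor_rows)
    n_invalidated = 0
    fallbacks: list[str] = []

    qc_ids = [r.sample_id for r in recs if r.sample_type is SampleType.QC]
    rsd_before = feature_rsd(matrix, qc_ids) if qc_ids else {}

    for j, fid in enumerate(matrix.feature_ids):
        col = vals[:, j]
        anchor_all = [i for i in anchor_rows if not np.isnan(col[i])]
        if not anchor_all:
            out[:, j] = np.nan
            n_invalidated += int((~np.isnan(col)).sum())
            fallbacks.append(f"{fid}: no observed anchors, feature invalidated")
            continue
        m_f = float(np.median(col[anchor_all]))
        for b in batch_names:
            rows = [i for i in range(len(recs)) if batches[i] == b]
            b_anchor = [i for i in rows if i in anchor_set and not np.isnan(col[i])]
            if len(b_anchor) < params.degree + 2:
                # median scaling fallback for this batch
                scale = float(np.median(col[b_anchor])) if b_anchor else np.nan
                fallbacks.append(f"{fid}/batch {b}: {len(b_anchor)} anchors, median scaling")
                if not np.isfinite(scale) or scale <= 0:
                    for i in rows:
                        if not np.isnan(col[i]):
                            n_invalidated += 1
                        out[i, j] = np.nan
                else:
                    for i in rows:
                        out[i, j] = col[i] / scale * m_f
                continue
            fit = fit_loess_drift(
                col[b_anchor], orders[b_anchor], params, feature_id=fid, batch=str(b)
            )
            pred = fit.predict(orders[rows])
            for i, p in zip(rows, pred):
                if np.isnan(col[i]):
                    continue
                if p <= 0:
                    out[i, j] = np.nan
                    n_invalidated += 1
                else:
                    out[i, j] = col[i] / p * m_f

    corrected = matrix.with_values(out)
    rsd_after = feature_rsd(corrected, qc_ids) if qc_ids else {}
    report = StageReport(
        stage_name="batch_correction",
        parameters={
            "anchor": params.anchor,
            "span": params.span,
            "degree": params.degree,
            "robust_iterations": params.robust_iterations,
            "per_batch": params.per_batch,
        },
        n_features_in=matrix.shape[1],
        n_features_out=matrix.shape[1],
        n_samples_in=matrix.shape[0],
        n_samples_out=matrix.shape[0],
        per_feature_metrics={
            fid: {
                "qc_rsd_before": rsd_before.get(fid, float("nan")),
                "qc_rsd_after": rsd_after.get(fid, float("nan")),
            }
            for fid in matrix.feature_ids
        },
        extra={"n_cells_invalidated": n_invalidated, "fallbacks": fallbacks},
    )
    return corrected, report
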