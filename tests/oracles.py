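"""Independent brute-force reference implementations used to cross-check
the package. Everything here is written as plain per-element loops, straight
from the rule definitions, and shares no code with the implementation."""

from __future__ import annotations

import math

import numpy as np


# -- filtering ---------------------------------------------------------------

def rsd_percent(values: list[float]) -> float | None:
    """Sample RSD% of a list of observed values; None when undefined."""
    obs = [v for v in values if not math.isnan(v)]
    if len(obs) < 2:
        return None
    mean = sum(obs) / len(obs)
    if mean == 0:
        return None
    var = sum((v - mean) ** 2 for v in obs) / (len(obs) - 1)
    return 100.0 * math.sqrt(var) / mean


def qc_filter_kept(
    vals: np.ndarray, qc_rows: list[int], max_missing: float, max_rsd: float,
    rule: str = "or",
) -> list[int]:
    """Columns kept by the QC rule, evaluated feature by feature."""
    kept = []
    for j in range(vals.shape[1]):
        qc_vals = [vals[i, j] for i in qc_rows]
        n_miss = sum(1 for v in qc_vals if math.isnan(v))
        miss_pct = 100.0 * n_miss / len(qc_rows)
        rsd = rsd_percent(qc_vals)
        fail_missing = miss_pct > max_missing
        fail_rsd = rsd is None or rsd > max_rsd
        delete = (fail_missing and fail_rsd) if rule == "and" else (fail_missing or fail_rsd)
        if not delete:
            kept.append(j)
    return kept


def blank_filter_kept(
    vals: np.ndarray, study_rows: list[int], blank_rows: list[int],
    fold: float, max_missing: float,
) -> list[int]:
    kept = []
    for j in range(vals.shape[1]):
        s = [vals[i, j] for i in study_rows if not math.isnan(vals[i, j])]
        b = [vals[i, j] for i in blank_rows if not math.isnan(vals[i, j])]
        s_mean = sum(s) / len(s) if s else 0.0
        b_mean = sum(b) / len(b) if b else 0.0
        miss_pct = 100.0 * (len(study_rows) - len(s)) / len(study_rows)
        if s_mean > fold * b_mean and miss_pct <= max_missing:
            kept.append(j)
    return kept


# -- KNN imputation ----------------------------------------------------------

def knn_impute(vals: np.ndarray, k: int) -> np.ndarray:
    """Feature-wise KNN by exhaustive neighbour enumeration."""
    n, p = vals.shape
    out = vals.copy()
    for j in range(p):
        missing_rows = [i for i in range(n) if math.isnan(vals[i, j])]
        if not missing_rows:
            continue
        dists = []
        for g in range(p):
            if g == j:
                continue
            co = [i for i in range(n)
                  if not math.isnan(vals[i, j]) and not math.isnan(vals[i, g])]
            if not co:
                continue
            ss = sum((vals[i, j] - vals[i, g]) ** 2 for i in co)
            dists.append((math.sqrt(n / len(co) * ss), g))
        dists.sort(key=lambda t: (t[0], t[1]))
        neighbours = [g for _, g in dists[:k]]
        obs = [vals[i, j] for i in range(n) if not math.isnan(vals[i, j])]
        feat_mean = sum(obs) / len(obs)
        for i in missing_rows:
            donors = [vals[i, g] for g in neighbours if not math.isnan(vals[i, g])]
            out[i, j] = sum(donors) / len(donors) if donors else feat_mean
    return out


# -- LOESS -------------------------------------------------------------------

def loess_fitted(x, y, span=0.75, degree=2, robust_iterations=4):
    """Robust local polynomial regression by explicit normal equations."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    q = min(max(int(math.ceil(span * n)), degree + 1), n)
    rob = [1.0] * n
    fitted = [0.0] * n
    for _ in range(robust_iterations + 1):
        for i in range(n):
            d = sorted((abs(x[m] - x[i]), m) for m in range(n))
            window = d[:q]
            dmax = window[-1][0]
            w = [0.0] * n
            for dist, m in window:
                if dmax == 0:
                    w[m] = 1.0
                else:
                    u = dist / dmax
                    w[m] = (1 - u**3) ** 3 if u < 1 else 0.0
            w = [w[m] * rob[m] for m in range(n)]
            if not any(v > 0 for v in w):
                for _, m in window:
                    w[m] = 1.0
            deg = min(degree, len({x[m] for m in range(n) if w[m] > 0}) - 1)
            # normal equations for weighted poly fit centred at x[i]
            a = [[0.0] * (deg + 1) for _ in range(deg + 1)]
            b = [0.0] * (deg + 1)
            for m in range(n):
                if w[m] == 0:
                    continue
                t = x[m] - x[i]
                for r in range(deg + 1):
                    b[r] += w[m] * (t**r) * y[m]
                    for c in range(deg + 1):
                        a[r][c] += w[m] * t ** (r + c)
            coef = np.linalg.solve(np.array(a), np.array(b))
            fitted[i] = float(coef[0])
        resid = [y[m] - fitted[m] for m in range(n)]
        s = sorted(abs(r) for r in resid)[len(resid) // 2] if len(resid) % 2 else (
            (sorted(abs(r) for r in resid)[len(resid) // 2 - 1]
             + sorted(abs(r) for r in resid)[len(resid) // 2]) / 2
        )
        if s <= 0:
            break
        rob = [max(0.0, 1 - (r / (6 * s)) ** 2) ** 2 for r in resid]
    return fitted


# -- accurate-mass search ----------------------------------------------------

def mass_search(features, db, adducts, ppm_tol):
    """Triple loop over (feature, adduct, compound)."""
    hits = set()
    for feat in features:
        for adduct in adducts:
            observed = (feat.mz * abs(adduct.charge) - adduct.mass_shift) / adduct.multimer
            if observed <= 0:
                continue
            for c in db:
                ppm = (observed - c.monoisotopic_mass) / c.monoisotopic_mass * 1e6
                if abs(ppm) <= ppm_tol:
                    hits.add((feat.feature_id, adduct.name, c.compound_id))
    return hits
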