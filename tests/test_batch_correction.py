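"""Robust-LOESS drift correction and batch merging."""

import numpy as np
import pytest

from metaproc import (
    RlscParams,
    SampleType,
    correct_rlsc,
    feature_rsd,
    fit_loess_drift,
    loess_fit,
    generate_dataset,
    preset,
)
from metaproc.errors import ParameterError

import oracles
from conftest import make_matrix, make_samples


class TestLoessFit:
    def test_reproduces_straight_line(self, rng):
        x = np.arange(1, 21, dtype=float)
        y = 3.0 + 0.5 * x
        for degree in (1, 2):
            fitted = loess_fit(x, y, span=0.75, degree=degree)
            np.testing.assert_allclose(fitted, y, atol=1e-6)

    def test_constant_values_fit_constant(self):
        x = np.arange(1, 11, dtype=float)
        fitted = loess_fit(x, np.full(10, 42.0))
        np.testing.assert_allclose(fitted, 42.0, atol=1e-9)

    def test_interpolation_of_line_is_exact(self):
        orders = np.arange(1.0, 31.0, 3.0)
        values = 10.0 + 2.0 * orders
        fit = fit_loess_drift(values, orders, RlscParams(degree=1))
        query = np.arange(orders.min(), orders.max() + 1)
        np.testing.assert_allclose(fit.predict(query), 10.0 + 2.0 * query, atol=1e-6)

    def test_extrapolation_is_clamped(self):
        orders = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = fit_loess_drift(values, orders, RlscParams(degree=1))
        assert fit.predict([0.0]) == pytest.approx(fit.predict([5.0]))
        assert fit.predict([99.0]) == pytest.approx(fit.predict([25.0]))

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ParameterError):
            fit_loess_drift(np.array([1.0, 2.0]), np.array([1.0, 2.0]), RlscParams())

    def test_matches_brute_force_wls_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 25))
            x = np.sort(rng.choice(np.arange(1, 100), size=n, replace=False)).astype(float)
            y = rng.lognormal(2, 0.5, n)
            span = float(rng.choice([0.5, 0.75, 1.0]))
            degree = int(rng.choice([1, 2]))
            robust = int(rng.choice([0, 2, 4]))
            ours = loess_fit(x, y, span=span, degree=degree, robust_iterations=robust)
            ref = oracles.loess_fitted(x, y, span=span, degree=degree,
                                       robust_iterations=robust)
            np.testing.assert_allclose(ours, np.asarray(ref), rtol=1e-6, atol=1e-8)


class TestCorrectRlsc:
    def test_identity_on_drift_free_data(self, rng):
        n = 30
        vals = np.tile(rng.lognormal(5, 1, 8), (n, 1))
        types = "".join("q" if (i + 1) % 5 == 0 else "s" for i in range(n))
        out, report = correct_rlsc(make_matrix(vals), make_samples(types), RlscParams())
        np.testing.assert_allclose(out.values, vals, rtol=1e-9)
        assert report.extra["n_cells_invalidated"] == 0

    def test_scale_equivariance_per_feature(self, rng):
        params = preset("drifty", seed=4)
        matrix, samples, _, _ = generate_dataset(params)
        out1, _ = correct_rlsc(matrix, samples, RlscParams())
        scaled_vals = matrix.values
        scaled_vals[:, 3] *= 11.0
        out2, _ = correct_rlsc(matrix.with_values(scaled_vals), samples, RlscParams())
        np.testing.assert_allclose(out2.values[:, 3], 11.0 * out1.values[:, 3], rtol=1e-9)

    def test_correction_only_depends_on_own_feature(self, rng):
        params = preset("drifty", seed=5)
        matrix, samples, _, _ = generate_dataset(params)
        out1, _ = correct_rlsc(matrix, samples, RlscParams())
        vals = matrix.values
        vals[:, 1:] = vals[:, 1:][:, rng.permutation(vals.shape[1] - 1)]
        out2, _ = correct_rlsc(matrix.with_values(vals), samples, RlscParams())
        np.testing.assert_allclose(out2.values[:, 0], out1.values[:, 0])

    def test_monotone_drift_reduces_qc_rsd(self):
        """QC-anchored RLSC shrinks QC RSD for nearly every feature under
        multiplicative monotone drift."""
        fractions = []
        for seed in range(3):
            matrix, samples, _, _ = generate_dataset(preset("drifty", seed=seed))
            out, _ = correct_rlsc(matrix, samples, RlscParams())
            qc_ids = [s.sample_id for s in samples if s.sample_type is SampleType.QC]
            before = feature_rsd(matrix, qc_ids)
            after = feature_rsd(out, qc_ids)
            improved = [after[f] < before[f] for f in matrix.feature_ids]
            fractions.append(np.mean(improved))
        assert np.mean(fractions) >= 0.95

    def test_two_batches_merge(self):
        """Per-batch correction brings per-feature QC means of a 2x offset
        batch pair within 5% of each other."""
        matrix, samples, _, _ = generate_dataset(preset("two-batch", seed=11))
        out, _ = correct_rlsc(matrix, samples, RlscParams())
        qc1 = [s.sample_id for s in samples if s.sample_type is SampleType.QC and s.batch == "1"]
        qc2 = [s.sample_id for s in samples if s.sample_type is SampleType.QC and s.batch == "2"]
        m1 = np.nanmean(out.select_samples(qc1).values, axis=0)
        m2 = np.nanmean(out.select_samples(qc2).values, axis=0)
        rel = np.abs(m1 - m2) / ((m1 + m2) / 2)
        assert (rel < 0.05).all()

    def test_missing_cells_stay_missing_and_sets_unchanged(self, rng):
        matrix, samples, _, _ = generate_dataset(preset("sparse", seed=2))
        out, report = correct_rlsc(matrix, samples, RlscParams())
        assert out.sample_ids == matrix.sample_ids
        assert out.feature_ids == matrix.feature_ids
        # correction may only ADD missing cells (non-positive fits)
        added = out.missing_mask & ~matrix.missing_mask
        assert (matrix.missing_mask <= out.missing_mask).all()
        assert report.extra["n_cells_invalidated"] == added.sum()

    def test_too_few_anchors_falls_back_to_median_scaling(self):
        vals = np.tile([[10.0], [20.0], [30.0], [40.0]], (1, 1)).astype(float)
        samples = make_samples("qsss")
        out, report = correct_rlsc(make_matrix(vals), samples, RlscParams())
        assert len(report.extra["fallbacks"]) == 1
        # single anchor: scale = anchor value, m_f = anchor median -> identity
        np.testing.assert_allclose(out.values, vals)
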