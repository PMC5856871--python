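"""Missing-value imputation: SV, feature-wise KNN and iterative RF."""

import numpy as np
import pytest

from metaproc import (
    ImputationParams,
    impute_knn,
    impute_random_forest,
    impute_small_value,
)
from metaproc.errors import ParameterError, ValidationError

import oracles
from conftest import make_matrix, random_matrix_with_missing


class TestSmallValue:
    def test_half_of_feature_minimum(self):
        out, _ = impute_small_value(make_matrix([[4.0], [8.0], [np.nan]]))
        assert out.values[:, 0].tolist() == [4.0, 8.0, 2.0]

    def test_multiple_missing_same_feature(self):
        out, _ = impute_small_value(make_matrix([[0.5], [np.nan], [np.nan]]))
        assert out.values[:, 0].tolist() == [0.5, 0.25, 0.25]

    def test_complete_matrix_unchanged(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        out, report = impute_small_value(m)
        assert out == m
        assert report.extra["n_imputed_cells"] == 0

    def test_per_sample_variant(self):
        m = make_matrix([[4.0, 10.0, np.nan], [6.0, 1.0, 7.0]])
        out, _ = impute_small_value(m, ImputationParams(method="sv", sv_scope="sample"))
        assert out.values[0, 2] == pytest.approx(2.0)  # half of sample min 4

    def test_all_missing_feature_rejected(self):
        with pytest.raises(ValidationError, match="F2"):
            impute_small_value(make_matrix([[1.0, np.nan], [2.0, np.nan]]))


class TestKnn:
    def test_identical_features_donate_their_value(self):
        vals = np.array([[5.0, 5.0, 5.0], [7.0, 7.0, 7.0], [np.nan, 9.0, 9.0]])
        out, _ = impute_knn(make_matrix(vals), ImputationParams(method="knn", k=2))
        assert out.values[2, 0] == pytest.approx(9.0)

    def test_k_equals_all_other_features_gives_row_mean(self):
        vals = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [np.nan, 8.0, 10.0]])
        out, _ = impute_knn(make_matrix(vals), ImputationParams(method="knn", k=2))
        assert out.values[2, 0] == pytest.approx((8.0 + 10.0) / 2)

    def test_complete_matrix_is_identity(self, rng):
        vals = rng.lognormal(3, 1, (6, 5))
        m = make_matrix(vals)
        out, _ = impute_knn(m, ImputationParams(method="knn", k=3))
        assert out == m

    def test_k_must_be_smaller_than_feature_count(self):
        with pytest.raises(ParameterError):
            impute_knn(make_matrix([[1.0, 2.0]]), ImputationParams(method="knn", k=2))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            n_s, n_f = int(rng.integers(4, 14)), int(rng.integers(3, 16))
            vals = random_matrix_with_missing(rng, n_s, n_f, missing_rate=0.2)
            # ensure every feature keeps an observation
            for j in np.where(np.isnan(vals).all(axis=0))[0]:
                vals[0, j] = 1.0
            k = int(rng.integers(1, n_f))
            out, _ = impute_knn(make_matrix(vals), ImputationParams(method="knn", k=k))
            expected = oracles.knn_impute(vals, k)
            np.testing.assert_allclose(out.values, expected, rtol=1e-12)


class TestRandomForest:
    def test_complete_matrix_is_identity_with_zero_iterations(self, rng):
        vals = rng.lognormal(3, 1, (10, 4))
        m = make_matrix(vals)
        out, report = impute_random_forest(m, ImputationParams(method="rf", seed=1))
        assert out == m
        assert report.extra["iterations"] == 0

    def test_fixed_seed_is_bit_identical(self, rng):
        vals = random_matrix_with_missing(rng, 40, 6, missing_rate=0.1)
        m = make_matrix(vals)
        params = ImputationParams(method="rf", rf_trees=20, seed=42)
        out1, _ = impute_random_forest(m, params)
        out2, _ = impute_random_forest(m, params)
        assert (out1.values == out2.values).all()

    def test_recovers_linear_relation(self):
        """With y = 2x and 10% of y missing, RF should land near the truth
        for the vast majority of imputed cells."""
        rng = np.random.default_rng(7)
        n = 200
        x = rng.uniform(10, 100, n)
        y = 2.0 * x
        vals = np.column_stack([x, y, x + rng.normal(0, 0.5, n)])
        miss = rng.choice(n, size=20, replace=False)
        vals[miss, 1] = np.nan
        out, _ = impute_random_forest(
            make_matrix(vals), ImputationParams(method="rf", rf_trees=50, seed=3)
        )
        rel_err = np.abs(out.values[miss, 1] - 2.0 * x[miss]) / (2.0 * x[miss])
        assert (rel_err < 0.15).mean() >= 0.90

    def test_convergence_trace_non_increasing_before_stop(self, rng):
        vals = random_matrix_with_missing(rng, 50, 8, missing_rate=0.15)
        for j in np.where(np.isnan(vals).all(axis=0))[0]:
            vals[0, j] = 1.0
        _, report = impute_random_forest(
            make_matrix(vals), ImputationParams(method="rf", rf_trees=20, seed=5)
        )
        trace = report.extra["convergence_trace"]
        returned = trace[:-1] if len(trace) > 1 and trace[-1] > trace[-2] else trace
        assert all(b <= a for a, b in zip(returned, returned[1:]))

    def test_needs_two_features(self):
        with pytest.raises(ParameterError):
            impute_random_forest(make_matrix([[1.0], [np.nan]]),
                                 ImputationParams(method="rf"))


@pytest.mark.parametrize("method", ["sv", "knn", "rf"])
def test_observed_cells_never_altered(method, rng):
    """Mask preservation: imputation only touches originally missing cells."""
    vals = random_matrix_with_missing(rng, 25, 8, missing_rate=0.15)
    for j in np.where(np.isnan(vals).all(axis=0))[0]:
        vals[0, j] = 1.0
    m = make_matrix(vals)
    params = ImputationParams(method=method, k=4, rf_trees=10, seed=1)
    if method == "sv":
        out, _ = impute_small_value(m, params)
    elif method == "knn":
        out, _ = impute_knn(m, params)
    else:
        out, _ = impute_random_forest(m, params)
    obs = ~np.isnan(vals)
    assert (out.values[obs] == vals[obs]).all()
    assert not np.isnan(out.values).any()
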