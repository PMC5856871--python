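"""QC- and blank-based feature filtering."""

import numpy as np
import pytest

from metaproc import (
    BlankFilterParams,
    QcFilterParams,
    feature_rsd,
    filter_by_blank,
    filter_by_qc,
)
from metaproc.errors import ConfigurationError, ParameterError

import oracles
from conftest import make_matrix, make_samples, random_matrix_with_missing


class TestFeatureRsd:
    def test_hand_computed_rsd(self):
        # values 100/120/80: deviations 0/+20/-20, variance (0+400+400)/2 -> SD 20
        m = make_matrix([[100.0], [120.0], [80.0]])
        rsd = feature_rsd(m, ["S1", "S2", "S3"])
        assert rsd["F1"] == pytest.approx(20.0)

    def test_constant_values_have_zero_rsd(self):
        m = make_matrix([[50.0], [50.0], [50.0]])
        assert feature_rsd(m, ["S1", "S2", "S3"])["F1"] == 0.0

    def test_single_observation_is_undefined(self):
        m = make_matrix([[100.0], [np.nan]])
        assert np.isnan(feature_rsd(m, ["S1", "S2"])["F1"])

    def test_empty_subset_rejected(self):
        m = make_matrix([[1.0]])
        with pytest.raises(ParameterError):
            feature_rsd(m, [])


class TestQcFilter:
    def _run(self, vals, types, **params):
        m = make_matrix(vals)
        return filter_by_qc(m, make_samples(types), QcFilterParams(**params))

    def test_mostly_missing_in_qcs_deleted(self):
        # missing in 4 of 6 QCs (66.7% > 50%) at defaults -> deleted
        vals = np.full((6, 1), np.nan)
        vals[0, 0] = vals[1, 0] = 100.0
        out, report = self._run(vals, "qqqqqq")
        assert out.feature_ids == [] or "F1" not in out.feature_ids
        assert report.removed_feature_ids == ["F1"]

    def test_rsd_exactly_at_threshold_retained(self):
        # QC RSD exactly 20% is not strictly greater -> retained
        out, _ = self._run([[100.0], [120.0], [80.0]], "qqq")
        assert out.feature_ids == ["F1"]

    def test_missing_exactly_half_retained(self):
        vals = np.array([[100.0], [100.0], [np.nan], [np.nan]])
        out, _ = self._run(vals, "qqqq")
        assert out.feature_ids == ["F1"]

    def test_no_qc_samples_raises_helpful_error(self):
        m = make_matrix([[1.0]])
        with pytest.raises(ConfigurationError, match="blank"):
            filter_by_qc(m, make_samples("s"), QcFilterParams())

    def test_and_rule_deletes_only_double_failures(self):
        # F1 fails only RSD; F2 fails both
        vals = np.array(
            [[100.0, 100.0], [200.0, np.nan], [100.0, np.nan], [95.0, np.nan]]
        )
        out_or, _ = self._run(vals, "qqqq", qc_rule="or")
        out_and, _ = self._run(vals, "qqqq", qc_rule="and")
        assert out_or.feature_ids == []
        assert out_and.feature_ids == ["F1"]

    def test_decision_ignores_study_intensities(self, rng):
        vals = random_matrix_with_missing(rng, 12, 20)
        types = "qqqq" + "s" * 8
        samples = make_samples(types)
        m1 = make_matrix(vals)
        shuffled = vals.copy()
        shuffled[4:, :] = shuffled[4:, :][rng.permutation(8), :]
        m2 = make_matrix(shuffled)
        out1, _ = filter_by_qc(m1, samples, QcFilterParams())
        out2, _ = filter_by_qc(m2, samples, QcFilterParams())
        assert out1.feature_ids == out2.feature_ids

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            n_s, n_f = int(rng.integers(4, 20)), int(rng.integers(1, 30))
            vals = random_matrix_with_missing(rng, n_s, n_f, missing_rate=0.3)
            n_qc = int(rng.integers(2, n_s))
            types = "q" * n_qc + "s" * (n_s - n_qc)
            max_missing = float(rng.choice([0, 25, 50, 75]))
            max_rsd = float(rng.choice([5, 20, 50, 150]))
            rule = str(rng.choice(["or", "and"]))
            out, _ = filter_by_qc(
                make_matrix(vals), make_samples(types),
                QcFilterParams(max_qc_missing_pct=max_missing,
                               max_qc_rsd_pct=max_rsd, qc_rule=rule),
            )
            expected = oracles.qc_filter_kept(
                vals, list(range(n_qc)), max_missing, max_rsd, rule
            )
            assert out.feature_ids == [f"F{j+1}" for j in expected]

    def test_retained_set_monotone_in_thresholds(self, rng):
        vals = random_matrix_with_missing(rng, 10, 40, missing_rate=0.3)
        m = make_matrix(vals)
        samples = make_samples("q" * 6 + "s" * 4)
        prev: set[str] = set()
        for miss, rsd in [(10, 5), (30, 15), (50, 20), (80, 60), (100, 500)]:
            out, _ = filter_by_qc(
                m, samples, QcFilterParams(max_qc_missing_pct=miss, max_qc_rsd_pct=rsd)
            )
            kept = set(out.feature_ids)
            assert prev <= kept
            prev = kept


class TestBlankFilter:
    def test_fold_rule_arithmetic(self):
        # study mean 1000 vs blank mean 200 * fold 3 = 600 -> retained
        # study mean 500 vs 600 -> deleted
        vals = np.array([[200.0, 200.0], [1000.0, 500.0], [1000.0, 500.0]])
        m = make_matrix(vals)
        samples = make_samples("bss")
        out, report = filter_by_blank(m, samples, BlankFilterParams(fold_factor=3.0))
        assert out.feature_ids == ["F1"]
        assert report.removed_feature_ids == ["F2"]

    def test_feature_absent_from_blanks_always_passes_fold(self):
        vals = np.array([[np.nan], [10.0], [20.0]])
        out, _ = filter_by_blank(
            make_matrix(vals), make_samples("bss"),
            BlankFilterParams(fold_factor=1e6),
        )
        assert out.feature_ids == ["F1"]

    def test_study_missingness_rule(self):
        vals = np.array([[np.nan], [10.0], [np.nan], [np.nan]])
        out, _ = filter_by_blank(
            make_matrix(vals), make_samples("bsss"),
            BlankFilterParams(fold_factor=2.0, max_sample_missing_pct=50.0),
        )
        assert out.feature_ids == []

    def test_requires_blank_samples(self):
        with pytest.raises(ConfigurationError):
            filter_by_blank(make_matrix([[1.0]]), make_samples("s"), BlankFilterParams())

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            n_s, n_f = int(rng.integers(5, 20)), int(rng.integers(1, 30))
            vals = random_matrix_with_missing(rng, n_s, n_f, missing_rate=0.3)
            n_b = int(rng.integers(1, 3))
            types = "b" * n_b + "s" * (n_s - n_b)
            fold = float(rng.choice([1, 3, 10]))
            max_missing = float(rng.choice([0, 50, 100]))
            out, _ = filter_by_blank(
                make_matrix(vals), make_samples(types),
                BlankFilterParams(fold_factor=fold, max_sample_missing_pct=max_missing),
            )
            expected = oracles.blank_filter_kept(
                vals, list(range(n_b, n_s)), list(range(n_b)), fold, max_missing
            )
            assert out.feature_ids == [f"F{j+1}" for j in expected]
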