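import numpy as np
import pytest

from icucourse.evaluation import (
    bbc_cv_interval,
    calibration_curve,
    calibration_slope,
    make_partitions,
    mean_calibration_slope,
    metric_timeseries,
    somers_dxy,
)
from icucourse.trajectory_model import Trajectory, sigmoid

from conftest import brute_force_dxy


class TestPartitions:
    def test_balanced_cohort_spreads_categories_evenly(self):
        y = np.repeat(np.arange(7), 5)  # 35 patients, 7x5
        scheme = make_partitions(y, repeats=1, folds=5, seed=0)
        for cell in scheme.cells():
            counts = np.bincount(y[cell.test_idx], minlength=7)
            assert np.all(counts == 1)

    def test_test_folds_partition_cohort_each_repeat(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 7, 120)
        scheme = make_partitions(y, repeats=3, folds=5, seed=1)
        for rep in range(3):
            cells = [c for c in scheme.cells() if c.repeat == rep]
            union = np.concatenate([c.test_idx for c in cells])
            assert sorted(union) == list(range(120))
            for c in cells:
                assert set(c.val_idx).isdisjoint(c.test_idx)
                assert set(c.train_idx).isdisjoint(c.test_idx)
                assert set(c.train_idx).isdisjoint(c.val_idx)

    @pytest.mark.parametrize("seed", range(10))
    def test_stratification_within_one_patient_of_proportionality(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 7, 140)
        folds = 5
        scheme = make_partitions(y, repeats=1, folds=folds, seed=seed)
        tot = np.bincount(y, minlength=7)
        for cell in scheme.cells():
            counts = np.bincount(y[cell.test_idx], minlength=7)
            for c in range(7):
                assert abs(counts[c] - tot[c] / folds) <= 1.0

    def test_category_smaller_than_folds_is_error(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match="fewer patients"):
            make_partitions(y, repeats=1, folds=5)


class TestSomersDxy:
    def test_perfect_concordance(self):
        y = np.repeat(np.arange(7), 3)
        s = np.argsort(np.argsort(y)) + 0.0
        assert float(somers_dxy(s, y)) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        y = rng.integers(0, 7, n)
        s = np.round(rng.normal(size=n), 1)  # coarse -> plenty of ties
        expected = brute_force_dxy(s, y)
        got = somers_dxy(s, y)
        if expected is None:
            assert got.value is None
        else:
            assert got.value == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 7, 100)
        s = rng.normal(size=100)
        a = float(somers_dxy(s, y))
        b = float(somers_dxy(np.exp(2 * s) + 5, y))
        assert a == pytest.approx(b, abs=1e-12)

    def test_null_scores_near_zero(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 7, 10_000)
        s = rng.normal(size=10_000)
        assert abs(float(somers_dxy(s, y))) < 0.03

    def test_degenerate_outcomes_reported_as_undefined(self):
        res = somers_dxy([1.0, 2.0, 3.0], [4, 4, 4])
        assert res.value is None
        assert "identical" in res.reason
        with pytest.raises(ValueError):
            float(res)


class TestCalibration:
    def test_self_consistent_probabilities_give_unit_slope(self):
        rng = np.random.default_rng(0)
        q = rng.uniform(0.05, 0.95, size=10_000)
        y = (rng.random(10_000) < q).astype(int)
        res = calibration_slope(q, y)
        assert 0.9 <= res.slope <= 1.1

    def test_logit_shrinkage_by_two_recovers_slope_two(self):
        rng = np.random.default_rng(1)
        q = rng.uniform(0.02, 0.98, size=10_000)
        y = (rng.random(10_000) < q).astype(int)
        lo = np.log(q / (1 - q))
        q_shrunk = sigmoid(lo / 2)  # underfit direction
        res = calibration_slope(q_shrunk, y)
        assert 1.8 <= res.slope <= 2.2

    def test_constant_predictions_undefined_with_reason(self):
        res = calibration_slope(np.full(100, 0.4), np.tile([0, 1], 50))
        assert res.slope is None
        assert "constant" in res.reason

    def test_single_class_outcome_reported_missing(self):
        res = calibration_slope(np.linspace(0.1, 0.9, 50), np.zeros(50))
        assert res.slope is None

    def test_mean_slope_averages_over_cuts(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=5000)
        theta = np.array([-2, -1.1, -0.4, 0.2, 0.9, 1.8])
        q = sigmoid(s[:, None] - theta)
        u = rng.random(5000)
        cum = np.concatenate(
            [np.zeros((5000, 1)), 1 - q], axis=1
        )  # P(Y <= k)
        y = (u[:, None] > cum[:, 1:]).sum(axis=1)
        slope = mean_calibration_slope(q, y)
        assert 0.9 <= slope <= 1.1

    def test_calibrated_curve_error_vanishes_with_n(self):
        rng = np.random.default_rng(3)
        q = rng.uniform(0.05, 0.95, size=20_000)
        y = (rng.random(20_000) < q).astype(int)
        curve = calibration_curve(q, y)
        assert curve.mace <= 0.02

    def test_constant_half_predictions_balanced_outcomes(self):
        q = np.full(2000, 0.5)
        y = np.tile([0, 1], 1000)
        curve = calibration_curve(q, y)
        assert curve.mace == pytest.approx(0.0, abs=1e-9)

    def test_anticalibrated_predictions_match_closed_form(self):
        rng = np.random.default_rng(4)
        q = rng.uniform(0.1, 0.9, size=20_000)
        y = (rng.random(20_000) < q).astype(int)
        curve = calibration_curve(1 - q, y)
        # smoothed curve approximates E[y | 1-q = g] = 1 - g; the error vs
        # the diagonal is mean |1 - 2g| over the grid
        expected = np.mean(np.abs(1 - 2 * curve.grid))
        assert curve.mace == pytest.approx(expected, abs=0.03)

    def test_tiny_sample_widens_span_with_warning(self):
        rng = np.random.default_rng(5)
        q = rng.uniform(0.2, 0.8, 12)
        y = (rng.random(12) < q).astype(int)
        with pytest.warns(UserWarning, match="span"):
            calibration_curve(q, y, span=0.1)


class TestBBCCV:
    def _null_scores(self, rng, n, k):
        return rng.normal(size=(n, k))

    def test_single_configuration_reduces_to_plain_bootstrap(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 7, 300)
        s = y + rng.normal(scale=2.0, size=300)
        res = bbc_cv_interval(s[:, None], y, n_boot=300, seed=1)
        base = float(somers_dxy(s, y))
        assert res.ci_lo <= base <= res.ci_hi
        assert res.naive_best == pytest.approx(base)
        assert abs(res.estimate - base) < 0.05

    def test_dominant_configuration_always_selected(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 7, 200)
        good = y + rng.normal(scale=0.5, size=200)
        noise = rng.normal(size=200)
        res = bbc_cv_interval(
            np.column_stack([noise, good]), y, n_boot=200, seed=2
        )
        assert res.best_config_counts[1] == res.best_config_counts.sum()

    def test_pure_noise_configurations_optimism_corrected(self):
        rng = np.random.default_rng(2)
        n, k = 150, 20
        y = rng.integers(0, 7, n)
        scores = rng.normal(size=(n, k))  # every config is noise, truth = 0
        res = bbc_cv_interval(scores, y, n_boot=400, seed=3)
        assert res.naive_best > res.estimate
        assert res.ci_lo <= 0.0 <= res.ci_hi

    def test_degenerate_constant_metric_zero_width_interval(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        scores = rng.normal(size=(100, 3))
        res = bbc_cv_interval(
            scores, y, metric_fn=lambda s, o: 0.42, n_boot=100, seed=4
        )
        assert res.ci_lo == res.ci_hi == pytest.approx(0.42)


def _toy_trajectory(pid, scores, y):
    T = len(scores)
    q = sigmoid(np.asarray(scores)[:, None] - np.linspace(-1, 1, 6))
    from icucourse.trajectory_model import threshold_to_class

    return Trajectory(pid, threshold_to_class(q), q, y)


class TestMetricTimeseries:
    def test_equal_stay_lengths_make_alignments_mirror_images(self):
        rng = np.random.default_rng(0)
        trajs = []
        for i in range(120):
            y = int(rng.integers(0, 7))
            s = y / 2 + rng.normal(scale=0.8, size=4)
            trajs.append(_toy_trajectory(f"P{i}", s, y))
        fwd = metric_timeseries(
            trajs, window_h=24, alignment="from_admission", horizon_h=96,
            n_boot=50, min_patients=10,
        )
        bwd = metric_timeseries(
            trajs, window_h=24, alignment="to_discharge", horizon_h=96,
            n_boot=50, min_patients=10,
        )
        fwd_vals = [p.estimate for p in fwd]
        bwd_vals = [p.estimate for p in bwd]
        assert fwd_vals == pytest.approx(bwd_vals[::-1])

    def test_sparse_timepoints_suppressed(self):
        rng = np.random.default_rng(1)
        trajs = [
            _toy_trajectory(
                f"P{i}",
                rng.normal(size=2 if i < 95 else 8),
                int(rng.integers(0, 7)),
            )
            for i in range(100)
        ]
        pts = metric_timeseries(
            trajs, window_h=24, horizon_h=192, n_boot=20, min_patients=50
        )
        assert all(p.n_patients >= 50 for p in pts)
        assert max(p.timepoint_h for p in pts) <= 2 * 24
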