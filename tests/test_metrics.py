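import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gaitffdb import (
    ConfigurationError,
    DataError,
    ExperimentBatch,
    error_distribution,
    icc,
    moving_average,
    msearr,
    relative_differences,
)


class TestMsearr:
    def test_hand_computed_case(self):
        score = msearr(ExperimentBatch(rmse=np.array([10.0, 20.0]), dist_avg=150.0))
        assert score.value == pytest.approx(0.1)
        assert score.sd == pytest.approx(np.std([10 / 150, 20 / 150], ddof=1))

    def test_exact_predictions_score_zero(self):
        assert msearr(ExperimentBatch(rmse=np.zeros(5), dist_avg=137.42)).value == 0.0

    @given(c=st.floats(0.01, 1e4))
    def test_scale_invariance(self, c):
        base = np.array([5.0, 12.0, 9.0])
        a = msearr(ExperimentBatch(rmse=base, dist_avg=140.0))
        b = msearr(ExperimentBatch(rmse=c * base, dist_avg=c * 140.0))
        assert b.value == pytest.approx(a.value, rel=1e-12)
        assert b.sd == pytest.approx(a.sd, rel=1e-9)

    def test_mostly_failed_configuration_hits_ceiling(self):
        score = msearr(ExperimentBatch(rmse=np.array([5.0]), dist_avg=100.0, n_failed=2))
        assert score.value == 1.0
        assert score.at_failure_ceiling
        ok = msearr(ExperimentBatch(rmse=np.array([5.0, 6.0]), dist_avg=100.0, n_failed=1))
        assert not ok.at_failure_ceiling

    def test_no_usable_experiments_hits_ceiling(self):
        score = msearr(ExperimentBatch(rmse=np.array([]), dist_avg=100.0, n_failed=3))
        assert score.value == 1.0 and score.n_used == 0

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError, match="dist_avg"):
            msearr(ExperimentBatch(rmse=np.array([1.0]), dist_avg=0.0))
        with pytest.raises(DataError):
            ExperimentBatch(rmse=np.array([np.inf]), dist_avg=100.0)


class TestMovingAverage:
    def test_hand_computed_fixture(self):
        np.testing.assert_allclose(
            moving_average([1, 2, 3, 4, 5], 3), [1.5, 2, 3, 4, 4.5]
        )

    def test_constant_series_unchanged(self):
        np.testing.assert_array_equal(moving_average([5, 5, 5], 3), [5, 5, 5])

    def test_single_element(self):
        np.testing.assert_array_equal(moving_average([7.0], 3), [7.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_length_preserved(self, series):
        assert len(moving_average(series, 3)) == len(series)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError, match="odd"):
            moving_average([1, 2, 3], 2)


class TestErrorDistribution:
    def test_all_exact(self):
        d = error_distribution([100.0, 150.0], [100.0, 150.0])
        assert (d["frac_lt_15m"], d["frac_15_to_25m"], d["frac_gt_25m"]) == (1.0, 0.0, 0.0)

    def test_one_per_band(self):
        d = error_distribution([110.0, 120.0, 130.0], [100.0, 100.0, 100.0])
        assert d["frac_lt_15m"] == pytest.approx(1 / 3)
        assert d["frac_15_to_25m"] == pytest.approx(1 / 3)
        assert d["frac_gt_25m"] == pytest.approx(1 / 3)

    @given(st.integers(0, 1000))
    def test_fractions_partition(self, seed):
        rng = np.random.default_rng(seed)
        actual = rng.uniform(50, 250, 40)
        pred = actual + rng.normal(0, 20, 40)
        d = error_distribution(pred, actual)
        assert d["frac_lt_15m"] + d["frac_15_to_25m"] + d["frac_gt_25m"] == pytest.approx(
            1.0, abs=1e-12
        )
        assert sum(d["histogram_counts"]) == 40

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            error_distribution([], [])


class TestRelativeDifferences:
    def test_hand_computed(self):
        d = relative_differences([100.0], [110.0])
        assert d["absolute_m"][0] == pytest.approx(10.0)
        assert d["relative"][0] == pytest.approx(0.10)

    def test_perfect_prediction(self):
        d = relative_differences([120.0, 80.0], [120.0, 80.0])
        assert d["mean_absolute_m"] == 0.0 and d["mean_relative"] == 0.0

    def test_matches_direct_recomputation(self, rng):
        m = rng.uniform(50, 250, 30)
        p = m + rng.normal(0, 15, 30)
        d = relative_differences(m, p)
        np.testing.assert_allclose(d["absolute_m"], np.abs(p - m))
        np.testing.assert_allclose(d["relative"], np.abs(p - m) / m)
        assert d["mean_absolute_m"] == pytest.approx(np.abs(p - m).mean())

    def test_nonpositive_measured_rejected(self):
        with pytest.raises(DataError):
            relative_differences([100.0, 0.0], [90.0, 10.0])


def _anova_icc21(data: np.ndarray) -> float:
    """Textbook two-way ANOVA ICC(2,1), written out sum by sum."""
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * sum((data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )


class TestICC:
    def test_perfect_agreement(self):
        m = np.array([100.0, 120.0, 140.0, 90.0])
        r = icc(m, m.copy())
        assert r.estimate == 1.0
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)

    def test_matches_anova_mean_squares_oracle(self, rng):
        m = rng.uniform(80, 200, 25)
        p = m + rng.normal(0, 12, 25)
        r = icc(m, p)
        assert r.estimate == pytest.approx(_anova_icc21(np.column_stack([m, p])), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        m = rng.uniform(80, 200, 30)
        p = m + rng.normal(0, 10, 30)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 2),
            "rater": np.tile(["a", "b"], 30),
            "value": np.column_stack([m, p]).ravel(),
        })
        row = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="value").set_index("Type").loc["ICC(A,1)"]
        assert icc(m, p).estimate == pytest.approx(float(row["ICC"]), abs=1e-12)

    def test_independent_pairs_score_near_zero(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(50, 250, 10000)
        shuffled = rng.permutation(m)
        assert abs(icc(m, shuffled).estimate) < 0.05

    def test_symmetric_in_rater_labels(self, rng):
        m = rng.uniform(80, 200, 20)
        p = m + rng.normal(0, 10, 20)
        a, b = icc(m, p), icc(p, m)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.ci_low == pytest.approx(b.ci_low, abs=1e-12)

    def test_ci_contains_estimate(self, rng):
        m = rng.uniform(80, 200, 15)
        p = m + rng.normal(0, 25, 15)
        r = icc(m, p)
        assert r.ci_low <= r.estimate <= r.ci_high

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError, match="at least 3"):
            icc([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DataError, match="undefined"):
            icc([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
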