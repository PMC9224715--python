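import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitffdb import (
    BenchmarkError,
    ConfigurationError,
    FFDBPlan,
    FFDBSearch,
    SyntheticSpec,
    estimate_space,
    generate,
    lr_grid,
    planned_stage_runs,
    run_ffdb,
    select_optimal_lr,
)
from gaitffdb.benchmark import select_winner


class TestEstimateSpace:
    def test_identity(self):
        assert estimate_space(1, 1, 1, 1, 1) == 1

    def test_small_product(self):
        assert estimate_space(2, 3, 2, 2, 2) == 48

    def test_rejects_non_positive_counts(self):
        with pytest.raises(ConfigurationError):
            estimate_space(0, 1, 1, 1, 1)


class TestLrGrid:
    def test_log_spacing_with_inclusive_bounds(self):
        grid = lr_grid(FFDBPlan(c_lr=6))
        assert len(grid) == 6
        assert grid[0] == pytest.approx(1e-6)
        assert grid[-1] == pytest.approx(1e-1)
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_single_point_grid(self):
        assert lr_grid(FFDBPlan(c_lr=1)).tolist() == [1e-6]


class TestSelectOptimalLr:
    def test_v_shaped_curve(self):
        lrs = [1e-4, 1e-3, 1e-2, 1e-1, 1.0]
        assert select_optimal_lr(lrs, [3, 2, 1, 2, 3]) == 1e-2

    def test_monotone_decreasing_picks_largest(self):
        lrs = [1e-4, 1e-3, 1e-2]
        assert select_optimal_lr(lrs, [3, 2, 1]) == 1e-2

    def test_smoothing_overrides_a_noise_spike(self):
        lrs = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        values = [10.0, 1.0, 10.0, 4.0, 4.2, 4.1]
        # raw argmin is the spike at lr=2; the window-3 moving average
        # ([5.5, 7, 5, 6.07, 4.1, 4.15]) bottoms out at lr=5
        assert np.argmin(values) == 1
        assert select_optimal_lr(lrs, values) == 5.0

    def test_tie_breaks_toward_smaller_lr(self):
        assert select_optimal_lr([1.0, 2.0, 3.0, 4.0], [5, 5, 5, 5]) == 1.0

    def test_too_short_curve_rejected(self):
        with pytest.raises(ConfigurationError):
            select_optimal_lr([1e-3, 1e-2], [1, 2])


class TestSelectWinner:
    def test_minimum_wins(self):
        assert select_winner({"Adam": 0.2, "SGD": 0.1}, ("Adam", "SGD")) == "SGD"

    def test_tie_resolves_by_plan_order(self):
        assert select_winner({"SGD": 0.1, "Adam": 0.1}, ("Adam", "SGD")) == "Adam"

    @given(st.integers(0, 10_000))
    def test_adding_a_worse_algorithm_never_changes_the_winner(self, seed):
        rng = np.random.default_rng(seed)
        order = ("SGD", "RMSProp", "Adam", "Adadelta", "Adagrad", "Adamax", "Nadam")
        names = list(rng.permutation(order[:4]))
        scores = {n: float(rng.uniform(0.01, 0.9)) for n in names}
        winner = select_winner(scores, order)
        worse = order[4]
        scores[worse] = max(scores.values()) + 0.1
        assert select_winner(scores, order) == winner

    def test_empty_comparison_rejected(self):
        with pytest.raises(BenchmarkError):
            select_winner({}, ())


def _micro_table(seed=5, n=24, p=3):
    spec = SyntheticSpec(n_patients=n, n_features=p,
                         informative_indices=(0,), informative_weights=(1.0,),
                         noise_rel=0.05, missing_rate=0.0, outlier_rate=0.0, seed=seed)
    return generate(spec)[0]


def _micro_plan(**overrides):
    defaults = dict(
        algorithms=("Adam",), n_exp=1, n_epoch=2, c_lr=2, lr_bounds=(1e-4, 1e-3),
        spreads=(1.0, 2.0), depths=(1, 2), sweep_spread=1.0, sweep_depth=1,
        probe_lr=1e-4, batch_size=16,
    )
    defaults.update(overrides)
    return FFDBPlan(**defaults)


class TestRunAccounting:
    def test_documented_example_totals_eight_runs(self):
        # 1 algorithm, c_LR=2, 2x2 grid, n_exp=1: 1 calibration + 2 sweep
        # + 4 grid + 1 comparison runs
        report = run_ffdb(_micro_plan(), _micro_table(), master_seed=1)
        assert report.run_count == 8
        per_stage = {}
        for rec in report.run_log:
            per_stage[rec["stage"]] = per_stage.get(rec["stage"], 0) + 1
        assert per_stage == {"calibration": 1, "lr_sweep": 2, "shape_grid": 4, "compare": 1}

    def test_counter_matches_closed_form_for_varied_plans(self):
        table = _micro_table()
        for seed in range(3):
            rng = np.random.default_rng(seed)
            plan = _micro_plan(
                algorithms=tuple(rng.permutation(["Adam", "SGD"])[: rng.integers(1, 3)]),
                n_exp=int(rng.integers(1, 3)),
                c_lr=int(rng.integers(1, 4)),
                spreads=tuple(float(s) for s in rng.choice([0.5, 1.0, 2.0], size=rng.integers(1, 3), replace=False)),
                depths=tuple(int(d) for d in rng.choice([1, 2], size=rng.integers(1, 3), replace=False)),
            )
            report = run_ffdb(plan, table, master_seed=seed)
            expected = planned_stage_runs(plan)
            per_stage = {}
            for rec in report.run_log:
                per_stage[rec["stage"]] = per_stage.get(rec["stage"], 0) + 1
            assert per_stage == expected
            assert report.run_count == sum(expected.values())


@pytest.fixture(scope="module")
def search():
    return FFDBSearch(plan=_micro_plan(n_exp=2, n_epoch=4), master_seed=7).fit_table(
        _micro_table(n=40)
    )


class TestBenchmarkReportContent:
    def test_best_config_carries_full_configuration(self, search):
        best = search.best_config_
        assert set(best) >= {"algorithm", "learning_rate", "spread", "depth", "n_epoch"}
        assert best["algorithm"] == "Adam"
        assert best["n_epoch"] == 4

    def test_decision_path_is_recorded_per_stage(self, search):
        stages = search.report_.stages
        assert list(stages) == ["calibration", "lr_sweep", "shape_grid", "compare"]
        assert "Adam" in stages["lr_sweep"]["selected"]
        assert stages["compare"]["winner"] == "Adam"

    def test_every_grid_configuration_has_a_record(self, search):
        grid = search.report_.stages["shape_grid"]["records"]["Adam"]
        assert {(s, d) for s, d, *_ in grid} == {(1.0, 1), (1.0, 2), (2.0, 1), (2.0, 2)}

    def test_winner_distribution_and_pairs_present(self, search):
        winner = search.report_.winner
        fracs = winner["error_distribution"]
        assert fracs["frac_lt_15m"] + fracs["frac_15_to_25m"] + fracs["frac_gt_25m"] == pytest.approx(1.0)
        assert len(winner["prediction_pairs"]) == 2 * 8  # n_exp * validation rows

    def test_ensemble_prediction_has_row_per_patient(self, search):
        table = _micro_table(n=40)
        preds = search.predict(table.features)
        assert preds.shape == (40,)
        assert np.isfinite(preds).all()

    def test_reverse_weight_table_covers_every_feature(self, search):
        assert len(search.rsw_table_) == 3
        assert len(search.report_.reverse_weight_table) == 3


class TestFailurePolicy:
    def test_diverging_algorithm_is_excluded_with_warning(self):
        table = _micro_table(n=30)
        plan = _micro_plan(algorithms=("SGD", "Adam"), lr_bounds=(1e5, 1e6),
                           n_epoch=3, probe_lr=1e-6)
        # SGD explodes at these rates; Adam's bounded steps survive
        with pytest.warns(UserWarning, match="SGD"):
            report = run_ffdb(plan, table, master_seed=2)
        assert "SGD" in report.excluded_algorithms
        assert report.best_config["algorithm"] == "Adam"

    def test_all_algorithms_diverging_is_fatal(self):
        table = _micro_table(n=30)
        plan = _micro_plan(algorithms=("SGD",), lr_bounds=(1e5, 1e6), n_epoch=3)
        with pytest.raises(BenchmarkError, match="every algorithm diverged"), pytest.warns(UserWarning):
            run_ffdb(plan, table, master_seed=2)

    def test_negative_master_seed_rejected(self):
        with pytest.raises(ConfigurationError, match="master_seed"):
            FFDBSearch(plan=_micro_plan(), master_seed=-1).fit_table(_micro_table())
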