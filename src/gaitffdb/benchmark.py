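"""Staged fractional-factorial benchmark over the training configuration space.

A full factorial sweep of the four-dimensional configuration space
(learning rate x hidden width factor x depth x training algorithm, with
``n_exp`` repeated experiments per point) is far beyond desk scale:
:func:`estimate_space` makes that explicit. The benchmark instead walks a
transparent fraction in a fixed stage order, freezing one factor per stage:

1. epoch calibration — every algorithm once at a small probe learning rate
   and the mid-size shape, producing loss-history evidence that the epoch
   budget suffices (informational; the budget is never changed adaptively);
2. learning-rate sweep — a log-spaced grid per algorithm at the mid-size
   shape; the per-algorithm optimum is the minimum of the moving-averaged
   score curve;
3. shape grid — width-factor x depth grid per algorithm at its optimal
   learning rate;
4. final comparison — fresh repeated experiments per algorithm at its
   optimized configuration; the minimum-score algorithm wins.

Every training run is derived from the master seed through a stable
per-(stage, algorithm, configuration, experiment) seed, re-splitting the
data and re-initializing the network each time, and every run is logged, so
any stage can be reproduced in isolation from the report alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import BenchmarkError, ConfigurationError
from .importance import rsw_table
from .io import FeatureTable
from .metrics import ExperimentBatch, QualityScore, error_distribution, moving_average, msearr
from .network import ALGORITHMS, DistanceMLPRegressor
from .preprocess import GaitPreprocessor, SplitSpec, split

__all__ = [
    "FFDBPlan", "FFDBSearch", "BenchmarkReport", "estimate_space", "lr_grid",
    "planned_stage_runs", "select_optimal_lr", "select_winner", "run_ffdb",
]

_STAGE_CODES = {"calibration": 1, "lr_sweep": 2, "shape_grid": 3, "compare": 4}


def estimate_space(n_exp: int, c_lr: int, c_spread: int, c_depth: int, c_alg: int) -> int:
    """Total runs of the hypothetical full factorial: the product of all five counts."""
    counts = (n_exp, c_lr, c_spread, c_depth, c_alg)
    if any(int(c) != c or c < 1 for c in counts):
        raise ConfigurationError(f"all counts must be positive integers, got {counts}")
    return int(np.prod([int(c) for c in counts]))


@dataclass(frozen=True)
class FFDBPlan:
    """The benchmark's configuration grids and repetition counts.

    Defaults reproduce the published study scale: 7 algorithms, 50
    log-spaced learning rates in [1e-6, 1e-1], 6x6 shape grid, 10 repeated
    experiments per configuration, 1000 epochs.
    """

    algorithms: tuple[str, ...] = ALGORITHMS
    n_exp: int = 10
    n_epoch: int = 1000
    c_lr: int = 50
    lr_bounds: tuple[float, float] = (1e-6, 1e-1)
    spreads: tuple[float, ...] = (1, 2, 3, 4, 5, 6)
    depths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    sweep_spread: float = 3.0
    sweep_depth: int = 3
    probe_lr: float = 1e-4
    train_fraction: float = 0.8
    outlier_k: float = 4.0
    batch_size: int = 32

    def __post_init__(self) -> None:
        from ._optim import canonical_algorithm

        object.__setattr__(self, "algorithms",
                           tuple(canonical_algorithm(a) for a in self.algorithms))
        if len(set(self.algorithms)) != len(self.algorithms) or not self.algorithms:
            raise ConfigurationError("algorithms must be a non-empty set of distinct names")
        if self.n_exp < 1 or self.n_epoch < 1 or self.c_lr < 1:
            raise ConfigurationError("n_exp, n_epoch and c_lr must be positive")
        lo, hi = self.lr_bounds
        if not (0 < lo <= hi):
            raise ConfigurationError(f"learning-rate bounds must satisfy 0 < low <= high, got {self.lr_bounds}")
        if self.c_lr > 1 and lo == hi:
            raise ConfigurationError("c_lr > 1 requires low < high learning-rate bounds")
        if not self.spreads or not self.depths:
            raise ConfigurationError("shape grids must be non-empty")

    def to_dict(self) -> dict:
        # JSON-safe: tuples become lists so reports round-trip exactly
        return {k: list(v) if isinstance(v, tuple) else v
                for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, payload: dict) -> "FFDBPlan":
        payload = dict(payload)
        for key in ("algorithms", "lr_bounds", "spreads", "depths"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def lr_grid(plan: FFDBPlan) -> np.ndarray:
    """c_lr learning rates, logarithmically equispaced, bounds inclusive."""
    lo, hi = plan.lr_bounds
    if plan.c_lr == 1:
        return np.array([lo])
    return np.geomspace(lo, hi, plan.c_lr)


def planned_stage_runs(plan: FFDBPlan, n_algorithms: int | None = None) -> dict[str, int]:
    """Closed-form training-run counts per stage (calibration counted separately)."""
    a = len(plan.algorithms) if n_algorithms is None else n_algorithms
    return {
        "calibration": a,
        "lr_sweep": plan.n_exp * plan.c_lr * a,
        "shape_grid": plan.n_exp * len(plan.spreads) * len(plan.depths) * a,
        "compare": plan.n_exp * a,
    }


def _derive_seed(master: int, stage: str, alg_idx: int, config_idx: int, exp_idx: int) -> int:
    ss = np.random.SeedSequence([int(master), _STAGE_CODES[stage], alg_idx, config_idx, exp_idx])
    return int(ss.generate_state(1)[0] % 2**31)


def select_optimal_lr(lrs, values, window: int = 3) -> float:
    """Learning rate at the minimum of the moving-averaged score curve.

    The raw per-point scores are noisy across repeated experiments, so the
    selection smooths first; ties resolve toward the smaller rate.
    """
    lrs = np.asarray(lrs, dtype=float)
    values = np.asarray(values, dtype=float)
    if lrs.size < window:
        raise ConfigurationError(f"curve has {lrs.size} points, need >= window ({window})")
    order = np.argsort(lrs)
    smoothed = moving_average(values[order], window)
    return float(lrs[order][int(np.argmin(smoothed))])


def select_winner(scores: dict[str, float], order: tuple[str, ...]) -> str:
    """Minimum-score algorithm; ties resolve by position in the plan's order."""
    if not scores:
        raise BenchmarkError("no surviving algorithms to compare")
    return min(scores, key=lambda alg: (scores[alg], order.index(alg)))


@dataclass
class BenchmarkReport:
    """Complete, JSON-serializable record of one benchmark execution.

    ``stages`` maps stage name to its records and selections (the decision
    path); ``run_log`` holds one entry per executed training run with its
    derived seed, so any stage can be re-run in isolation and compared.
    """

    plan: dict
    master_seed: int
    stages: dict = field(default_factory=dict)
    best_config: dict | None = None
    winner: dict | None = None
    reverse_weight_table: list | None = None
    excluded_algorithms: dict = field(default_factory=dict)
    run_log: list = field(default_factory=list)
    run_count: int = 0
    run_config: dict | None = None

    STAGE_ORDER = ("calibration", "lr_sweep", "shape_grid", "compare")

    @property
    def partial(self) -> bool:
        return any(s not in self.stages for s in self.STAGE_ORDER)

    def to_dict(self) -> dict:
        return {
            "plan": self.plan,
            "master_seed": self.master_seed,
            "partial": self.partial,
            "stages": self.stages,
            "best_config": self.best_config,
            "winner": self.winner,
            "reverse_weight_table": self.reverse_weight_table,
            "excluded_algorithms": self.excluded_algorithms,
            "run_log": self.run_log,
            "run_count": self.run_count,
            "run_config": self.run_config,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BenchmarkReport":
        return cls(
            plan=payload["plan"],
            master_seed=payload["master_seed"],
            stages=payload["stages"],
            best_config=payload.get("best_config"),
            winner=payload.get("winner"),
            reverse_weight_table=payload.get("reverse_weight_table"),
            excluded_algorithms=payload.get("excluded_algorithms", {}),
            run_log=payload.get("run_log", []),
            run_count=payload.get("run_count", 0),
            run_config=payload.get("run_config"),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BenchmarkReport):
            return NotImplemented
        return self.to_dict() == other.to_dict()


class FFDBSearch(BaseEstimator):
    """Staged benchmark as a fit-once meta-estimator.

    ``fit`` executes the four stages on a feature matrix and measured
    distances; afterwards ``predict`` averages the ensemble of winning
    models (one per repeated final experiment, each with its own
    train-fitted preprocessor), which is the recommended deployment mode
    given the run-to-run volatility of single networks.

    Attributes
    ----------
    report_ : :class:`BenchmarkReport`
    best_config_ : dict with algorithm, learning_rate, spread, depth, n_epoch.
    best_models_ : list of (regressor, preprocessor) pairs from the winner's
        final-stage experiments.
    rsw_table_ : ensemble-averaged reverse-weight table of the winner.
    run_count_ : executed training runs (matches the closed-form counts).
    """

    def __init__(self, plan: FFDBPlan | None = None, master_seed: int = 0):
        self.plan = plan
        self.master_seed = master_seed

    # ------------------------------------------------------------------ api

    def fit(self, X, y) -> "FFDBSearch":
        if isinstance(X, pd.DataFrame):
            features = X.copy()
        else:
            X = np.asarray(X, dtype=float)
            features = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        table = FeatureTable(
            features=features.reset_index(drop=True),
            target=pd.Series(np.asarray(y, dtype=float), name="distance_m"),
            patient_id=pd.RangeIndex(len(features)),
        )
        return self.fit_table(table)

    def fit_table(self, table: FeatureTable) -> "FFDBSearch":
        plan = self.plan if self.plan is not None else FFDBPlan()
        if int(self.master_seed) < 0:
            raise ConfigurationError("master_seed must be non-negative")
        dist_avg = float(table.target.dropna().mean())
        if not np.isfinite(dist_avg) or dist_avg <= 0:
            raise ConfigurationError("mean measured distance must be positive")
        self.dist_avg_ = dist_avg
        self.run_count_ = 0
        report = BenchmarkReport(plan=plan.to_dict(), master_seed=int(self.master_seed))

        self._calibrate(plan, table, report)
        surviving = self._lr_sweep(plan, table, report)
        shapes = self._shape_grid(plan, table, report, surviving)
        self._compare(plan, table, report, shapes)

        report.run_count = self.run_count_
        self.report_ = report
        return self

    def predict(self, X) -> np.ndarray:
        preds = [model.predict(prep.transform(self._frame(X)))
                 for model, prep in self.best_models_]
        return np.mean(preds, axis=0)

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    # --------------------------------------------------------------- stages

    def _experiment(self, plan: FFDBPlan, table: FeatureTable, stage: str,
                    alg_idx: int, config_idx: int, exp_idx: int,
                    algorithm: str, learning_rate: float, spread: float, depth: int,
                    n_epoch: int | None = None):
        """One seeded training run: fresh split, fresh preprocessing, fresh init."""
        run_seed = _derive_seed(self.master_seed, stage, alg_idx, config_idx, exp_idx)
        s_split, s_net = (int(v % 2**31)
                          for v in np.random.SeedSequence(run_seed).generate_state(2))
        train, val = split(table, SplitSpec(plan.train_fraction, s_split))
        prep = GaitPreprocessor(outlier_k=plan.outlier_k).fit(train.features)
        model = DistanceMLPRegressor(
            spread=spread, depth=depth, algorithm=algorithm,
            learning_rate=learning_rate, n_epoch=n_epoch or plan.n_epoch,
            batch_size=plan.batch_size, random_state=s_net,
        ).fit(prep.transform(train.features), train.target.to_numpy())
        self.run_count_ += 1

        if model.failed_:
            rmse, failed = None, True
        else:
            pred = model.predict(prep.transform(val.features))
            err = pred - val.target.to_numpy()
            rmse = float(np.sqrt(np.mean(err**2)))
            failed = not np.isfinite(rmse)
            rmse = rmse if not failed else None
        record = {
            "stage": stage, "algorithm": algorithm, "learning_rate": float(learning_rate),
            "spread": float(spread), "depth": int(depth), "experiment": exp_idx,
            "seed": run_seed, "rmse_m": rmse, "failed": failed,
        }
        pairs = None
        if not failed:
            pairs = np.column_stack([val.target.to_numpy(), pred])
        return record, model, prep, pairs

    def _score(self, records: list[dict]) -> QualityScore:
        usable = [r["rmse_m"] for r in records if not r["failed"]]
        return msearr(ExperimentBatch(
            rmse=np.array(usable), dist_avg=self.dist_avg_,
            n_failed=sum(r["failed"] for r in records),
        ))

    def _calibrate(self, plan: FFDBPlan, table: FeatureTable, report: BenchmarkReport) -> None:
        records = {}
        for a, alg in enumerate(plan.algorithms):
            rec, model, _, _ = self._experiment(
                plan, table, "calibration", a, 0, 0,
                alg, plan.probe_lr, plan.sweep_spread, plan.sweep_depth,
            )
            report.run_log.append(rec)
            hist = model.loss_history_
            tail = hist[-max(2, int(np.ceil(0.1 * len(hist)))):]
            plateau = (
                len(hist) >= 2
                and np.isfinite(tail).all()
                and tail[0] > 0
                and (tail[0] - tail[-1]) / tail[0] < 0.01
            )
            records[alg] = {
                "probe_lr": plan.probe_lr, "loss_history": [float(v) for v in hist],
                "plateau": bool(plateau), "seed": rec["seed"],
            }
        report.stages["calibration"] = {"n_epoch": plan.n_epoch, "records": records}

    def _lr_sweep(self, plan: FFDBPlan, table: FeatureTable, report: BenchmarkReport) -> list[str]:
        grid = lr_grid(plan)
        records: dict[str, list] = {}
        selected: dict[str, float] = {}
        surviving = []
        for a, alg in enumerate(plan.algorithms):
            curve = []
            any_usable = False
            for c, lr in enumerate(grid):
                runs = []
                for e in range(plan.n_exp):
                    rec, *_ = self._experiment(
                        plan, table, "lr_sweep", a, c, e,
                        alg, lr, plan.sweep_spread, plan.sweep_depth,
                    )
                    report.run_log.append(rec)
                    runs.append(rec)
                score = self._score(runs)
                any_usable = any_usable or score.n_used > 0
                curve.append([float(lr), score.value, score.sd, score.n_failed])
            records[alg] = curve
            if not any_usable:
                warnings.warn(f"every learning-rate run failed for {alg}; excluding it")
                report.excluded_algorithms[alg] = "all learning-rate sweep runs failed"
                continue
            window = min(3, len(grid) if len(grid) % 2 else len(grid) - 1) or 1
            selected[alg] = select_optimal_lr(
                [c[0] for c in curve], [c[1] for c in curve], window=window
            )
            surviving.append(alg)
        report.stages["lr_sweep"] = {"records": records, "selected": selected}
        if not surviving:
            raise BenchmarkError("every algorithm diverged across the whole learning-rate grid")
        return surviving

    def _shape_grid(self, plan: FFDBPlan, table: FeatureTable, report: BenchmarkReport,
                    surviving: list[str]) -> dict[str, tuple[float, int]]:
        selected_lr = report.stages["lr_sweep"]["selected"]
        records: dict[str, list] = {}
        best_shape: dict[str, tuple[float, int]] = {}
        for a, alg in enumerate(plan.algorithms):
            if alg not in surviving:
                continue
            grid_records = []
            best = None
            for c, (spread, depth) in enumerate(
                (s, d) for s in plan.spreads for d in plan.depths
            ):
                runs = []
                for e in range(plan.n_exp):
                    rec, *_ = self._experiment(
                        plan, table, "shape_grid", a, c, e,
                        alg, selected_lr[alg], spread, depth,
                    )
                    report.run_log.append(rec)
                    runs.append(rec)
                score = self._score(runs)
                grid_records.append([float(spread), int(depth), score.value,
                                     score.sd, score.n_failed])
                # strict < keeps the first optimum: smaller spread, then depth
                if best is None or score.value < best[0]:
                    best = (score.value, spread, depth)
            records[alg] = grid_records
            best_shape[alg] = (best[1], best[2])
        report.stages["shape_grid"] = {
            "records": records,
            "selected": {alg: [float(s), int(d)] for alg, (s, d) in best_shape.items()},
        }
        return best_shape

    def _compare(self, plan: FFDBPlan, table: FeatureTable, report: BenchmarkReport,
                 shapes: dict[str, tuple[float, int]]) -> None:
        selected_lr = report.stages["lr_sweep"]["selected"]
        records: dict[str, dict] = {}
        scores: dict[str, float] = {}
        artifacts: dict[str, tuple] = {}
        for a, alg in enumerate(plan.algorithms):
            if alg not in shapes:
                continue
            spread, depth = shapes[alg]
            runs, models, pair_list = [], [], []
            for e in range(plan.n_exp):
                rec, model, prep, pairs = self._experiment(
                    plan, table, "compare", a, 0, e, alg, selected_lr[alg], spread, depth,
                )
                report.run_log.append(rec)
                runs.append(rec)
                if pairs is not None:
                    models.append((model, prep))
                    pair_list.append(pairs)
            score = self._score(runs)
            records[alg] = {
                "learning_rate": selected_lr[alg], "spread": float(spread),
                "depth": int(depth), "msearr": score.value, "sd": score.sd,
                "n_failed": score.n_failed,
            }
            scores[alg] = score.value
            artifacts[alg] = (models, pair_list)

        winner = select_winner(scores, plan.algorithms)
        report.stages["compare"] = {"records": records, "winner": winner}
        report.best_config = {
            "algorithm": winner, "learning_rate": records[winner]["learning_rate"],
            "spread": records[winner]["spread"], "depth": records[winner]["depth"],
            "n_epoch": plan.n_epoch, "msearr": records[winner]["msearr"],
            "sd": records[winner]["sd"],
        }
        models, pair_list = artifacts[winner]
        if not models:
            raise BenchmarkError(f"winning algorithm {winner} has no usable final models")
        all_pairs = np.vstack(pair_list)
        report.winner = {
            "algorithm": winner,
            "error_distribution": error_distribution(all_pairs[:, 1], all_pairs[:, 0]),
            "prediction_pairs": all_pairs.tolist(),
        }
        self.best_models_ = models
        self.best_config_ = report.best_config
        table_rsw = rsw_table([m for m, _ in models], table.feature_names)
        self.rsw_table_ = table_rsw
        report.reverse_weight_table = table_rsw[["feature", "reverse_weight"]].values.tolist()


def run_ffdb(plan: FFDBPlan, table: FeatureTable, master_seed: int = 0) -> BenchmarkReport:
    """Execute the full staged benchmark on a feature table; returns the report."""
    return FFDBSearch(plan=plan, master_seed=master_seed).fit_table(table).report_
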