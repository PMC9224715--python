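"""Prediction-quality, smoothing, distribution, and reliability metrics.

The central score is the average relative rooted mean square error: the mean
over repeated experiments of each experiment's validation RMSE (meters),
divided by the dataset's global mean measured distance. Dividing by one
global scale makes scores comparable across datasets and use cases; a score
of 1.0 means the typical prediction error equals the average walking
distance, which is also the ceiling assigned to diverged configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

#: absolute-error band edges (meters) for the prediction-quality summary
GOOD_ERROR_M = 15.0
OUTLIER_ERROR_M = 25.0

#: score assigned to configurations where training predominantly diverged
FAILURE_CEILING = 1.0


@dataclass
class ExperimentBatch:
    """Validation RMSEs of repeated experiments for one configuration.

    ``rmse`` holds only usable (finite) per-experiment values; diverged runs
    are counted in ``n_failed``. ``dist_avg`` is the global mean measured
    distance of the full dataset, in meters.
    """

    rmse: np.ndarray
    dist_avg: float
    n_failed: int = 0
    prediction_pairs: np.ndarray | None = None  # columns: measured, predicted

    def __post_init__(self) -> None:
        self.rmse = np.asarray(self.rmse, dtype=float)
        if self.rmse.size and (not np.isfinite(self.rmse).all() or (self.rmse < 0).any()):
            raise DataError("RMSE values must be finite and non-negative")

    @property
    def n_exp(self) -> int:
        return self.rmse.size + self.n_failed


@dataclass
class QualityScore:
    value: float
    sd: float
    n_used: int
    n_failed: int
    at_failure_ceiling: bool = False


def msearr(batch: ExperimentBatch) -> QualityScore:
    """Average relative rooted mean square error with its SD.

    Returns the mean of ``rmse / dist_avg`` over usable experiments and the
    sample SD (ddof=1) of the same ratios. Failed-run policy: if more than
    half of the experiments diverged, or none are usable, the configuration
    is scored at the ceiling of 1.0 (100% relative error).
    """
    if batch.dist_avg <= 0:
        raise ConfigurationError(f"dist_avg must be positive, got {batch.dist_avg}")
    n_used = batch.rmse.size
    if n_used == 0 or batch.n_failed > batch.n_exp / 2:
        return QualityScore(FAILURE_CEILING, 0.0, n_used, batch.n_failed, True)
    rel = batch.rmse / batch.dist_avg
    sd = float(np.std(rel, ddof=1)) if n_used > 1 else 0.0
    return QualityScore(float(rel.mean()), sd, n_used, batch.n_failed)


def moving_average(series, window: int = 3) -> np.ndarray:
    """Centered moving average; the window shrinks at the series edges.

    Each output point is the mean of the input points inside the centered
    window intersected with the series bounds, so the output has the same
    length as the input and a constant series is left unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"window must be a positive odd integer, got {window}")
    series = pd.Series(np.asarray(series, dtype=float))
    if series.empty:
        raise ConfigurationError("cannot smooth an empty series")
    return series.rolling(window, center=True, min_periods=1).mean().to_numpy()


def error_distribution(predictions, actuals) -> dict:
    """Absolute-error band fractions plus histogram/scatter export data.

    Bands: |error| < 15 m (good), 15-25 m (moderate), > 25 m (outliers);
    the three fractions always sum to 1. The histogram uses 5 m bins of
    signed errors (predicted - measured).
    """
    predictions = np.asarray(predictions, dtype=float)
    actuals = np.asarray(actuals, dtype=float)
    if predictions.size == 0 or predictions.shape != actuals.shape:
        raise DataError("predictions and actuals must be equal-length and non-empty")
    signed = predictions - actuals
    abs_err = np.abs(signed)
    n = abs_err.size
    frac_good = float((abs_err < GOOD_ERROR_M).sum() / n)
    frac_outlier = float((abs_err > OUTLIER_ERROR_M).sum() / n)
    frac_moderate = 1.0 - frac_good - frac_outlier
    lo = np.floor(signed.min() / 5.0) * 5.0
    hi = np.ceil(signed.max() / 5.0) * 5.0
    if hi <= lo:
        edges = np.array([lo, lo + 5.0])
    elif (hi - lo) / 5.0 > 200:  # wild predictions: cap the bin count
        edges = np.linspace(lo, hi, 201)
    else:
        edges = np.arange(lo, hi + 5.0, 5.0)
    counts, edges = np.histogram(signed, bins=edges)
    return {
        "frac_lt_15m": frac_good,
        "frac_15_to_25m": frac_moderate,
        "frac_gt_25m": frac_outlier,
        "histogram_counts": counts.tolist(),
        "histogram_edges_m": edges.tolist(),
        "scatter_pairs": np.column_stack([actuals, predictions]).tolist(),
    }


def relative_differences(measured, predicted) -> dict:
    """Per-patient absolute (m) and relative differences, as absolute values."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if (measured <= 0).any():
        raise DataError("measured distances must be strictly positive")
    absolute = np.abs(predicted - measured)
    relative = absolute / measured
    return {
        "absolute_m": absolute,
        "relative": relative,
        "mean_absolute_m": float(absolute.mean()),
        "sd_absolute_m": float(np.std(absolute, ddof=1)) if absolute.size > 1 else 0.0,
        "mean_relative": float(relative.mean()),
        "sd_relative": float(np.std(relative, ddof=1)) if relative.size > 1 else 0.0,
    }


@dataclass
class ICCResult:
    """Intraclass correlation estimate with its 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    variance_components: dict = field(default_factory=dict)


def icc(measured, predicted) -> ICCResult:
    """Agreement between measured and predicted distances.

    Two-way random-effects, absolute-agreement, single-measure ICC(2,1) —
    the standard form for method comparison, here treating the manual
    odometer measurement and the model prediction as two raters of every
    patient. Computed from the two-way ANOVA mean squares, with the 95%
    confidence interval from the McGraw-Wong F-based construction.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.ndim != 1:
        raise DataError("measured and predicted must be equal-length vectors")
    n = measured.size
    if n < 3:
        raise DataError(f"need at least 3 paired observations for an ICC, got {n}")
    data = np.column_stack([measured, predicted])
    if np.ptp(data.mean(axis=1)) == 0:
        raise DataError("between-subject variance is zero; ICC is undefined")

    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.var(row_means, ddof=1)                    # between subjects
    msc = n * np.var(col_means, ddof=1)                    # between raters
    sst = ((data - grand) ** 2).sum()
    mse = (sst - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
    mse = max(mse, 0.0)                                    # guard tiny negative roundoff
    components = {"ms_rows": float(msr), "ms_cols": float(msc), "ms_error": float(mse)}

    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    estimate = float((msr - mse) / denom)

    if np.allclose(data[:, 0], data[:, 1]):                # perfect agreement
        return ICCResult(1.0, 1.0, 1.0, components)

    from scipy.stats import f as f_dist

    alpha = 0.05
    a = k * estimate / (n * (1.0 - estimate))
    b = 1.0 + k * estimate * (n - 1) / (n * (1.0 - estimate))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f_up = f_dist.ppf(1 - alpha / 2, v, n - 1)
    ci_low = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return ICCResult(estimate, float(min(ci_low, estimate)),
                     float(max(ci_high, estimate)), components)
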