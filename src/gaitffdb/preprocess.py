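"""Imputation, outlier clipping, z-scoring, and seeded train/validation splits.

All statistics are fitted on training rows only and then applied unchanged to
validation rows, so no information leaks from the held-out set into the
preprocessing model. The target (measured distance in meters) is never
transformed: the regressor predicts meters directly, so reported errors stay
in meters.

Order of operations inside the fitted transform: impute missing cells with
the training mean of the observed entries, clip to mean +/- k*SD (winsorize
rather than drop, preserving the patient count), then standardize with the
center/scale of the imputed-and-clipped training matrix. Population SD
(ddof=0) is used throughout; constant features get scale 1 so the transform
stays well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, DataError
from .io import FeatureTable


@dataclass(frozen=True)
class SplitSpec:
    """Seeded random train/validation partition.

    train_fraction must lie strictly inside (0, 1); the training size is
    round-half-away-from-zero of ``train_fraction * n`` so that 500 rows at
    0.8 give exactly 400 training and 100 validation rows.
    """

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


def split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Partition a table into disjoint train/validation tables.

    The same seed always yields the same index sets; different seeds draw
    independent permutations.
    """
    n = table.n_patients
    if n < 5:
        raise ConfigurationError(f"need at least 5 rows to split, got {n}")
    n_train = int(np.floor(spec.train_fraction * n + 0.5))  # round half away from zero
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(spec.seed).permutation(n)
    return table.take(np.sort(perm[:n_train])), table.take(np.sort(perm[n_train:]))


class GaitPreprocessor(TransformerMixin, BaseEstimator):
    """Train-fitted impute -> clip -> z-score transformer for feature matrices.

    Parameters
    ----------
    outlier_k : float, default 4.0
        Half-width of the clipping band in training SDs around the training
        mean of the observed entries.

    Attributes
    ----------
    feature_names_in_ : list of column names seen at fit time.
    impute_values_ : per-feature training mean of observed entries.
    clip_lower_, clip_upper_ : winsorization bounds.
    center_, scale_ : standardization parameters (after impute + clip).
    """

    def __init__(self, outlier_k: float = 4.0):
        self.outlier_k = outlier_k

    def fit(self, X: pd.DataFrame, y=None) -> "GaitPreprocessor":
        if self.outlier_k <= 0:
            raise ConfigurationError(f"outlier_k must be positive, got {self.outlier_k}")
        X = self._as_frame(X)
        if len(X) == 0:
            raise ConfigurationError("cannot fit preprocessor on an empty table")
        values = X.to_numpy(dtype=float)
        observed = ~np.isnan(values)
        n_obs = observed.sum(axis=0)
        if (n_obs == 0).any():
            name = X.columns[int(np.flatnonzero(n_obs == 0)[0])]
            raise DataError(f"feature {name!r} has no observed training entries")

        with np.errstate(invalid="ignore"):
            mean_obs = np.nanmean(values, axis=0)
            sd_obs = np.nanstd(values, axis=0)  # ddof=0
        self.impute_values_ = mean_obs
        self.clip_lower_ = mean_obs - self.outlier_k * sd_obs
        self.clip_upper_ = mean_obs + self.outlier_k * sd_obs

        treated = np.where(observed, values, mean_obs)
        treated = np.clip(treated, self.clip_lower_, self.clip_upper_)
        self.center_ = treated.mean(axis=0)
        scale = treated.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        self.feature_names_in_ = list(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._as_frame(X)
        if list(X.columns) != self.feature_names_in_:
            raise ConfigurationError(
                "feature columns do not match the fitted preprocessor "
                f"(got {len(X.columns)} columns, fitted on {len(self.feature_names_in_)})"
            )
        values = X.to_numpy(dtype=float)
        values = np.where(np.isnan(values), self.impute_values_, values)
        values = np.clip(values, self.clip_lower_, self.clip_upper_)
        values = (values - self.center_) / self.scale_
        return pd.DataFrame(values, columns=self.feature_names_in_, index=X.index)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def fit_preprocess(train: FeatureTable, outlier_k: float = 4.0) -> GaitPreprocessor:
    """Fit the impute/clip/standardize model on training rows only."""
    return GaitPreprocessor(outlier_k=outlier_k).fit(train.features)


def apply_preprocess(model: GaitPreprocessor, table: FeatureTable) -> FeatureTable:
    """Apply a fitted preprocessor; the target passes through untouched."""
    return FeatureTable(
        features=model.transform(table.features),
        target=table.target.copy(),
        patient_id=table.patient_id,
    )
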