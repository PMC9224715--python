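"""Synthetic gait-feature tables with the statistical structure of a 2MWT study.

The generator emulates a cohort of patients who each completed a 2-minute
walk test while wearing body-worn inertial sensors: one latent
walking-ability factor per patient drives both the measured distance and a
small set of informative spatiotemporal features (cadence-, speed- and
stride-like, with realistic units in the column names), while the remaining
columns are correlated nuisance features that mimic the redundancy of
left/right/aggregate sensor outputs without carrying signal. Distance gets
multiplicative noise; missing cells and gross outliers are injected at
configurable rates. Everything is deterministic given the seed.

Defaults target the published cohort scale: 511 patients, 92 features, mean
distance ~137 m with ~33 m spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import FeatureTable

_INFORMATIVE_NAMES = (
    ("Lower Limb - Cadence R (steps/min)", 110.0, 12.0),
    ("Lower Limb - Gait Speed R (m/s)", 1.15, 0.30),
    ("Lower Limb - Gait Speed L (m/s)", 1.15, 0.30),
    ("Lower Limb - Stride Length L (m)", 1.25, 0.28),
    ("Lower Limb - Cadence L (steps/min)", 110.0, 12.0),
)

_NUISANCE_TEMPLATES = (
    ("Lower Limb - Swing {s} (%GCT)", 38.0, 3.0),
    ("Lower Limb - Step Duration {s} (s)", 0.55, 0.08),
    ("Lower Limb - Double Support {s} (%GCT)", 24.0, 5.0),
    ("Lower Limb - Terminal Double Support {s} (%GCT)", 12.0, 3.0),
    ("Upper Limb - Arm Range of Motion {s} (degrees)", 28.0, 9.0),
    ("Upper Limb - Arm Swing Velocity {s} (degrees/s)", 160.0, 45.0),
    ("Trunk - Lateral Range of Motion {s} (degrees)", 6.0, 2.0),
    ("Trunk - Sagittal Range of Motion {s} (degrees)", 4.5, 1.5),
    ("Lumbar - Coronal Range of Motion {s} (degrees)", 7.0, 2.5),
    ("Lower Limb - Circumduction {s} (cm)", 2.5, 1.2),
    ("Lower Limb - Toe Off Angle {s} (degrees)", 36.0, 6.0),
    ("Lower Limb - Elevation at Midswing {s} (cm)", 1.8, 0.9),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic cohort.

    noise_rel is the SD of the multiplicative noise on the measured distance;
    feature_noise_rel (defaults to noise_rel when None) plays the same role
    for the informative features, so a fully zero-noise specification makes
    the distance an exact function of each informative feature.
    """

    n_patients: int = 511
    n_features: int = 92
    informative_indices: tuple[int, ...] = (3, 17, 31, 55, 80)
    informative_weights: tuple[float, ...] = (1.0, 0.95, 0.9, 0.85, 0.8)
    noise_rel: float = 0.05
    feature_noise_rel: float | None = None
    missing_rate: float = 0.02
    outlier_rate: float = 0.005
    seed: int = 0
    dist_center: float = 137.0
    dist_spread: float = 33.0
    nuisance_rank: int = 5
    nuisance_idiosyncratic: float = 0.15

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_features < 1:
            raise ConfigurationError("n_patients and n_features must be positive")
        if not 0 <= self.missing_rate < 0.5 or not 0 <= self.outlier_rate < 0.5:
            raise ConfigurationError("missing_rate and outlier_rate must lie in [0, 0.5)")
        if self.noise_rel < 0:
            raise ConfigurationError("noise_rel must be non-negative")
        if self.feature_noise_rel is not None and self.feature_noise_rel < 0:
            raise ConfigurationError("feature_noise_rel must be non-negative")
        if len(self.informative_indices) != len(self.informative_weights):
            raise ConfigurationError("informative_indices and informative_weights differ in length")
        if len(set(self.informative_indices)) != len(self.informative_indices):
            raise ConfigurationError("informative_indices must be unique")
        if self.informative_indices and not all(
            0 <= i < self.n_features for i in self.informative_indices
        ):
            raise ConfigurationError("informative_indices out of range")
        if self.dist_center <= 0 or self.dist_spread < 0:
            raise ConfigurationError("dist_center must be positive, dist_spread non-negative")
        if not 0 < self.nuisance_idiosyncratic <= 1:
            raise ConfigurationError("nuisance_idiosyncratic must lie in (0, 1]")

    @property
    def effective_feature_noise(self) -> float:
        return self.noise_rel if self.feature_noise_rel is None else self.feature_noise_rel


def feature_names(spec: SyntheticSpec) -> list[str]:
    """Deterministic MLS-style column names; informative slots get gait-central names."""
    informative = set(spec.informative_indices)
    names: list[str] = []
    info_iter = iter(range(len(spec.informative_indices)))
    nuisance_pool = [
        (tpl.format(s=side), c, s)
        for tpl, c, s in _NUISANCE_TEMPLATES
        for side in ("R", "L")
    ]
    n_pool = 0
    for j in range(spec.n_features):
        if j in informative:
            k = next(info_iter)
            names.append(_INFORMATIVE_NAMES[k % len(_INFORMATIVE_NAMES)][0])
        elif n_pool < len(nuisance_pool):
            names.append(nuisance_pool[n_pool][0])
            n_pool += 1
        else:
            names.append(f"Sensor Aggregate {j:02d} (a.u.)")
    # de-duplicate (informative names may repeat beyond five)
    seen: dict[str, int] = {}
    unique = []
    for name in names:
        if name in seen:
            seen[name] += 1
            unique.append(name.replace(" (", f" #{seen[name]} ("))
        else:
            seen[name] = 1
            unique.append(name)
    return unique


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, dict]:
    """Draw one cohort; returns the table and the generating ground truth.

    The ground-truth record carries the latent walking-ability values, the
    informative index set with the per-feature affine coefficients, and the
    distance model, enabling recovery tests without the clinical data.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_patients, spec.n_features

    latent = rng.standard_normal(n)
    # keep the noiseless distance strictly positive (tail beyond ~4 SD)
    floor = (1.0 - spec.dist_center) / spec.dist_spread if spec.dist_spread > 0 else -np.inf
    for _ in range(100):
        bad = latent <= floor
        if not bad.any():
            break
        latent[bad] = rng.standard_normal(bad.sum())
    clean = spec.dist_center + spec.dist_spread * latent
    distance = clean * (1.0 + spec.noise_rel * rng.standard_normal(n))
    for _ in range(100):
        bad = distance <= 1.0
        if not bad.any():
            break
        distance[bad] = clean[bad] * (1.0 + spec.noise_rel * rng.standard_normal(bad.sum()))
    distance = np.maximum(distance, 1.0)

    names = feature_names(spec)
    X = np.empty((n, p))
    fnoise = spec.effective_feature_noise
    informative = dict(zip(spec.informative_indices, spec.informative_weights))
    slopes: dict[int, tuple[float, float]] = {}

    # correlated nuisance structure: shared low-rank factors, independent of the latent
    factors = rng.standard_normal((n, spec.nuisance_rank))
    nuisance_meta = [
        (tpl.format(s=side), c, s) for tpl, c, s in _NUISANCE_TEMPLATES for side in ("R", "L")
    ]
    n_pool = 0
    for j in range(p):
        if j in informative:
            k = list(informative).index(j)
            _, center, scale = _INFORMATIVE_NAMES[k % len(_INFORMATIVE_NAMES)]
            w = informative[j]
            X[:, j] = center + scale * (w * latent + fnoise * rng.standard_normal(n))
            slopes[j] = (center, scale * w)
        else:
            if n_pool < len(nuisance_meta):
                _, center, scale = nuisance_meta[n_pool]
                n_pool += 1
            else:
                center, scale = 10.0 + 0.5 * j, 2.0 + 0.05 * j
            loading = rng.standard_normal(spec.nuisance_rank)
            loading /= np.linalg.norm(loading)
            shared = factors @ loading
            # aggregated per-patient means: variance dominated by shared
            # mobility traits, small within-patient averaging noise
            idio = spec.nuisance_idiosyncratic
            X[:, j] = center + scale * (
                np.sqrt(1.0 - idio**2) * shared + idio * rng.standard_normal(n)
            )

    if spec.outlier_rate > 0:
        mask = rng.random((n, p)) < spec.outlier_rate
        col_scale = np.array([slopes.get(j, (0, 0))[1] or X[:, j].std() or 1.0 for j in range(p)])
        col_scale = np.where(col_scale == 0, 1.0, np.abs(col_scale))
        signs = rng.choice([-1.0, 1.0], size=(n, p))
        X = np.where(mask, X + signs * 8.0 * col_scale, X)
    if spec.missing_rate > 0:
        X = np.where(rng.random((n, p)) < spec.missing_rate, np.nan, X)

    table = FeatureTable(
        features=pd.DataFrame(X, columns=names),
        target=pd.Series(distance, name="distance_m"),
        patient_id=pd.RangeIndex(n),
    )
    truth = {
        "latent": latent,
        "informative_indices": tuple(spec.informative_indices),
        "informative_names": [names[j] for j in spec.informative_indices],
        "feature_affine": slopes,  # index -> (intercept, slope) w.r.t. the latent
        "distance_model": (spec.dist_center, spec.dist_spread),
        "spec": spec,
    }
    return table, truth
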