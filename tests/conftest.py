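import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cohort():
    """An 80-patient, 8-feature synthetic cohort with known ground truth."""
    from gaitffdb import SyntheticSpec, generate

    spec = SyntheticSpec(
        n_patients=80, n_features=8,
        informative_indices=(1, 4), informative_weights=(1.0, 0.9),
        noise_rel=0.05, missing_rate=0.02, outlier_rate=0.01, seed=42,
    )
    return generate(spec)
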