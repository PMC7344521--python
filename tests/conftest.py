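import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small fully rendered noise-free cohort shared across pipeline tests."""
    from spinemetry.motion_sim import NoiseSpec, default_cohort_spec, generate_cohort

    spec = default_cohort_spec(n_per_group=4)
    return generate_cohort(spec, noise=NoiseSpec.noiseless(), seed=7, render="full")
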