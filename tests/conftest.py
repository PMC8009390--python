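import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-person cohort reused by scoring/pipeline tests."""
    from lhstudy.cohort import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(n_total=30, rng_seed=7))
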