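import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One mid-sized synthetic cohort shared by read-only tests."""
    from coda_activity import synthetic

    cohort, truth = synthetic.generate_cohort(
        synthetic.CohortSpec(n_participants=600, seed=42)
    )
    return cohort, truth
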