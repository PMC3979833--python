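import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dilipipe import adjudicate_cohort, generate_cohort, published_uln
from dilipipe.simulate import SimConfig


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic cohort shared across the suite."""
    cohort, truth = generate_cohort(SimConfig(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def default_calls(default_sim):
    cohort, _ = default_sim
    return adjudicate_cohort(cohort, published_uln()).calls


@pytest.fixture(scope="session")
def uln():
    return published_uln()
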