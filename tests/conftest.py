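import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from nutriscreen import CohortConfig, expand_contingency_fixture, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default calibrated cohort (250 assessed + 918 unassessed), seed 7."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def assessed_only_cohort():
    return generate_cohort(CohortConfig(n_unassessed=0, seed=11))


@pytest.fixture(scope="session")
def pseudo_cohorts():
    """Per-element pseudo-cohorts expanded from the bundled counts."""
    return expand_contingency_fixture()
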