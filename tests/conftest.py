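import datetime

import pytest
from hypothesis import HealthCheck, settings

from allocsim.cohort import CohortMarginals, generate_candidates, generate_donors

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def marginals():
    return CohortMarginals.default()


@pytest.fixture(scope="session")
def candidate_pool(marginals):
    """A mid-sized candidate pool shared across tests (read-only)."""
    return generate_candidates(2000, marginals, seed=42)


@pytest.fixture(scope="session")
def donor_pool(marginals):
    return generate_donors(
        400, marginals, seed=42,
        start_date=datetime.date(2010, 1, 1), end_date=datetime.date(2011, 12, 31),
    )
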