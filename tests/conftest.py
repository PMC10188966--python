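import pytest
from hypothesis import HealthCheck, settings

import thyropmx as tx
from thyropmx.cohort import CohortConfig, generate_cohort

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pk_params() -> tx.PKParameters:
    return tx.PKParameters()


@pytest.fixture(scope="session")
def pd_params() -> tx.PDParameters:
    return tx.PDParameters()


@pytest.fixture(scope="session")
def default_pop() -> tx.PopulationParameters:
    return tx.PopulationParameters()


@pytest.fixture(scope="session")
def small_cohort(default_pop):
    """A small but realistic cohort shared across estimation tests."""
    return generate_cohort(CohortConfig(n_patients=8), default_pop, rng_seed=3)


@pytest.fixture(scope="session")
def full_cohort(default_pop):
    """A full-size (n=44) cohort at the packaged truths."""
    return generate_cohort(CohortConfig(), default_pop, rng_seed=11)


def constant_tid_regimen(daily_mg: float, n_days: int):
    from thyropmx.events import tid_doses

    return [e for d in range(n_days) for e in tid_doses(daily_mg, float(d))]


@pytest.fixture(scope="session")
def tid_regimen_30d():
    return constant_tid_regimen(22.6, 30)
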