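import numpy as np
import pytest

from devalsim import PopulationParams, get_preset, simulate_cohort


@pytest.fixture(scope="session")
def cohort_a_config():
    return get_preset("cohortA")


@pytest.fixture(scope="session")
def cohort_b_config():
    return get_preset("cohortB")


@pytest.fixture(scope="session")
def small_cohort(cohort_a_config):
    """Eight agents through the shorter (cohort-A) protocol."""
    return simulate_cohort(8, cohort_a_config, PopulationParams(), rng_seed=3)


@pytest.fixture(scope="session")
def full_cohort(cohort_b_config):
    """A study-sized cohort (65 agents, 22 explicit) with default effects."""
    return simulate_cohort(65, cohort_b_config, PopulationParams(), rng_seed=7)


@pytest.fixture(scope="session")
def full_report(full_cohort):
    from devalsim.pipeline import analyze_cohort

    return analyze_cohort(full_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
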