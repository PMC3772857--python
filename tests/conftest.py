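import pytest

from pancrisk import published_coefficients
from pancrisk.synth import SimulationConfig, no_missingness, simulate_life_table, \
    simulate_population


@pytest.fixture(scope="session")
def coeffs():
    return published_coefficients()


@pytest.fixture(scope="session")
def small_sample():
    """Complete-data simulated sample at reduced scale, shared across tests."""
    config = no_missingness(SimulationConfig(n_cases=800, n_controls=900, seed=42))
    return simulate_population(config)


@pytest.fixture(scope="session")
def paper_scale_sample():
    """One complete-data draw at the pooled-consortium sample size."""
    config = no_missingness(SimulationConfig(seed=7))
    return simulate_population(config)


@pytest.fixture(scope="session")
def male_life_table():
    return simulate_life_table("male")


@pytest.fixture(scope="session")
def female_life_table():
    return simulate_life_table("female")
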