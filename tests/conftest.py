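import numpy as np
import pytest

from mhcrq.engine import run_simulation
from mhcrq.populations import ScenarioConfig
from mhcrq.recognition import MatchRule


@pytest.fixture
def rule16():
    return MatchRule(16, 7)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def tiny_run():
    """A small but non-trivial Red Queen run shared by several tests."""
    config = ScenarioConfig(
        scenario="RQ",
        n_hosts=40,
        n_species=8,
        antigens_per_pathogen=5,
        mu_pathogen=5e-3,
        host_site_mutation_rate=2e-4,
        burn_in=20,
        recorded_generations=80,
        seed=42,
    )
    return run_simulation(config)
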