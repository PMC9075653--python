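import numpy as np
import pytest

import pesim
from pesim.reference import GrowthReference


@pytest.fixture(scope="session")
def ref():
    return GrowthReference.packaged()


@pytest.fixture()
def cfg():
    return pesim.SimConfig()


@pytest.fixture(scope="session")
def small_pop():
    """A 1,500-agent cohort shared by read-only tests."""
    cfg = pesim.SimConfig()
    cfg.population.n_agents = 1_500
    return cfg, pesim.generate_population(cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
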