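import logging

import numpy as np
import pytest

from potsim import SimulationConfig, run_iteration

logging.getLogger("potsim").setLevel(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(master_seed=0)


@pytest.fixture(scope="session")
def one_iteration(default_config):
    """A single full pipeline replication, shared across tests."""
    return run_iteration(default_config, 0)
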