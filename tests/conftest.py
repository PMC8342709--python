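import numpy as np
import pytest

from wmdecode.bold import simulate_timeseries
from wmdecode.design import generate_design, generate_training_design
from wmdecode.iem import ChannelBasis
from wmdecode.population import generate_population


@pytest.fixture(scope="session")
def basis():
    return ChannelBasis()


@pytest.fixture(scope="session")
def population():
    return generate_population(120, seed=7)


@pytest.fixture(scope="session")
def training_session(population, basis):
    """Noiseless, un-z-scored training session and its trial design."""
    design = generate_training_design(4, seed=11)
    ts = simulate_timeseries(design, population, noise_sd=0.0, seed=12,
                             zscore=False)
    return design, ts


@pytest.fixture(scope="session")
def task_design():
    return generate_design(10, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
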