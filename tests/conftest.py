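import numpy as np
import pytest
from hypothesis import settings

from bifinfer import NoiseSpec, SolverConfig, Theta, TimeGrid, generate_observation

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

ALL_MODELS = [
    "saddle_node",
    "transcritical",
    "pitchfork_supercritical",
    "pitchfork_subcritical",
]


@pytest.fixture(scope="session")
def cfg():
    return SolverConfig()


@pytest.fixture(scope="session")
def grid1000():
    return TimeGrid(n_obs=1000)


@pytest.fixture(scope="session")
def grid10():
    return TimeGrid(n_obs=10)


@pytest.fixture(scope="session")
def saddle_obs_noiseless(grid1000):
    """Noiseless saddle-node data from theta_true = (1, 1.5)."""
    return generate_observation(
        "saddle_node", Theta(1.0, 1.5), grid1000, NoiseSpec(0.0), seed=0
    )
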