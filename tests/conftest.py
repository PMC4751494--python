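import numpy as np
import pandas as pd
import pytest

from mirnet.matrix import CountMatrix
from mirnet.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_sequences,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """One shared synthetic dataset: (mirna matrix, gene matrix, truth)."""
    return simulate_counts(sim_config)


@pytest.fixture(scope="session")
def sim_sequences(sim_config, sim_data):
    _, _, truth = sim_data
    return simulate_sequences(sim_config, truth)


@pytest.fixture()
def toy_counts() -> CountMatrix:
    data = pd.DataFrame(
        {
            "s1": [10, 20, 30, 0],
            "s2": [12, 18, 33, 1],
            "s3": [50, 100, 150, 2],
            "s4": [55, 95, 160, 0],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    groups = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    return CountMatrix(data, groups=groups)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(202)
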