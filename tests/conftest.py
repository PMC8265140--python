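import numpy as np
import pandas as pd
import pytest

from healthineq import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=12345)


@pytest.fixture(scope="session")
def small_survey(default_config) -> pd.DataFrame:
    """~3,500 individuals from the default generator settings."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def large_survey() -> pd.DataFrame:
    """~50,000 individuals; shared across the heavier recovery checks."""
    cfg = SimulationConfig(seed=777, n_clusters=1430, households_per_cluster=25)
    return generate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
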