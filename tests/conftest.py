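import numpy as np
import pytest

from nitriso import ColumnConfig, simulate_column


@pytest.fixture(scope="session")
def default_config() -> ColumnConfig:
    return ColumnConfig()


@pytest.fixture(scope="session")
def default_column(default_config):
    """Noise-free synthetic column under the default configuration."""
    return simulate_column(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
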