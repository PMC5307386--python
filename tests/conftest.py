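import numpy as np
import pytest

from socmap import SyntheticConfig, assemble_dataset

DOMAIN = (0.0, 0.0, 40_000.0, 70_000.0)


@pytest.fixture(scope="session")
def default_dataset():
    """One fixed draw of the default 111-plot synthetic survey."""
    return assemble_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_coords(default_dataset):
    return default_dataset[["x", "y"]].to_numpy(dtype=float)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
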