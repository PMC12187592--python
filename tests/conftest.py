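import numpy as np
import pytest

from wsmial.config import WSMIALConfig
from wsmial.proposals import AnchorSet, build_grid
from wsmial.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_grid():
    return build_grid(64, 8, AnchorSet.preset("tiny64"))


@pytest.fixture(scope="session")
def small_dataset():
    """50 seeded synthetic samples shared across read-only tests."""
    return generate_dataset(SyntheticSpec(seed=11), 50)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def fast_config():
    """Config shrunk for unit-test speed; method semantics unchanged."""
    return WSMIALConfig(epoch=2, n_restarts=1, final_restarts=1,
                        final_epochs=2, pretrain_epochs=2)
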