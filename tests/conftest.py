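import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plinet.model import ModelConfig, PLIModel
from plinet.training import init_parameters

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TINY_MODEL_CONFIG = dict(
    protein_shape=(20, 48),
    ligand_shape=(64, 24),
    protein_block_channels=(4, 4, 4),
    ligand_block_channels=(4, 4, 4),
    embedding_dim=8,
    dense_units=(8, 4, 1),
)


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(**TINY_MODEL_CONFIG)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return PLIModel(tiny_config)


@pytest.fixture(scope="session")
def tiny_params(tiny_model):
    return init_parameters(tiny_model, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_onehot(rng, rows, cols, n, density=0.9):
    """Batch of valid one-hot matrices with a few all-zero (padding) columns."""
    X = np.zeros((n, rows, cols))
    for i in range(n):
        filled = rng.random(cols) < density
        choices = rng.integers(0, rows, size=cols)
        X[i, choices[filled], np.flatnonzero(filled)] = 1.0
    return X
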