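import numpy as np
import pytest

from emit.model import EMITConfig, init_model_state
from emit.motifs import build_dictionary


@pytest.fixture(scope="session")
def dict_k4():
    return build_dictionary(4)


@pytest.fixture(scope="session")
def dict_k2():
    return build_dictionary(2)


@pytest.fixture(scope="session")
def tiny_model(dict_k2):
    """Small untrained encoder over the k=2 vocabulary (20 tokens)."""
    config = EMITConfig(
        hidden_size=16, num_heads=2, num_layers=1,
        vocab_size=dict_k2.vocab_size, max_positions=18, dropout_rate=0.1,
    )
    return init_model_state(config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
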