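import numpy as np
import pytest

from ftda import (DecoderTrainConfig, ToyTextEncoder, make_standard_fixture,
                  train_decoder)


@pytest.fixture(scope="session")
def fixture_bundle():
    """The canonical simulated study corpus (seed 0)."""
    return make_standard_fixture(seed=0)


@pytest.fixture(scope="session")
def unit_encoder():
    return ToyTextEncoder(d_text=16, seed=0)


@pytest.fixture(scope="session")
def small_decoder(unit_encoder):
    """A quickly trained decoder over three labels, shared across unit tests."""
    texts = ["clip applied", "hook dissection", "irrigation"] * 20
    cfg = DecoderTrainConfig(seed=0, epochs=6, batch_size=16, preset="mini",
                             max_length=8)
    return train_decoder(texts, unit_encoder, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
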