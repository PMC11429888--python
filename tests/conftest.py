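import numpy as np
import pytest

from scprofile.backbone import EncoderConfig
from scprofile.model import ModelConfig, ProfileModel


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained model shared by structural tests."""
    cfg = ModelConfig(
        encoder=EncoderConfig(input_length=2048, channels=32, seed=0),
        embedding_dim=6,
        seed=0,
    )
    return ProfileModel(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_sequence():
    r = np.random.default_rng(7)
    return "".join(r.choice(list("ACGT"), 2048))
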