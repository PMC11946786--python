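import numpy as np
import pytest

from echomasa.model import ModelConfig, assemble_model
from echomasa.phantom import PhantomConfig, generate_clip


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(image_size=64)


@pytest.fixture(scope="session")
def phantom_record(phantom_config):
    return generate_clip(phantom_config, seed=3)


@pytest.fixture(scope="session")
def reduced_model():
    """A small but complete model instance shared across read-only tests."""
    return assemble_model(ModelConfig.reduced(image_size=64, channels=1), seed=1)
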