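import numpy as np
import pytest

from vesselkd.model import ModelConfig
from vesselkd.phantom import PhantomConfig, generate_sample


@pytest.fixture(scope="session")
def tiny_phantom_cfg() -> PhantomConfig:
    return PhantomConfig.default(image_size=64, seed=1)


@pytest.fixture(scope="session")
def tiny_samples(tiny_phantom_cfg):
    """A small in-memory phantom set shared across training tests."""
    return [generate_sample(tiny_phantom_cfg, i) for i in range(20)]


@pytest.fixture(scope="session")
def tiny_model_cfg() -> ModelConfig:
    return ModelConfig(base_width=4, depth=2, aspp_rates=(2,), seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
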