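import numpy as np
import pytest

from needletrack import PhantomConfig, generate_sample


@pytest.fixture(scope="session")
def desk_config() -> PhantomConfig:
    """Noiseless single-coil 64-pixel phantom configuration."""
    return PhantomConfig.desk(rng_seed=3)


@pytest.fixture(scope="session")
def desk_sample(desk_config):
    """One noiseless dynamic sample shared across read-only tests."""
    return generate_sample(desk_config, sample_id="desk")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
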