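import numpy as np
import pytest

from advseg.config import RunConfig
from advseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# small, fast study objects shared across test modules -----------------

TINY_CFG = dict(
    patch_size=16, stride=8, batch_size=2, steps=4,
    scales=2, base_channels=4, disc_channels=(4, 8, 8, 8),
)


@pytest.fixture
def tiny_config():
    return RunConfig(alpha=0.0, seed=3, **TINY_CFG)


@pytest.fixture
def tiny_adv_config():
    return RunConfig(alpha=0.15, seed=3, **TINY_CFG)


@pytest.fixture(scope="session")
def small_phantoms():
    """Three small phantom cases for training-shaped tests."""
    return [
        generate_phantom(PhantomSpec(shape=(64, 64, 64), n_lobes=2, seed=s))
        for s in (11, 12, 13)
    ]
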