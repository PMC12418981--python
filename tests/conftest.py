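import numpy as np
import pytest

from pflow.synth_scenes import make_texture, translate_scene


@pytest.fixture(scope="session")
def texture64():
    return make_texture(64, 64, correlation_length=1.0, rng_seed=0)


@pytest.fixture(scope="session")
def translate64(texture64):
    """64x64 texture rigidly translating at (1, 0) px/frame for 10 frames."""
    return translate_scene(texture64, (1.0, 0.0), T=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
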