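import numpy as np
import pytest

from mwtselect import SynthConfig, gen_recording, get_wavelet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def haar():
    return get_wavelet("db1")


@pytest.fixture(scope="session")
def db4():
    return get_wavelet("db4")


@pytest.fixture(scope="session")
def sym9():
    return get_wavelet("sym9")


@pytest.fixture(scope="session")
def short_recording():
    """4-second synthetic 19-channel recording (fast, deterministic)."""
    return gen_recording(SynthConfig(duration=4.0, seed=7))
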