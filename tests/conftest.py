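import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom32():
    from cryolite.simulate import default_phantom

    return default_phantom(32)


@pytest.fixture(scope="session")
def phantom32_ft(phantom32):
    from cryolite.fourier import oversampled_ft

    return oversampled_ft(phantom32)
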