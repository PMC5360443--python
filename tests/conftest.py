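import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def test_image_64():
    """Structured 64x64 test image with mean away from mid-grey."""
    gen = np.random.default_rng(7)
    y, x = np.mgrid[0:64, 0:64] / 64.0
    img = 0.55 + 0.2 * np.sin(6 * np.pi * x) * np.cos(4 * np.pi * y)
    img += 0.05 * gen.random((64, 64))
    return np.clip(img, 0.0, 1.0)


@pytest.fixture(scope="session")
def test_image_256():
    gen = np.random.default_rng(11)
    y, x = np.mgrid[0:256, 0:256] / 256.0
    img = 0.5 + 0.25 * np.sin(10 * np.pi * x * y) + 0.1 * np.cos(8 * np.pi * y)
    img += 0.04 * gen.random((256, 256))
    return np.clip(img, 0.0, 1.0)
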