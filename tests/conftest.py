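import numpy as np
import pytest

from microcalc import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_image():
    """A constant 96x96 image at level 100."""
    return GrayImage(np.full((96, 96), 100.0))


def disk_image(radius, size=64, level=100.0, background=0.0):
    """A bright disk centred in a square frame."""
    dy, dx = np.mgrid[:size, :size]
    c = size // 2
    return np.where(np.hypot(dy - c, dx - c) <= radius, level, background)
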