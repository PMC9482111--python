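import numpy as np
import pytest

from fibroquant import Micrograph, RegionMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def full_mask_64():
    return RegionMask(np.ones((64, 64), dtype=bool))


@pytest.fixture
def vertical_stripes_64():
    """Sinusoidal stripes whose fibrils run vertically (intensity varies
    along x only)."""
    xx = np.arange(64)[None, :].repeat(64, axis=0)
    return Micrograph(np.sin(xx * 0.7) ** 2)


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return RegionMask((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2)
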