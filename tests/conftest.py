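import numpy as np
import pytest
from scipy import ndimage

from wmseg import Image2D, BinaryMask, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def noisy_phantom():
    """Default noisy phantom slice plus its crisp ground truth."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture
def blobby_image():
    """An image with many strong blob features so SIFT finds keypoints."""
    r = np.random.default_rng(7)
    x = np.zeros((128, 128))
    for _ in range(40):
        rr, cc = r.integers(10, 118, 2)
        amp = r.uniform(120, 255)
        sig = r.uniform(1.5, 4.0)
        x[rr, cc] += amp * 2 * np.pi * sig**2
    x = ndimage.gaussian_filter(x, 3.0)
    return Image2D(np.clip(x, 0, 255))


@pytest.fixture
def full_mask():
    return BinaryMask.from_bool(np.ones((128, 128), bool))
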