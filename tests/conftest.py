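import numpy as np
import pytest

from earcount.raster import BinaryMask, GrayImage, RgbImage
from earcount.synthetic import EarFixtureSpec, generate_ear


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260301)


@pytest.fixture(scope="session")
def nontouching_ear():
    """5 x 8 grid of well-separated kernels with exact ground truth."""
    spec = EarFixtureSpec(rows=8, cols=5, seed=11)
    img, truth = generate_ear(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def gradient_ear():
    spec = EarFixtureSpec(
        rows=8, cols=5, illumination="linear_gradient", illumination_amplitude=60.0, seed=12
    )
    img, truth = generate_ear(spec)
    return spec, img, truth


def random_gray(rng, h, w, smooth=False):
    px = rng.integers(0, 256, size=(h, w)).astype(np.float64)
    if smooth:
        from scipy import ndimage

        px = ndimage.gaussian_filter(px, 1.5)
        px = 255.0 * (px - px.min()) / max(px.ptp(), 1e-9)
    return GrayImage(px)


def random_mask(rng, h, w, p=0.4):
    return BinaryMask.from_bool(rng.random((h, w)) < p)
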