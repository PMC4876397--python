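import numpy as np
import pytest

from gbiq.image_io import ImageChannel, MultiChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_channel(rng):
    """A 240x240 8-bit channel of uniform noise."""
    px = rng.integers(0, 256, size=(240, 240), dtype=np.uint8)
    return ImageChannel(name="H33342", pixels=px, bit_depth=8)


@pytest.fixture
def small_image(rng):
    """A 60x60 3-channel image with distinct random content per channel."""
    chans = tuple(
        ImageChannel(
            name=n,
            pixels=rng.integers(0, 256, size=(60, 60), dtype=np.uint8),
            bit_depth=8,
        )
        for n in ("H33342", "EGFP", "antiOct4")
    )
    return MultiChannelImage(image_id="img0", channels=chans)


def planted_mixture(k, n, d=2, sep=10.0, sigma=1.0, seed=None):
    """Well-separated Gaussian mixture sample with its true labels."""
    r = np.random.default_rng(seed)
    means = r.normal(0.0, sep, (k, d))
    labels = r.integers(0, k, n)
    X = means[labels] + r.normal(0.0, sigma, (n, d))
    return X, labels, means
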