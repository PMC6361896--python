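import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def ring_image():
    """A dark annulus (value 0.1) on a bright background (0.9), 16x16."""
    img = np.full((16, 16), 0.9)
    rr, cc = np.mgrid[0:16, 0:16]
    rad = np.hypot(rr - 8, cc - 8)
    img[(rad > 3) & (rad < 6)] = 0.1
    return img


def random_quantized_image(rng, max_side=12, levels=6):
    """Small random image with deliberate ties/plateaus."""
    m, n = rng.integers(1, max_side + 1, 2)
    return rng.integers(0, levels, (m, n)) / (levels - 1)
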