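import numpy as np
import pytest

from turfcam.colorspace import hsv_to_rgb


def uniform_rgb(h, s, v, shape=(8, 8)):
    """Uniform frame from one integer HSV triple (hue 0-179, s/v 0-255)."""
    color = hsv_to_rgb(np.array(h), np.array(s), np.array(v))
    return np.broadcast_to(color, shape + (3,)).copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
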