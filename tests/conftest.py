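import numpy as np
import pytest
from skimage import draw


def disk_mask(radius: int, pad: int = 6) -> np.ndarray:
    size = 2 * radius + 2 * pad + 1
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((radius + pad, radius + pad), radius)
    mask[rr, cc] = True
    return mask


def ellipse_mask(a: int, b: int, pad: int = 6) -> np.ndarray:
    """Axis-aligned ellipse with semi-axes (a along columns, b along rows)."""
    mask = np.zeros((2 * b + 2 * pad + 1, 2 * a + 2 * pad + 1), dtype=bool)
    rr, cc = draw.ellipse(b + pad, a + pad, b, a)
    mask[rr, cc] = True
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
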