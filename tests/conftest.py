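import numpy as np
import pytest

from dyadscape.image_core import Image2D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ellipse_image():
    """A bright solid ellipse (long axis horizontal) on a dim background."""
    rr, cc = np.mgrid[0:120, 0:200]
    mask = ((cc - 100) / 80.0) ** 2 + ((rr - 60) / 35.0) ** 2 <= 1.0
    return Image2D(mask * 100.0 + 1.0, pixel_size_um=0.16)


def rotated_ellipse(angle_deg, shape=(200, 200), semi=(80, 30), value=100.0):
    """Solid ellipse whose long axis makes ``angle_deg`` with the horizontal
    (counter-clockwise, y up)."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    ang = np.deg2rad(angle_deg)
    x = cc - shape[1] / 2.0
    y = -(rr - shape[0] / 2.0)
    u = x * np.cos(ang) + y * np.sin(ang)
    v = -x * np.sin(ang) + y * np.cos(ang)
    mask = (u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0
    return Image2D(mask * value + 1.0, pixel_size_um=0.16), mask
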