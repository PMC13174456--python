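import numpy as np
import pytest

from dermatomics import segmentation, synthetic


@pytest.fixture(scope="session")
def he_phantom():
    """Default H&E phantom rendered once: (image, truth)."""
    return synthetic.render_he_phantom()


@pytest.fixture(scope="session")
def buttock_cfg():
    return segmentation.ColorFilterConfig.for_site("buttock")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_blob_image(radius: int, size: int = 600) -> np.ndarray:
    """White frame with one round H&E-colored tissue blob of given radius."""
    img = np.full((size, size, 3), 255, np.uint8)
    yy, xx = np.mgrid[:size, :size]
    blob = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2
    img[blob] = (150, 60, 160)
    return img
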