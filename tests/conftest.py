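import numpy as np
import pytest

from colonychannels import Calibration, Image2D, PolarImage
from colonychannels.segmentation import Centre


@pytest.fixture
def calibration():
    return Calibration(pixel_size_um=0.5)


def make_polar(pixels, pixel_size_um=1.0, valid=None, range_max=255.0):
    """Wrap a raw (radius x angle) array as a PolarImage for direct tests."""
    pixels = np.asarray(pixels, dtype=float)
    if valid is None:
        valid = np.ones_like(pixels, dtype=bool)
    return PolarImage(
        pixels=pixels,
        valid=valid,
        origin=Centre(0.0, 0.0),
        calibration=Calibration(pixel_size_um=pixel_size_um),
        n_angular=pixels.shape[1],
        range_max=range_max,
    )


def disk_image(size, radius, value=100.0, background=0.0, centre=None, dtype=float):
    """A filled disk on a flat background, as a plain array."""
    if centre is None:
        centre = ((size - 1) / 2.0, (size - 1) / 2.0)
    ys, xs = np.mgrid[0:size, 0:size]
    inside = (xs - centre[0]) ** 2 + (ys - centre[1]) ** 2 <= radius**2
    img = np.full((size, size), background, dtype=float)
    img[inside] = value
    return img.astype(dtype)


@pytest.fixture(scope="session")
def small_colony():
    """A small rendered colony + ground truth shared by slower tests."""
    from colonychannels import SyntheticSpec, generate

    spec = SyntheticSpec(
        size_px=1500,
        colony_radius_um=600.0,
        ellipticity=0.95,
        n_channels=16,
        seed=7,
    )
    return generate(spec)
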