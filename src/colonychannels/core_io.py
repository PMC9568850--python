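"""Calibrated image containers and TIFF input/output.

The pipeline works on single-channel grayscale rasters with an explicit
physical calibration. The lateral pixel size is never guessed from file
metadata: it is a mandatory input carried on every image, because the
downstream conversion of angular widths to micrometres depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "Calibration",
    "Image2D",
    "ZStack",
    "read_image",
    "write_image",
    "max_intensity_projection",
    "median_prefilter",
]


@dataclass(frozen=True)
class Calibration:
    """Physical pixel calibration.

    Parameters
    ----------
    pixel_size_um : float
        Lateral size of one pixel in micrometres. Must be positive.
    z_step_um : float, optional
        Axial spacing between z-slices in micrometres; required only for
        thickness measurements on z-stacks.
    """

    pixel_size_um: float
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be a positive finite number")
        if self.z_step_um is not None and (
            not np.isfinite(self.z_step_um) or self.z_step_um <= 0
        ):
            raise ValueError("z_step_um must be a positive finite number when given")


def _bit_range(dtype: np.dtype) -> float:
    """Full-scale value of the image bit range (255 for 8-bit, 65535 for 16-bit)."""
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return 255.0


@dataclass
class Image2D:
    """A single calibrated grayscale image.

    ``range_max`` is the nominal full-scale intensity (bit range), used by
    intensity inversion and histogram equalisation; it defaults to the dtype's
    full scale (255.0 for floating-point data).
    """

    pixels: np.ndarray
    calibration: Calibration
    range_max: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2-D single-channel raster")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError("image too small: at least 16x16 pixels required")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise ValueError("image contains non-finite values")
        if self.range_max == 0.0:
            self.range_max = _bit_range(self.pixels.dtype)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ZStack:
    """An ordered stack of equally sized slices sharing one calibration."""

    slices: list[Image2D]

    def __post_init__(self) -> None:
        if len(self.slices) < 2:
            raise ValueError("a z-stack needs at least 2 slices")
        shape0 = self.slices[0].shape
        cal0 = self.slices[0].calibration
        for s in self.slices[1:]:
            if s.shape != shape0:
                raise ValueError("all slices must share the same raster dimensions")
            if s.calibration != cal0:
                raise ValueError("all slices must share one calibration")

    @property
    def calibration(self) -> Calibration:
        return self.slices[0].calibration

    def as_array(self) -> np.ndarray:
        return np.stack([s.pixels for s in self.slices], axis=0)


def read_image(path: str | Path, calibration: Calibration) -> Image2D | ZStack:
    """Read a grayscale TIFF as an :class:`Image2D` (1 page) or :class:`ZStack`.

    Intensities are preserved bit-exactly. RGB or multi-channel input is
    rejected: the pipeline analyses single-channel fluorescence data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        return Image2D(pages, calibration)
    if pages.ndim == 3:
        # Distinguish a z-stack (pages, H, W) from an RGB image (H, W, 3|4).
        if pages.shape[-1] in (3, 4) and pages.shape[0] not in (3, 4):
            raise ValueError("grayscale required: RGB/multi-channel TIFF not supported")
        return ZStack([Image2D(p, calibration) for p in pages])
    raise ValueError(f"unsupported TIFF dimensionality: {pages.ndim}")


def write_image(img: Image2D | ZStack, path: str | Path) -> None:
    """Write an image or z-stack to TIFF, preserving dtype."""
    path = Path(path)
    if isinstance(img, ZStack):
        tifffile.imwrite(path, img.as_array())
    else:
        tifffile.imwrite(path, img.pixels)


def max_intensity_projection(stack: ZStack) -> Image2D:
    """Project a z-stack to 2-D by taking the per-pixel maximum over slices."""
    mip = stack.as_array().max(axis=0)
    return Image2D(mip, stack.calibration, range_max=stack.slices[0].range_max)


def median_prefilter(img: Image2D, radius_px: int = 2) -> Image2D:
    """Rank-median filter within a disk, as used to denoise widefield images.

    The structuring element is a disk of the given radius (pixels at Euclidean
    distance <= radius are included), matching FIJI's "Median..." semantics.
    Borders are edge-replicated so the colony rim is not darkened.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    footprint = disk(radius_px)
    filtered = ndimage.median_filter(img.pixels, footprint=footprint, mode="nearest")
    return Image2D(filtered, img.calibration, range_max=img.range_max)
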