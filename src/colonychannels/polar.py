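"""Polar unwrap of the colony image and polar-geometry arc-length conversion.

Unwrapping the colony about its centre turns circumferences into straight
rows: the pixel at (r, k) samples the source image at radius r (in source
pixels) and angle 2*pi*k/n_angular. Channel cross-sections along a row are
then 1-D peak problems, and an angular extent converts to micrometres by
arc length at the row's physical radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import Calibration, Image2D
from .segmentation import Centre

__all__ = ["PolarImage", "to_polar", "arc_length_um", "from_polar"]

#: Angular sampling used throughout: 7200 samples over the full turn
#: (20 per degree), fine enough to resolve micrometre-scale channels by
#: arc length at every measured radius.
DEFAULT_N_ANGULAR = 7200


@dataclass
class PolarImage:
    """Colony unwrapped to a (radius x angle) raster.

    Row r corresponds to radius r source pixels from ``origin``; column k to
    angle 2*pi*k/n_angular from the +x axis. ``valid`` flags samples whose
    source coordinates fell inside the frame; invalid samples are excluded
    from enhancement histograms and bar profile extraction.
    """

    pixels: np.ndarray
    valid: np.ndarray
    origin: Centre
    calibration: Calibration
    n_angular: int
    range_max: float

    def __post_init__(self) -> None:
        if self.pixels.shape != self.valid.shape:
            raise ValueError("pixels and valid mask must share a shape")
        if self.pixels.shape[1] != self.n_angular:
            raise ValueError("angular axis length must equal n_angular")

    @property
    def n_radial(self) -> int:
        return self.pixels.shape[0]

    def radius_um(self, row: int) -> float:
        return row * self.calibration.pixel_size_um


def to_polar(
    img: Image2D,
    centre: Centre,
    n_angular: int = DEFAULT_N_ANGULAR,
    max_radius_px: int | None = None,
) -> PolarImage:
    """Unwrap ``img`` about ``centre`` into (radius, angle) coordinates.

    Bilinear interpolation; angle 0 along +x, increasing towards +y. Samples
    outside the frame are flagged invalid rather than zero-filled, so the
    downstream full-circumference exclusion can act on them.
    """
    h, w = img.pixels.shape
    if not (0 <= centre.x_px <= w - 1 and 0 <= centre.y_px <= h - 1):
        raise ValueError("centre outside image frame")
    if max_radius_px is None:
        # farthest corner: the polar raster covers the whole frame
        max_radius_px = int(
            np.ceil(
                max(
                    np.hypot(centre.x_px - cx, centre.y_px - cy)
                    for cx in (0, w - 1)
                    for cy in (0, h - 1)
                )
            )
        )
    radii = np.arange(max_radius_px + 1, dtype=float)
    theta = 2.0 * np.pi * np.arange(n_angular) / n_angular
    xs = centre.x_px + radii[:, None] * np.cos(theta)[None, :]
    ys = centre.y_px + radii[:, None] * np.sin(theta)[None, :]
    valid = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    sampled = ndimage.map_coordinates(
        img.pixels.astype(float), [ys, xs], order=1, mode="nearest"
    )
    return PolarImage(
        pixels=sampled,
        valid=valid,
        origin=centre,
        calibration=img.calibration,
        n_angular=n_angular,
        range_max=img.range_max,
    )


def from_polar(polar: PolarImage, shape: tuple[int, int]) -> np.ndarray:
    """Re-project a polar raster back to cartesian (QC utility).

    Nearest-valid reconstruction by bilinear sampling of the polar raster at
    each cartesian pixel's (r, theta); pixels beyond the polar radial extent
    are zero.
    """
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    dx = xs - polar.origin.x_px
    dy = ys - polar.origin.y_px
    r = np.hypot(dx, dy)
    th = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    k = th / (2.0 * np.pi) * polar.n_angular
    # wrap the angular axis so interpolation across the seam is seamless
    wrapped = np.concatenate([polar.pixels, polar.pixels[:, :1]], axis=1)
    out = ndimage.map_coordinates(wrapped, [r, k], order=1, mode="nearest")
    out[r > polar.n_radial - 1] = 0.0
    return out


def arc_length_um(delta_angular_px: float, radius_um: float, n_angular: int) -> float:
    """Convert an angular extent (in polar-raster pixels) to arc length in um.

    ``delta_angular_px / n_angular`` of a full turn at radius ``radius_um``:
    arc = delta/n * 2*pi*r.
    """
    if delta_angular_px < 0 or radius_um < 0:
        raise ValueError("angular extent and radius must be non-negative")
    if delta_angular_px > n_angular:
        raise ValueError("angular extent exceeds one full turn")
    return delta_angular_px / n_angular * 2.0 * np.pi * radius_um
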