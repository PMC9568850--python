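"""Colony segmentation: mask, base area, centre, measurable radius, thickness.

The colony footprint is obtained by thresholding at the mean gray level of
the whole frame, keeping the largest 8-connected component and filling its
holes (intra-colony channels are darker than cells and would otherwise
puncture the mask). The mask centroid serves as the colony centre for the
polar unwrap, and the largest radius at which a full circle fits inside the
mask bounds the measurable radial range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .core_io import Calibration, Image2D, ZStack

__all__ = [
    "ColonyMask",
    "Centre",
    "segment_colony",
    "base_area",
    "estimate_centre",
    "max_full_circumference_radius",
    "biofilm_thickness",
]


@dataclass
class ColonyMask:
    """Binary colony footprint (exactly one filled connected component)."""

    mask: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty colony mask")


@dataclass(frozen=True)
class Centre:
    """Sub-pixel colony centre in raster (x, y) coordinates."""

    x_px: float
    y_px: float


def segment_colony(img: Image2D) -> ColonyMask:
    """Threshold at the mean gray level and keep the largest component.

    Foreground is ``pixels >= mean`` (ties go to foreground). Holes inside
    the retained component are filled. Raises if the image has no intensity
    variance or no foreground survives.
    """
    pixels = img.pixels
    if np.ptp(pixels) == 0:
        raise ValueError("no colony detected: image has zero intensity variance")
    threshold = pixels.mean()
    fg = pixels >= threshold
    if not fg.any():
        raise ValueError("no colony detected: empty foreground after threshold")
    labels = label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = counts.argmax()
    mask = ndimage.binary_fill_holes(labels == largest)
    return ColonyMask(mask, img.calibration)


def base_area(mask: ColonyMask) -> float:
    """Colony base area in square micrometres (pixel count x pixel area)."""
    px = mask.calibration.pixel_size_um
    return float(mask.mask.sum()) * px * px


def estimate_centre(mask: ColonyMask) -> Centre:
    """Colony centre as the mask centroid (first image moments), sub-pixel."""
    ys, xs = np.nonzero(mask.mask)
    return Centre(x_px=float(xs.mean()), y_px=float(ys.mean()))


def max_full_circumference_radius(
    mask: ColonyMask, centre: Centre, n_angular: int = 7200
) -> float:
    """Largest radius (um) at which a full circle about the centre stays inside.

    The circle is sampled at the polar transform's angular density; the first
    radius at which any sample leaves the foreground terminates the search,
    implementing the rule that only radii with a complete circumference are
    measured.
    """
    m = mask.mask
    h, w = m.shape
    iy = int(round(centre.y_px))
    ix = int(round(centre.x_px))
    if not (0 <= iy < h and 0 <= ix < w) or not m[iy, ix]:
        raise ValueError("centre outside mask")
    theta = 2.0 * np.pi * np.arange(n_angular) / n_angular
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    r_limit = int(np.ceil(np.hypot(max(centre.x_px, w - centre.x_px),
                                   max(centre.y_px, h - centre.y_px))))
    last_full = 0
    for r in range(1, r_limit + 1):
        xs = np.rint(centre.x_px + r * cos_t).astype(int)
        ys = np.rint(centre.y_px + r * sin_t).astype(int)
        inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        if not inside.all() or not m[ys, xs].all():
            break
        last_full = r
    return last_full * mask.calibration.pixel_size_um


def _local_minima(profile: np.ndarray) -> list[int]:
    """Indices of local minima; endpoints qualify when below their neighbour."""
    n = len(profile)
    minima = []
    for i in range(n):
        left = profile[i - 1] if i > 0 else np.inf
        right = profile[i + 1] if i < n - 1 else np.inf
        if profile[i] < left and profile[i] < right:
            minima.append(i)
    return minima


def biofilm_thickness(
    stack: ZStack, region: np.ndarray | None = None, smooth: bool = True
) -> float:
    """Biofilm thickness from the z-axis mean-intensity profile.

    The per-slice mean intensity (over ``region`` or the whole frame) is
    optionally smoothed with a 3-point moving average, its two lowest local
    minima located, and the thickness returned as their slice separation
    times the z-step. The minima bracket the biofilm: signal falls off above
    the colony surface and below the substrate.
    """
    if len(stack.slices) < 3:
        raise ValueError("thickness needs at least 3 slices")
    z_step = stack.calibration.z_step_um
    if z_step is None:
        raise ValueError("z_step_um calibration required for thickness")
    arr = stack.as_array().astype(float)
    if region is not None:
        region = np.asarray(region, dtype=bool)
        profile = arr[:, region].mean(axis=1)
    else:
        profile = arr.mean(axis=(1, 2))
    if smooth:
        # 3-point moving average; endpoints average the 2 available values
        kernel = np.ones(3)
        profile = np.convolve(profile, kernel, mode="same") / np.convolve(
            np.ones_like(profile), kernel, mode="same"
        )
    minima = _local_minima(profile)
    if len(minima) < 2:
        raise ValueError("thickness undefined: fewer than two local minima")
    order = sorted(minima, key=lambda i: profile[i])[:2]
    lo, hi = sorted(order)
    return float(hi - lo) * z_step
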