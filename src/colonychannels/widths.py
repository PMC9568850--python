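"""Circumferential profiles, peak detection, FWHM and physical channel widths.

A row of the enhanced polar raster is the intensity along a full
circumference. Channels appear as peaks; each peak's full width at half
maximum (half the topographic prominence below the apex) is measured in
angular pixels and converted to micrometres by arc length at the profile's
radius. Profiles are treated as circular throughout: a circumference has no
endpoints, and a channel crossing angle zero must not be split in two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polar import PolarImage, arc_length_um

__all__ = [
    "Profile",
    "ChannelDetection",
    "FwhmUndefinedError",
    "extract_profile",
    "detect_peaks",
    "circular_prominence",
    "peak_fwhm",
    "widths_to_um",
    "modified_z_scores",
    "remove_outliers",
    "detections_to_table",
]

logger = logging.getLogger(__name__)

#: Modified z-score scale factor: the MAD of a normal sample estimates
#: sigma / 1.4826, so 0.6745 * deviation / MAD is on the z scale.
MAD_SCALE = 0.6745
#: Analogous consistency factor for the mean absolute deviation fallback.
MEAN_AD_SCALE = 1.253314


class FwhmUndefinedError(ValueError):
    """The half-maximum level is never crossed on one side of the peak."""


@dataclass
class Profile:
    """Angular intensity profile at one radius (one polar-raster row)."""

    radius_um: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if self.radius_um < 0:
            raise ValueError("radius_um must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ChannelDetection:
    """One measured channel crossing: where it is and how wide."""

    radius_um: float
    angular_position_px: float
    width_px: float
    width_um: float
    prominence: float


def extract_profile(polar: PolarImage, radius_um: float) -> Profile:
    """Angular intensity vector at the radial row nearest to ``radius_um``.

    Raises if the row lies beyond the raster or its circumference is not
    fully inside the source frame (the full-circumference exclusion rule).
    """
    row = int(round(radius_um / polar.calibration.pixel_size_um))
    if row < 0 or row >= polar.n_radial:
        raise ValueError(
            f"incomplete circumference: radius {radius_um} um beyond polar raster"
        )
    if not polar.valid[row].all():
        raise ValueError(
            f"incomplete circumference at radius {radius_um} um"
        )
    return Profile(radius_um=polar.radius_um(row), values=polar.pixels[row].copy())


# ---------------------------------------------------------------------------
# circular peak analysis


def _circular_local_maxima(x: np.ndarray) -> list[int]:
    """Indices of circular local maxima; a plateau yields its midpoint.

    A run of equal values is a maximum when both circular neighbours of the
    run are strictly lower; its representative index is the midpoint of the
    run (left-of-centre for even runs).
    """
    n = len(x)
    if n < 2 or np.all(x == x[0]):
        return []
    diffs = np.diff(x)
    if np.all(diffs != 0) and x[0] != x[-1]:
        # fast path: no plateaus anywhere, including across the seam
        prev_ = np.roll(x, 1)
        next_ = np.roll(x, -1)
        return list(np.flatnonzero((x > prev_) & (x > next_)))
    # general path: scan runs of equal values around the circle
    start = next(i for i in range(n) if x[i] != x[i - 1])
    maxima = []
    i, covered = start, 0
    while covered < n:
        run_len = 1
        while run_len < n and x[(i + run_len) % n] == x[i]:
            run_len += 1
        prev_v = x[(i - 1) % n]
        next_v = x[(i + run_len) % n]
        if x[i] > prev_v and x[i] > next_v:
            maxima.append((i + (run_len - 1) // 2) % n)
        i = (i + run_len) % n
        covered += run_len
    return sorted(maxima)


def circular_prominence(x: np.ndarray, peak: int) -> float:
    """Topographic prominence of ``x[peak]`` on the circular signal.

    On each side, walk away from the peak until a strictly higher sample is
    found (or the walk returns to the peak, for a global maximum), tracking
    the minimum en route; the prominence is the peak height minus the higher
    of the two side minima.
    """
    n = len(x)
    h = x[peak]
    side_bases = []
    for step in (-1, 1):
        lowest = h
        i = peak
        for _ in range(n - 1):
            i = (i + step) % n
            if x[i] > h:
                break
            if x[i] < lowest:
                lowest = x[i]
        side_bases.append(lowest)
    return float(h - max(side_bases))


def detect_peaks(
    profile: Profile | np.ndarray,
    prominence_fraction: float = 0.20,
    min_distance_px: int = 9,
) -> list[int]:
    """Detect channel peaks on a circular profile.

    Local maxima whose circular prominence reaches ``prominence_fraction``
    of the profile's full range survive; among surviving maxima closer than
    ``min_distance_px`` (circular distance), the higher one wins (ties break
    towards the more prominent, then the lower index). A flat profile yields
    no peaks. Returns sorted peak indices.
    """
    x = profile.values if isinstance(profile, Profile) else np.asarray(profile, float)
    n = len(x)
    if n < 2 * min_distance_px:
        raise ValueError("profile too short for the requested minimum distance")
    rng = float(x.max() - x.min())
    if rng == 0:
        return []
    threshold = prominence_fraction * rng
    candidates = []
    for idx in _circular_local_maxima(x):
        prom = circular_prominence(x, idx)
        if prom >= threshold:
            candidates.append((idx, float(x[idx]), prom))
    # greedy suppression: highest first
    candidates.sort(key=lambda c: (-c[1], -c[2], c[0]))
    kept: list[int] = []
    for idx, _, _ in candidates:
        ok = True
        for k in kept:
            d = abs(idx - k)
            if min(d, n - d) < min_distance_px:
                ok = False
                break
        if ok:
            kept.append(idx)
    return sorted(kept)


def peak_fwhm(profile: Profile | np.ndarray, peak_index: int) -> float:
    """Full width at half maximum of a detected peak, in angular pixels.

    The half-maximum level is the peak height minus half its circular
    prominence (robust to sloping baselines). Crossing points on each side
    are located by linear interpolation between the last sample at or above
    the level and the first below it; the width is the circular distance
    between the two crossings.
    """
    x = profile.values if isinstance(profile, Profile) else np.asarray(profile, float)
    n = len(x)
    h = x[peak_index]
    prom = circular_prominence(x, peak_index)
    level = h - prom / 2.0

    def _crossing(step: int) -> float:
        prev_val = h
        for d in range(1, n + 1):
            cur = x[(peak_index + step * d) % n]
            if cur < level:
                t = (prev_val - level) / (prev_val - cur)
                return (d - 1) + t
            prev_val = cur
        raise FwhmUndefinedError(
            f"half-maximum level never crossed on side {step:+d} of peak "
            f"{peak_index}"
        )

    return _crossing(-1) + _crossing(+1)


def widths_to_um(
    detections: list[tuple[float, float, float, float]] | list[ChannelDetection],
    polar: PolarImage,
) -> list[ChannelDetection]:
    """Convert angular-pixel FWHMs to micrometre widths by arc length.

    Accepts ``(radius_um, angular_position_px, width_px, prominence)`` tuples
    (or detections with ``width_um`` unset) and returns completed
    :class:`ChannelDetection` records.
    """
    out = []
    for det in detections:
        if isinstance(det, ChannelDetection):
            r, pos, w_px, prom = det.radius_um, det.angular_position_px, det.width_px, det.prominence
        else:
            r, pos, w_px, prom = det
        w_um = arc_length_um(w_px, r, polar.n_angular)
        out.append(
            ChannelDetection(
                radius_um=r,
                angular_position_px=pos,
                width_px=w_px,
                width_um=w_um,
                prominence=prom,
            )
        )
    return out


# ---------------------------------------------------------------------------
# robust outlier rejection


def modified_z_scores(values: np.ndarray) -> np.ndarray:
    """Modified z-scores M = 0.6745 (x - median) / MAD.

    When the MAD is zero (at least half the values identical) the mean
    absolute deviation replaces it, M = (x - median) / (1.253314 * meanAD);
    if that is also zero the data have no dispersion and all scores are 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad > 0:
        return MAD_SCALE * dev / mad
    mean_ad = np.mean(np.abs(dev))
    if mean_ad > 0:
        return dev / (MEAN_AD_SCALE * mean_ad)
    return np.zeros_like(x)


def remove_outliers(widths, threshold: float = 3.0):
    """Drop values whose |modified z-score| exceeds ``threshold`` (strictly).

    Applied once (single pass), as when pruning spuriously wide detections
    at the colony edge. A score of exactly ``threshold`` is retained.
    """
    x = np.asarray(widths, dtype=float)
    scores = modified_z_scores(x)
    keep = np.abs(scores) <= threshold
    return list(x[keep])


def detections_to_table(
    detections: list[ChannelDetection],
    biofilm_id: str,
    condition: str = "",
    retained: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate detections as the pipeline's channel-width table."""
    rows = pd.DataFrame(
        {
            "biofilm_id": biofilm_id,
            "condition": condition,
            "radius_um": [d.radius_um for d in detections],
            "angle_px": [d.angular_position_px for d in detections],
            "width_um": [d.width_um for d in detections],
            "prominence": [d.prominence for d in detections],
        }
    )
    rows["retained"] = True if retained is None else np.asarray(retained, bool)
    bad = ~np.isfinite(rows["width_um"])
    if bad.any():
        raise ValueError("non-finite width in detection table")
    return rows
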