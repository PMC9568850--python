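"""Radial aggregation of channel widths and trend fitting.

Widths are measured along whole circumferences on a fixed radial grid
(every 50 um starting at 200 um; smaller radii are too distorted by the
unwrap to be reliable). The mean width per radius is then fitted with both
a straight line and an exponential y = a*exp(b*x), and widths are summarised
at normalised radial positions (20%, 50%, 100% of the outermost measured
radius) so colonies of different sizes can be compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .polar import PolarImage
from .widths import (
    ChannelDetection,
    FwhmUndefinedError,
    circular_prominence,
    detect_peaks,
    extract_profile,
    peak_fwhm,
    widths_to_um,
)

__all__ = [
    "RadialSeries",
    "LinearFit",
    "ExponentialFit",
    "RadialFitResult",
    "measure_radial_series",
    "fit_linear",
    "fit_exponential",
    "fit_radial_trends",
    "normalised_position_summary",
]

logger = logging.getLogger(__name__)

RADIAL_START_UM = 200.0
RADIAL_STEP_UM = 50.0


@dataclass
class RadialSeries:
    """Channel widths grouped by sampled radius (strictly increasing grid)."""

    widths_by_radius: dict[float, list[float]]
    detections: list[ChannelDetection] = field(default_factory=list)

    @property
    def radii(self) -> list[float]:
        return sorted(self.widths_by_radius)

    def mean_widths(self) -> tuple[np.ndarray, np.ndarray]:
        """Radii and per-radius mean widths, dropping radii with no detections."""
        radii = [r for r in self.radii if self.widths_by_radius[r]]
        means = [float(np.mean(self.widths_by_radius[r])) for r in radii]
        return np.asarray(radii), np.asarray(means)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class ExponentialFit:
    a: float
    b: float
    r_squared: float


@dataclass(frozen=True)
class RadialFitResult:
    linear: LinearFit
    exponential: ExponentialFit


def measure_radial_series(
    polar: PolarImage,
    max_radius_um: float,
    prominence_fraction: float = 0.20,
    min_distance_px: int = 9,
    start_um: float = RADIAL_START_UM,
    step_um: float = RADIAL_STEP_UM,
) -> RadialSeries:
    """Measure channel widths at every grid radius with a full circumference.

    Runs profile extraction, peak detection, FWHM measurement and arc-length
    conversion at r = start, start+step, ... up to ``max_radius_um``. Radii
    whose circumference leaves the frame are skipped; peaks whose FWHM is
    undefined at the edge of valid data are discarded with a logged warning.
    """
    if max_radius_um < start_um:
        raise ValueError("colony below measurable size")
    radii = np.arange(start_um, max_radius_um + 1e-9, step_um)
    widths_by_radius: dict[float, list[float]] = {}
    detections: list[ChannelDetection] = []
    for r in radii:
        try:
            profile = extract_profile(polar, float(r))
        except ValueError:
            logger.info("skipping radius %.0f um: incomplete circumference", r)
            continue
        peaks = detect_peaks(profile, prominence_fraction, min_distance_px)
        raw = []
        for p in peaks:
            try:
                w_px = peak_fwhm(profile, p)
            except FwhmUndefinedError as exc:
                logger.info("discarding peak at radius %.0f um: %s", r, exc)
                continue
            prom = circular_prominence(profile.values, p)
            raw.append((profile.radius_um, float(p), w_px, prom))
        dets = widths_to_um(raw, polar)
        # key by the snapped (row-centre) radius so detections and groups agree
        key = float(profile.radius_um)
        if key in widths_by_radius:
            continue
        widths_by_radius[key] = [d.width_um for d in dets]
        detections.extend(dets)
    if not widths_by_radius:
        raise ValueError("colony below measurable size")
    return RadialSeries(widths_by_radius, detections)


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - fitted) ** 2))
    if sst == 0.0:
        return 0.0
    return 1.0 - sse / sst


def fit_linear(radii_um, mean_widths) -> LinearFit:
    """Ordinary least squares of mean width on radius."""
    x = np.asarray(radii_um, dtype=float)
    y = np.asarray(mean_widths, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 radii to fit a trend")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    return LinearFit(float(slope), float(intercept), _r_squared(y, fitted))


def fit_exponential(radii_um, mean_widths) -> ExponentialFit:
    """Log-linear least squares fit of y = a*exp(b*x).

    ln(y) is regressed on x; a = exp(intercept), b = slope, and R^2 is
    computed in log space (the spreadsheet-trendline convention).
    """
    x = np.asarray(radii_um, dtype=float)
    y = np.asarray(mean_widths, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 radii to fit a trend")
    if np.any(y <= 0):
        raise ValueError("exponential fit requires positive widths")
    ly = np.log(y)
    b, log_a = np.polyfit(x, ly, 1)
    fitted = b * x + log_a
    return ExponentialFit(float(np.exp(log_a)), float(b), _r_squared(ly, fitted))


def fit_radial_trends(series: RadialSeries) -> RadialFitResult:
    """Fit both trend models to the per-radius mean widths."""
    radii, means = series.mean_widths()
    return RadialFitResult(
        linear=fit_linear(radii, means),
        exponential=fit_exponential(radii, means),
    )


def normalised_position_summary(
    series: RadialSeries, fractions: tuple[float, ...] = (0.2, 0.5, 1.0)
) -> dict[float, tuple[float, list[float]]]:
    """Width lists at normalised radial positions.

    For each fraction f the sampled radius nearest to f x (outermost sampled
    radius) is selected (ties towards the smaller radius) and its width list
    returned, keyed by fraction.
    """
    radii = series.radii
    if not radii:
        raise ValueError("empty radial series")
    r_max = radii[-1]
    out = {}
    for f in fractions:
        target = f * r_max
        nearest = min(radii, key=lambda r: (abs(r - target), r))
        out[f] = (nearest, list(series.widths_by_radius[nearest]))
    return out
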