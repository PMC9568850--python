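"""Synthetic colony-biofilm images with known channel geometry.

The generator renders the phenomenology the measurement pipeline is built
for: a bright, roughly elliptical, dome-profiled colony on a dark
background, with darker channels radiating from the centre. Each channel's
local full width follows a programmed law (constant, linear or exponential
in radius) and its cross-section is a raised cosine, so the programmed
width *is* the full width at half maximum by construction. Optional angular
meander reproduces the wandering, folding channel trajectories of colonies
on nutrient-rich substrates; amplitude zero gives the near-straight radial
channels of nutrient-limited growth. The rendered image is degraded by
Gaussian blur and additive (optionally Poisson) noise and is bit-identical
for a fixed seed.

Every rendered image ships with its ground truth (mask, centre, base area,
width law), giving each pipeline stage a known acceptance surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import ndimage

from .core_io import Calibration, Image2D

__all__ = [
    "SyntheticSpec",
    "SyntheticGroundTruth",
    "generate",
    "ground_truth_series",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic colony image.

    Width laws (widths in um, radius r in um):

    - ``constant``: w(r) = w0
    - ``linear``: w(r) = w0 + width_slope * r
    - ``exponential``: w(r) = w0 * exp(width_b * r)
    """

    size_px: int = 2800
    pixel_size_um: float = 1.0
    colony_radius_um: float = 1150.0
    ellipticity: float = 0.95          # minor/major axis ratio, in (0, 1]
    centre_offset_px: tuple[float, float] = (0.0, 0.0)
    n_channels: int = 30
    width_law: Literal["constant", "linear", "exponential"] = "constant"
    w0_um: float = 12.0
    width_slope: float = 0.0           # um width per um radius (linear law)
    width_b: float = 0.0               # 1/um exponent (exponential law)
    meander_amplitude_um: float = 0.0  # RMS transverse wander of a trajectory
    channel_depth: float = 0.25        # fractional intensity dip at channel centre
    channel_start_um: float = 40.0     # channels fade in over ~20 um from here
    dome_exponent: float = 2.0
    dome_pedestal: float = 0.75        # rim intensity fraction of the dome peak
    peak_intensity: float = 220.0
    background: float = 8.0
    blur_sigma_px: float = 0.3
    noise_sigma: float = 3.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ellipticity <= 1):
            raise ValueError("ellipticity must be in (0, 1]")
        if not (0 <= self.channel_depth < 1):
            raise ValueError("channel_depth must be in [0, 1)")
        if self.pixel_size_um <= 0 or self.colony_radius_um <= 0:
            raise ValueError("pixel size and colony radius must be positive")

    def width_at(self, r_um):
        """Programmed channel full width (um) at radius ``r_um``."""
        r = np.asarray(r_um, dtype=float)
        if self.width_law == "constant":
            w = np.full_like(r, self.w0_um)
        elif self.width_law == "linear":
            w = self.w0_um + self.width_slope * r
        elif self.width_law == "exponential":
            w = self.w0_um * np.exp(self.width_b * r)
        else:
            raise ValueError(f"unknown width law {self.width_law!r}")
        if np.any(w <= 0):
            raise ValueError("width law non-positive inside the colony")
        return w if w.ndim else float(w)


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spec: SyntheticSpec
    mask: np.ndarray                      # pre-blur ellipse interior
    centre_px: tuple[float, float]        # (x, y) raster coordinates
    base_area_um2: float                  # analytic ellipse area
    channel_angles_rad: np.ndarray        # base angle per channel
    meander_r_um: np.ndarray              # radial grid of the wander tables
    meander_offsets_um: np.ndarray        # (n_channels, len(grid)) transverse wander

    def width_at(self, r_um):
        return self.spec.width_at(r_um)

    def channel_theta(self, channel: int, r_um):
        """Angular trajectory theta(r) of one channel (radians)."""
        r = np.asarray(r_um, dtype=float)
        wander = np.interp(r, self.meander_r_um, self.meander_offsets_um[channel])
        return self.channel_angles_rad[channel] + wander / np.maximum(r, 1.0)


def _check_packing(spec: SyntheticSpec, check_radius_um: float = 200.0) -> None:
    if spec.n_channels == 0:
        return
    circumference = 2.0 * np.pi * check_radius_um
    occupied = spec.n_channels * spec.width_at(check_radius_um)
    if occupied * 2.0 > circumference:
        raise ValueError(
            f"channels overlap at r = {check_radius_um:.0f} um: "
            f"{spec.n_channels} channels of width "
            f"{spec.width_at(check_radius_um):.1f} um exceed half the "
            f"circumference; reduce n_channels or the width law"
        )


def generate(spec: SyntheticSpec) -> tuple[Image2D, SyntheticGroundTruth]:
    """Render one synthetic colony image and its ground truth."""
    _check_packing(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    px = spec.pixel_size_um
    cx = (n - 1) / 2.0 + spec.centre_offset_px[0]
    cy = (n - 1) / 2.0 + spec.centre_offset_px[1]
    a_px = spec.colony_radius_um / px
    b_px = spec.ellipticity * a_px

    ys, xs = np.mgrid[0:n, 0:n].astype(np.float32)
    dx = xs - cx
    dy = ys - cy
    rho = np.sqrt((dx / a_px) ** 2 + (dy / b_px) ** 2)  # elliptical radius
    mask = rho <= 1.0
    if not mask.any():
        raise ValueError("colony larger than frame or outside it")

    # dome intensity profile with a pedestal: real colonies fluoresce
    # appreciably out to the rim rather than fading to background
    dome = spec.dome_pedestal + (1.0 - spec.dome_pedestal) * (
        1.0 - np.clip(rho, 0, 1) ** spec.dome_exponent
    )

    # channel trajectories: evenly spaced base angles with seeded jitter,
    # plus an optional smoothed random transverse wander
    n_ch = spec.n_channels
    base_angles = np.sort(
        (2.0 * np.pi * np.arange(n_ch) / max(n_ch, 1)
         + rng.uniform(-0.3, 0.3, size=n_ch) * 2.0 * np.pi / max(n_ch, 1))
        % (2.0 * np.pi)
    )
    r_grid = np.arange(0.0, spec.colony_radius_um + 50.0, 10.0)
    if spec.meander_amplitude_um > 0 and n_ch > 0:
        steps = rng.normal(size=(n_ch, len(r_grid)))
        walk = np.cumsum(steps, axis=1)
        walk = ndimage.gaussian_filter1d(walk, sigma=8.0, axis=1, mode="nearest")
        rms = np.sqrt(np.mean(walk**2, axis=1, keepdims=True))
        offsets = walk / np.maximum(rms, 1e-12) * spec.meander_amplitude_um
    else:
        offsets = np.zeros((max(n_ch, 1), len(r_grid)))

    dip_total = np.zeros_like(dome)
    if n_ch > 0:
        r_um = np.hypot(dx, dy) * px
        theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
        w_local = spec.width_at(np.maximum(r_um, 1.0))
        # fade channels in over 20 um around channel_start_um
        onset = np.clip((r_um - spec.channel_start_um) / 20.0 + 0.5, 0.0, 1.0)
        inside = mask & (onset > 0)
        r_in = r_um[inside]
        th_in = theta[inside]
        w_in = np.asarray(w_local)[inside]
        dip_in = np.zeros_like(r_in)
        for c in range(n_ch):
            th_c = base_angles[c] + np.interp(
                r_in, r_grid, offsets[c]
            ) / np.maximum(r_in, 1.0)
            d_theta = np.mod(th_in - th_c + np.pi, 2.0 * np.pi) - np.pi
            near = np.abs(d_theta) < np.pi / 2
            d_um = r_in[near] * np.sin(d_theta[near])
            w_near = w_in[near]
            hit = np.abs(d_um) <= w_near
            dip = np.zeros_like(d_um)
            dip[hit] = np.cos(np.pi * d_um[hit] / (2.0 * w_near[hit])) ** 2
            sub = dip_in[near]
            np.maximum(sub, dip, out=sub)
            dip_in[near] = sub
        dip_total[inside] = dip_in * spec.channel_depth * onset[inside]

    img = spec.background + np.where(
        mask, (spec.peak_intensity - spec.background) * dome * (1.0 - dip_total), 0.0
    )
    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma_px)
    if spec.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = SyntheticGroundTruth(
        spec=spec,
        mask=mask,
        centre_px=(cx, cy),
        base_area_um2=float(np.pi * spec.colony_radius_um**2 * spec.ellipticity),
        channel_angles_rad=base_angles,
        meander_r_um=r_grid,
        meander_offsets_um=offsets,
    )
    calibration = Calibration(pixel_size_um=px)
    return Image2D(pixels, calibration), gt


def ground_truth_series(gt: SyntheticGroundTruth, radii_um) -> np.ndarray:
    """True mean channel width at each requested radius (evaluates the law)."""
    radii = np.asarray(radii_um, dtype=float)
    if np.any(radii < 0) or np.any(radii > gt.spec.colony_radius_um):
        raise ValueError("requested radii outside the colony")
    return np.asarray(gt.spec.width_at(radii), dtype=float)
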