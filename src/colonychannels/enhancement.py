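"""Contrast enhancement of the polar raster: CLAHE, despeckle, invert.

Channels are darker than the surrounding cells; after local contrast
enhancement, a 3x3 median despeckle and an intensity inversion they appear
as bright, prominent peaks on circumferential profiles.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .polar import PolarImage

__all__ = ["clahe", "despeckle", "invert"]


def _tile_edges(n: int, block: int) -> list[tuple[int, int]]:
    """Contiguous tile extents covering [0, n); the last tile absorbs the remainder."""
    n_tiles = max(1, n // block)
    edges = [(i * block, (i + 1) * block) for i in range(n_tiles)]
    edges[-1] = (edges[-1][0], n)
    return edges


def _clipped_lut(
    hist: np.ndarray, n_pixels: int, bins: int, max_slope: float, range_max: float
) -> np.ndarray:
    """Equalisation LUT from a histogram clipped at the max-slope limit.

    The clip limit is ``max_slope * n_pixels / bins`` (a uniform histogram has
    slope 1); clipped excess is redistributed uniformly over all bins, then
    the cumulative distribution is rescaled to the full bit range.
    """
    if n_pixels == 0:
        return (np.arange(bins) + 0.5) / bins * range_max
    clip = max(max_slope * n_pixels / bins, 1.0)
    clipped = np.minimum(hist, clip)
    excess = n_pixels - clipped.sum()
    clipped = clipped + excess / bins
    cdf = np.cumsum(clipped)
    return cdf / cdf[-1] * range_max


def clahe(
    img: PolarImage, block_size: int = 60, max_slope: float = 3.0, bins: int = 256
) -> PolarImage:
    """Contrast-limited adaptive histogram equalisation (FIJI parameterisation).

    The raster is divided into ``block_size`` x ``block_size`` contextual
    tiles. Each tile's intensity histogram (``bins`` bins over the bit range)
    is clipped so no equalisation slope exceeds ``max_slope``, and pixels are
    remapped by bilinear blending of the four surrounding tile mappings.
    Invalid (out-of-frame) samples are excluded from the histograms so the
    raster edge does not distort equalisation near the colony rim.
    """
    if block_size < 8:
        raise ValueError("block_size must be >= 8")
    h, w = img.pixels.shape
    if block_size > h or block_size > w:
        raise ValueError("block_size larger than image")

    range_max = img.range_max
    binned = np.clip(
        (img.pixels / range_max * bins).astype(int), 0, bins - 1
    )
    y_edges = _tile_edges(h, block_size)
    x_edges = _tile_edges(w, block_size)
    nty, ntx = len(y_edges), len(x_edges)

    luts = np.empty((nty, ntx, bins))
    for i, (y0, y1) in enumerate(y_edges):
        for j, (x0, x1) in enumerate(x_edges):
            tile_bins = binned[y0:y1, x0:x1][img.valid[y0:y1, x0:x1]]
            hist = np.bincount(tile_bins.ravel(), minlength=bins).astype(float)
            luts[i, j] = _clipped_lut(
                hist, tile_bins.size, bins, max_slope, range_max
            )

    def _axis_interp(n: int, edges: list[tuple[int, int]]):
        centres = np.array([(a + b - 1) / 2.0 for a, b in edges])
        pos = np.arange(n, dtype=float)
        idx = np.clip(np.searchsorted(centres, pos) - 1, 0, len(centres) - 2)
        if len(centres) == 1:
            return np.zeros(n, int), np.zeros(n, int), np.zeros(n)
        frac = (pos - centres[idx]) / (centres[idx + 1] - centres[idx])
        return idx, idx + 1, np.clip(frac, 0.0, 1.0)

    ty0, ty1, wy = _axis_interp(h, y_edges)
    tx0, tx1, wx = _axis_interp(w, x_edges)
    wy = wy[:, None]
    wx = wx[None, :]
    out = (
        (1 - wy) * (1 - wx) * luts[ty0[:, None], tx0[None, :], binned]
        + (1 - wy) * wx * luts[ty0[:, None], tx1[None, :], binned]
        + wy * (1 - wx) * luts[ty1[:, None], tx0[None, :], binned]
        + wy * wx * luts[ty1[:, None], tx1[None, :], binned]
    )
    return replace(img, pixels=out, valid=img.valid.copy())


def despeckle(img: PolarImage) -> PolarImage:
    """3x3 median filter (the classic despeckle), edge-replicated borders."""
    out = ndimage.median_filter(img.pixels, size=3, mode="nearest")
    return replace(img, pixels=out, valid=img.valid.copy())


def invert(img: PolarImage) -> PolarImage:
    """Bit-range complement, making dark channels appear as bright peaks."""
    return replace(img, pixels=img.range_max - img.pixels, valid=img.valid.copy())
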