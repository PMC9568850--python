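"""Independent brute-force reference implementations used as test oracles.

Everything here is written as directly and literally as possible (explicit
loops, no shared code with the package) so that agreement with the package
is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_disk_median(img: np.ndarray, radius: int) -> np.ndarray:
    """Disk-footprint median with edge replication, pixel by pixel."""
    h, w = img.shape
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy, dx in offsets:
                yy = min(max(y + dy, 0), h - 1)
                xx = min(max(x + dx, 0), w - 1)
                vals.append(img[yy, xx])
            out[y, x] = np.median(vals)
    return out


def brute_median_3x3(img: np.ndarray) -> np.ndarray:
    """Square 3x3 median with edge replication."""
    h, w = img.shape
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    vals.append(img[yy, xx])
            out[y, x] = np.median(vals)
    return out


def brute_circular_maxima(x: np.ndarray) -> list[int]:
    """Circular plateau-aware local maxima, midpoint representative."""
    n = len(x)
    if all(v == x[0] for v in x):
        return []
    maxima = []
    for i in range(n):
        # find the run of equal values containing i; only handle i == run start
        if x[i] == x[(i - 1) % n]:
            continue
        length = 1
        while x[(i + length) % n] == x[i]:
            length += 1
        if x[i] > x[(i - 1) % n] and x[i] > x[(i + length) % n]:
            maxima.append((i + (length - 1) // 2) % n)
    return sorted(maxima)


def brute_prominence(x: np.ndarray, peak: int) -> float:
    """Circular prominence by explicit two-sided scans."""
    n = len(x)
    h = x[peak]
    bases = []
    for direction in (1, -1):
        seen = []
        for step in range(1, n):
            v = x[(peak + direction * step) % n]
            if v > h:
                break
            seen.append(v)
        bases.append(min(seen) if seen else h)
    return float(h - max(bases))


def brute_detect_peaks(x, prominence_fraction=0.20, min_distance=9) -> list[int]:
    """Reference peak detector: maxima, prominence filter, distance rule."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return []
    cands = []
    for idx in brute_circular_maxima(x):
        prom = brute_prominence(x, idx)
        if prom >= prominence_fraction * (hi - lo):
            cands.append((idx, x[idx], prom))
    cands.sort(key=lambda c: (-c[1], -c[2], c[0]))
    kept = []
    for idx, _, _ in cands:
        if all(
            min(abs(idx - k), n - abs(idx - k)) >= min_distance for k in kept
        ):
            kept.append(idx)
    return sorted(kept)


def brute_remove_outliers(values, threshold=3.0) -> list[float]:
    """Reference modified z-score filter (single pass, strict threshold)."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    med = (
        vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2.0
    )
    abs_dev = sorted(abs(v - med) for v in vals)
    mad = abs_dev[n // 2] if n % 2 else (abs_dev[n // 2 - 1] + abs_dev[n // 2]) / 2.0
    out = []
    for v in values:
        v = float(v)
        if mad > 0:
            score = 0.6745 * (v - med) / mad
        else:
            mean_ad = sum(abs(u - med) for u in vals) / n
            score = (v - med) / (1.253314 * mean_ad) if mean_ad > 0 else 0.0
        if abs(score) <= threshold:
            out.append(v)
    return out


def enumerate_mannwhitney(a, b) -> tuple[float, float]:
    """Exact U and two-sided p by enumerating all group labelings."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    pooled = a + b
    n_a, n_b = len(a), len(b)

    def u_of(sample_a, sample_b):
        u = 0.0
        for x in sample_a:
            for y in sample_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_of(a, b)
    centre = n_a * n_b / 2.0
    total = 0
    as_extreme = 0
    for idx_a in combinations(range(len(pooled)), n_a):
        set_a = set(idx_a)
        sa = [pooled[i] for i in idx_a]
        sb = [pooled[i] for i in range(len(pooled)) if i not in set_a]
        u = u_of(sa, sb)
        total += 1
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            as_extreme += 1
    return u_obs, as_extreme / total
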