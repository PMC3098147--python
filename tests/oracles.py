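"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (flood fill, per-ray stepping, exhaustive
threshold search, per-value binning) kept separate from the package code they
cross-check.
"""

from __future__ import annotations

import numpy as np


def flood_fill_count(mask: np.ndarray) -> int:
    """Count connected components under full connectivity (8 in 2D, 26 in 3D)
    with an explicit-stack flood fill."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    offsets = [off for off in np.ndindex(*(3,) * mask.ndim)
               if any(o != 1 for o in off)]
    offsets = [tuple(o - 1 for o in off) for off in offsets]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            cur = stack.pop()
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nb, mask.shape)) \
                        and mask[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
    return count


def otsu_exhaustive(image: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search over all histogram bins for the threshold maximizing
    between-class variance; returns the bin-center threshold."""
    image = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(image, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    best_var, best_thr = -1.0, centers[0]
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[k - 1]
    return float(best_thr)


def otsu_between_class_variance(image: np.ndarray, threshold: float,
                                nbins: int = 256) -> float:
    """Between-class variance of the histogram split at a given threshold."""
    image = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(image, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    lo = centers <= threshold
    w0, w1 = counts[lo].sum(), counts[~lo].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (counts[lo] * centers[lo]).sum() / w0
    mu1 = (counts[~lo] * centers[~lo]).sum() / w1
    return (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2


def ray_sum(slice2d: np.ndarray, angle_deg: float, pixel_pitch_nm: float,
            step: float = 0.1) -> np.ndarray:
    """Per-ray stepping line integrals (dimensionless, Beer-Lambert exponent)
    of one (y, x) slice at one angle, bilinear interpolation.

    Geometry: 0 deg ray direction along +x; rotation center (n-1)/2; detector
    coordinate d satisfies d = c - (dy cos(t) + dx sin(t)) for a point offset
    (dy, dx) from the center.
    """
    img = np.asarray(slice2d, dtype=float)
    ny, nx = img.shape
    assert ny == nx, "oracle assumes square slices"
    n = nx
    c = (n - 1) / 2.0
    t = np.radians(angle_deg)
    u = np.array([-np.sin(t), np.cos(t)])        # ray direction (dy, dx)
    w = np.array([-np.cos(t), -np.sin(t)])       # detector axis direction
    half = n / np.sqrt(2.0)
    s_vals = np.arange(-half, half, step)
    out = np.zeros(n)
    for d in range(n):
        pts = (np.array([c, c]) + (d - c) * w)[None, :] + s_vals[:, None] * u[None, :]
        y, x = pts[:, 0], pts[:, 1]
        y0 = np.floor(y).astype(int)
        x0 = np.floor(x).astype(int)
        fy, fx = y - y0, x - x0
        total = np.zeros(len(s_vals))
        for dy_i, wy in ((0, 1 - fy), (1, fy)):
            for dx_i, wx in ((0, 1 - fx), (1, fx)):
                yy, xx = y0 + dy_i, x0 + dx_i
                ok = (yy >= 0) & (yy < n) & (xx >= 0) & (xx < n)
                vals = np.zeros(len(s_vals))
                vals[ok] = img[yy[ok], xx[ok]]
                total += wy * wx * vals
        out[d] = total.sum() * step
    return out * (pixel_pitch_nm / 1000.0)


def bin_by_search(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per-value binary-search histogram (right-exclusive except last bin)."""
    counts = np.zeros(len(edges) - 1, dtype=int)
    for v in values:
        lo, hi = 0, len(edges) - 1
        if v < edges[0] or v > edges[-1]:
            continue
        if v == edges[-1]:
            counts[-1] += 1
            continue
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if v >= edges[mid]:
                lo = mid
            else:
                hi = mid
        counts[lo] += 1
    return counts


def render_ball(shape, center, radius) -> np.ndarray:
    """Boolean ball mask; voxel centers at index + 0.5."""
    grids = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")
    q = sum((g - c) ** 2 for g, c in zip(grids, center))
    return q <= radius ** 2


def render_ellipsoid(shape, center, semi_axes, rotation=None) -> np.ndarray:
    """Boolean (possibly rotated) ellipsoid/ellipse mask."""
    grids = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")
    rel = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    if rotation is not None:
        rel = rel @ np.asarray(rotation)
    q = np.sum((rel / np.asarray(semi_axes)) ** 2, axis=-1)
    return q <= 1.0


def ks_statistic_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Max empirical-CDF difference scanned over every observed value."""
    a, b = np.sort(a), np.sort(b)
    pts = np.concatenate([a, b])
    stat = 0.0
    for p in pts:
        fa = np.mean(a <= p)
        fb = np.mean(b <= p)
        stat = max(stat, abs(fa - fb))
    return stat
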