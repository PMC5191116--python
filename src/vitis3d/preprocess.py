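"""Point-cloud cleanup: HSV background removal, statistical outlier removal,
moving-least-squares smoothing and minimum-distance subsampling.

The raw multi-view-stereo cloud of a night-time vineyard scan contains dark
mixed pixels on object borders (the black background bleeding into object
silhouettes), isolated outliers and surface noise. The stages below run in
the fixed order background -> SOR -> MLS -> subsample; each returns a subset
(or a smoothed version) of its input and never creates points.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import PointCloud


def rgb_to_hsv(colors: np.ndarray) -> np.ndarray:
    """Convert RGB in [0, 1] to HSV with H in degrees [0, 360), S, V in [0, 1].

    Standard hexcone formulas; achromatic pixels (S = 0) get H = 0.
    """
    colors = np.asarray(colors, dtype=np.float64)
    if colors.ndim != 2 or colors.shape[1] != 3:
        raise ValueError("colors must be (N, 3)")
    if colors.min(initial=0.0) < -1e-12 or colors.max(initial=0.0) > 1 + 1e-12:
        raise ValueError("RGB values must lie in [0, 1]")
    r, g, b = colors[:, 0], colors[:, 1], colors[:, 2]
    cmax = colors.max(axis=1)
    cmin = colors.min(axis=1)
    delta = cmax - cmin
    h = np.zeros_like(cmax)
    nz = delta > 0
    rmax = nz & (cmax == r)
    gmax = nz & ~rmax & (cmax == g)
    bmax = nz & ~rmax & ~gmax
    with np.errstate(invalid="ignore", divide="ignore"):
        h[rmax] = 60.0 * (((g[rmax] - b[rmax]) / delta[rmax]) % 6.0)
        h[gmax] = 60.0 * ((b[gmax] - r[gmax]) / delta[gmax] + 2.0)
        h[bmax] = 60.0 * ((r[bmax] - g[bmax]) / delta[bmax] + 4.0)
    h %= 360.0
    s = np.where(cmax > 0, delta / np.where(cmax > 0, cmax, 1.0), 0.0)
    return np.column_stack([h, s, cmax])


def remove_background(cloud: PointCloud, v_threshold: float):
    """Drop points whose HSV brightness V falls below ``v_threshold``.

    Removes the dark background and low-accuracy mixed border pixels.
    Returns ``(kept_cloud, removed_indices)``.
    """
    if cloud.colors is None:
        raise ValueError("background removal requires colors")
    v = rgb_to_hsv(cloud.colors)[:, 2]
    keep = v >= v_threshold
    removed = np.flatnonzero(~keep)
    return cloud.select(keep), removed


def sor_filter(cloud: PointCloud, k: int = 6, sigma_mult: float = 1.0):
    """Statistical outlier removal.

    For each point, the mean distance d_i to its k nearest neighbors is
    compared against the global mean mu and standard deviation sigma of all
    d_i; points with d_i > mu + sigma_mult * sigma are rejected.
    Returns ``(kept_cloud, removed_indices)``.
    """
    n = len(cloud)
    if n <= k:
        raise ValueError(f"SOR requires more than k={k} points (got {n})")
    tree = cKDTree(cloud.coords)
    # k+1 because the query returns the point itself at distance 0
    dists, _ = tree.query(cloud.coords, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    mu, sigma = mean_d.mean(), mean_d.std()
    keep = mean_d <= mu + sigma_mult * sigma
    removed = np.flatnonzero(~keep)
    return cloud.select(keep), removed


def _poly_terms(u: np.ndarray, v: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(u)]
    for total in range(1, order + 1):
        for j in range(total + 1):
            cols.append(u ** (total - j) * v**j)
    return np.column_stack(cols)


def mls_smooth(cloud: PointCloud, radius: float = 0.004, order: int = 2) -> PointCloud:
    """Moving-least-squares surface smoothing.

    Each point is projected onto a local bivariate polynomial of the given
    order, fitted by Gaussian-weighted least squares (weight scale radius/2)
    over its radius-neighborhood expressed in the frame of the local
    weighted-PCA plane. Points with too few neighbors pass through
    unmoved. Colors and labels are carried over; the point count is
    unchanged.
    """
    if radius <= 0:
        raise ValueError("MLS radius must be positive")
    if order not in (1, 2, 3):
        raise ValueError("MLS order must be 1, 2 or 3")
    coords = cloud.coords
    n = len(cloud)
    ncoef = (order + 1) * (order + 2) // 2
    min_nb = max(6, ncoef + 2)
    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, radius)
    h = radius / 2.0
    out = coords.copy()
    for i in range(n):
        nb = neighborhoods[i]
        if len(nb) < min_nb:
            continue
        pts = coords[nb]
        d2 = ((pts - coords[i]) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2.0 * h * h))
        wsum = w.sum()
        centroid = (w[:, None] * pts).sum(axis=0) / wsum
        centered = pts - centroid
        cov = (w[:, None] * centered).T @ centered / wsum
        evals, evecs = np.linalg.eigh(cov)
        normal = evecs[:, 0]
        tang = evecs[:, 1:]
        # local frame: heights along the plane normal, (u, v) in the plane
        uv = centered @ tang
        height = centered @ normal
        design = _poly_terms(uv[:, 0], uv[:, 1], order)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], height * sw, rcond=None)
        p_local = coords[i] - centroid
        pu, pv = p_local @ tang
        ph = _poly_terms(np.array([pu]), np.array([pv]), order)[0] @ coef
        out[i] = centroid + pu * tang[:, 0] + pv * tang[:, 1] + ph * normal
    smoothed = cloud.copy()
    smoothed.coords = out
    return smoothed


def subsample_min_distance(cloud: PointCloud, d_min: float = 0.001) -> PointCloud:
    """Greedy subsampling to a minimum point-to-point distance.

    Scans points in storage order over a spatial grid of cell size d_min
    and keeps a point iff no previously kept point lies within d_min
    (first-come retention; deterministic, no RNG). All attributes are
    carried through.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    coords = cloud.coords
    n = len(cloud)
    inv = 1.0 / d_min
    grid: dict[tuple[int, int, int], list[int]] = {}
    keep = np.zeros(n, dtype=bool)
    d2min = d_min * d_min
    for i in range(n):
        p = coords[i]
        cx, cy, cz = int(np.floor(p[0] * inv)), int(np.floor(p[1] * inv)), int(np.floor(p[2] * inv))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((cx + dx, cy + dy, cz + dz), ()):
                        d = coords[j] - p
                        if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] < d2min:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            keep[i] = True
            grid.setdefault((cx, cy, cz), []).append(i)
    return cloud.select(keep)


def preprocess(cloud: PointCloud, *, v_threshold: float = 0.10, sor_k: int = 6,
               sor_sigma_mult: float = 1.0, mls_radius: float = 0.004,
               mls_order: int = 2, subsample_min_dist: float = 0.001):
    """Run the full cleanup chain; returns (cloud, per-stage removal counts)."""
    counts = {"input": len(cloud)}
    cloud, removed = remove_background(cloud, v_threshold)
    counts["background_removed"] = len(removed)
    cloud, removed = sor_filter(cloud, sor_k, sor_sigma_mult)
    counts["sor_removed"] = len(removed)
    cloud = mls_smooth(cloud, mls_radius, mls_order)
    cloud = subsample_min_distance(cloud, subsample_min_dist)
    counts["after_subsample"] = len(cloud)
    return cloud, counts
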