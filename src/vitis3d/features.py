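"""Per-point descriptors: surface normals, 125-bin surface feature
histograms (SFH) and HSV color, concatenated into 128 features per point.

The SFH characterizes the local surface geometry around a point: for every
unordered pair of points in the r_H-neighborhood (the neighborhood includes
the query point itself), three Darboux-frame angle features of
point-feature-histogram type are computed from the pair's positions and
normals, each quantized into 5 equal-width bins over its analytic range, and
accumulated into a joint 5x5x5 = 125-bin histogram, normalized to sum 1.
Because the features are relative angles, the descriptor is invariant under
rigid motion. With r_N = 3 mm and r_H = 9 mm the histogram spans about one
and a half berries, so the "valley-ridge" geometry of a grape bunch surface
produces a histogram clearly distinct from locally planar leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .pointcloud import CameraTrack, PointCloud
from .preprocess import rgb_to_hsv

N_BINS_PER_ANGLE = 5
N_SFH_BINS = N_BINS_PER_ANGLE**3  # 125
N_FEATURES = N_SFH_BINS + 3       # + H, S, V


@dataclass
class SfhParams:
    r_N: float = 0.003
    r_H: float = 0.009

    def __post_init__(self) -> None:
        if not (self.r_H > self.r_N > 0):
            raise ValueError("radii must satisfy r_H > r_N > 0")


@dataclass
class FeatureMatrix:
    """N x 128 feature matrix: columns 0-124 SFH, 125-127 H, S, V (all in [0, 1])."""

    values: np.ndarray
    valid: np.ndarray  # per-row validity (enough neighbors for the SFH)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.valid = np.ascontiguousarray(self.valid, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must be (N, {N_FEATURES})")
        if self.valid.shape != (self.values.shape[0],):
            raise ValueError("valid mask must be (N,)")

    def __len__(self) -> int:
        return self.values.shape[0]


def estimate_normals(cloud: PointCloud, r_N: float, cameras: CameraTrack):
    """PCA surface normals over r_N-neighborhoods, oriented toward the camera.

    The normal of a point is the eigenvector of the neighborhood covariance
    with the smallest eigenvalue, sign-flipped so it points toward the
    nearest camera position (positive dot product with camera - point).
    Points with fewer than 3 neighbors (including themselves) get a NaN
    normal and ``valid = False``.

    Returns ``(normals, valid)``.
    """
    if r_N <= 0:
        raise ValueError("r_N must be positive")
    coords = cloud.coords
    n = len(cloud)
    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, r_N)
    normals = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    cams = cameras.positions
    for i in range(n):
        nb = neighborhoods[i]
        if len(nb) < 3:
            continue
        pts = coords[nb]
        centered = pts - pts.mean(axis=0)
        cov = centered.T @ centered
        evals, evecs = np.linalg.eigh(cov)
        normal = evecs[:, 0]
        d2 = ((cams - coords[i]) ** 2).sum(axis=1)
        to_cam = cams[int(np.argmin(d2))] - coords[i]
        if normal @ to_cam < 0:
            normal = -normal
        normals[i] = normal
        valid[i] = True
    return normals, valid


@njit(cache=True)
def _pair_bin(ps, ns, pt, nt):
    """Joint 125-bin index of the three Darboux angle features of a pair.

    The source point is the one whose normal subtends the smaller angle with
    the vector connecting it to the other point. Features: f1 = v . n_t in
    [-1, 1]; f2 = u . d in [-1, 1]; f3 = atan2(w . n_t, u . n_t) in
    (-pi, pi]. Equal-width bins; boundary values fall in the upper bin.
    """
    d = pt - ps
    dist = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
    if dist <= 0.0:
        return -1
    d = d / dist
    # pick the source: larger signed cosine with the outgoing direction
    cos_s = ns[0] * d[0] + ns[1] * d[1] + ns[2] * d[2]
    cos_t = -(nt[0] * d[0] + nt[1] * d[1] + nt[2] * d[2])
    if cos_t > cos_s:
        tmp = ps; ps = pt; pt = tmp
        tmpn = ns; ns = nt; nt = tmpn
        d = -d
    u = ns
    # v = u x d, normalized (degenerate when u parallel to d)
    vx = u[1] * d[2] - u[2] * d[1]
    vy = u[2] * d[0] - u[0] * d[2]
    vz = u[0] * d[1] - u[1] * d[0]
    vn = np.sqrt(vx * vx + vy * vy + vz * vz)
    if vn < 1e-12:
        return -1
    vx /= vn; vy /= vn; vz /= vn
    wx = u[1] * vz - u[2] * vy
    wy = u[2] * vx - u[0] * vz
    wz = u[0] * vy - u[1] * vx
    f1 = vx * nt[0] + vy * nt[1] + vz * nt[2]                      # [-1, 1]
    f2 = u[0] * d[0] + u[1] * d[1] + u[2] * d[2]                   # [-1, 1]
    f3 = np.arctan2(wx * nt[0] + wy * nt[1] + wz * nt[2],
                    u[0] * nt[0] + u[1] * nt[1] + u[2] * nt[2])    # (-pi, pi]
    b1 = int((f1 + 1.0) * 0.5 * N_BINS_PER_ANGLE)
    b2 = int((f2 + 1.0) * 0.5 * N_BINS_PER_ANGLE)
    b3 = int((f3 + np.pi) / (2.0 * np.pi) * N_BINS_PER_ANGLE)
    if b1 > N_BINS_PER_ANGLE - 1:
        b1 = N_BINS_PER_ANGLE - 1
    if b2 > N_BINS_PER_ANGLE - 1:
        b2 = N_BINS_PER_ANGLE - 1
    if b3 > N_BINS_PER_ANGLE - 1:
        b3 = N_BINS_PER_ANGLE - 1
    if b1 < 0:
        b1 = 0
    if b2 < 0:
        b2 = 0
    if b3 < 0:
        b3 = 0
    return b1 * 25 + b2 * 5 + b3


@njit(cache=True)
def _sfh_kernel(coords, normals, valid, indices, indptr):
    n = indptr.shape[0] - 1
    hist = np.zeros((n, N_SFH_BINS))
    ok = np.zeros(n, dtype=np.bool_)
    for i in range(n):
        start, end = indptr[i], indptr[i + 1]
        count = 0.0
        for a_idx in range(start, end):
            a = indices[a_idx]
            if not valid[a]:
                continue
            for b_idx in range(a_idx + 1, end):
                b = indices[b_idx]
                if not valid[b]:
                    continue
                k = _pair_bin(coords[a], normals[a], coords[b], normals[b])
                if k >= 0:
                    hist[i, k] += 1.0
                    count += 1.0
        if count > 0.0:
            for k in range(N_SFH_BINS):
                hist[i, k] /= count
            ok[i] = True
    return hist, ok


def compute_sfh(cloud: PointCloud, normals: np.ndarray, r_H: float,
                normals_valid: np.ndarray | None = None):
    """All-pairs 125-bin surface feature histogram per point.

    Points whose neighborhood yields fewer than one valid pair receive the
    zero histogram and ``valid = False``.

    Returns ``(histograms (N, 125), valid (N,))``.
    """
    if normals is None:
        raise ValueError("SFH requires normals")
    normals = np.asarray(normals, dtype=np.float64)
    if normals.shape != cloud.coords.shape:
        raise ValueError("normals shape must match coords")
    if normals_valid is None:
        normals_valid = np.isfinite(normals).all(axis=1)
    coords = cloud.coords
    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, r_H)
    lengths = np.fromiter((len(nb) for nb in neighborhoods), dtype=np.int64,
                          count=len(neighborhoods))
    indptr = np.zeros(len(cloud) + 1, dtype=np.int64)
    np.cumsum(lengths, out=indptr[1:])
    indices = np.concatenate([np.asarray(nb, dtype=np.int64) for nb in neighborhoods]) \
        if len(cloud) else np.zeros(0, dtype=np.int64)
    safe_normals = np.nan_to_num(normals, nan=0.0)
    hist, ok = _sfh_kernel(coords, safe_normals, np.ascontiguousarray(normals_valid),
                           indices, indptr)
    return hist, ok


def compute_features(cloud: PointCloud, sfh: np.ndarray,
                     sfh_valid: np.ndarray | None = None) -> FeatureMatrix:
    """Concatenate the SFH block with HSV color (H scaled to [0, 1])."""
    sfh = np.asarray(sfh, dtype=np.float64)
    if sfh.ndim != 2 or sfh.shape[1] != N_SFH_BINS:
        raise ValueError(f"sfh must be (N, {N_SFH_BINS})")
    if sfh.shape[0] != len(cloud):
        raise ValueError("sfh row count must match the cloud")
    if cloud.colors is None:
        raise ValueError("HSV features require colors")
    hsv = rgb_to_hsv(cloud.colors)
    hsv[:, 0] /= 360.0
    values = np.hstack([sfh, hsv])
    valid = np.ones(len(cloud), dtype=bool) if sfh_valid is None \
        else np.asarray(sfh_valid, dtype=bool)
    return FeatureMatrix(values=values, valid=valid)


def extract_features(cloud: PointCloud, cameras: CameraTrack,
                     params: SfhParams | None = None) -> FeatureMatrix:
    """Full descriptor chain: normals -> SFH -> SFH + HSV."""
    params = params or SfhParams()
    normals, nvalid = estimate_normals(cloud, params.r_N, cameras)
    sfh, svalid = compute_sfh(cloud, normals, params.r_H, nvalid)
    return compute_features(cloud, sfh, svalid)
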