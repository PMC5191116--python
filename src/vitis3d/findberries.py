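"""findBerries: randomized sphere-fitting berry detection.

A grape bunch is an aggregate of near-spherical berries; its surface
alternates between berry crowns ("ridges") and inter-berry gaps
("valleys"). The detector repeatedly draws a random source point from the
remaining bunch points, fits a sphere to its neighborhood, and runs a
hierarchical four-stage evaluation:

1. radius — reject spheres outside the plausible berry radius range;
2. support — points whose distance to the center diverges from the radius
   by more than 10% are outliers; the inlier fraction must be high enough;
3. valley test — a sphere fitted into the empty space between berries has
   no surface points along the ray from its center toward the nearest
   camera, a real berry crown does; require enough points on that line;
4. overlap — of two strongly overlapping spheres only the one with the
   larger support survives.

On acceptance, support points leave the remaining pool; the algorithm stops
after 2 x (#remaining points) consecutive failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .pointcloud import CameraTrack


class DegenerateFitError(ValueError):
    """Sphere fit impossible (too few or coplanar points)."""


@dataclass
class BerryParams:
    r_min: float = 0.004
    r_max: float = 0.010
    fit_radius: Optional[float] = None     # None -> 1.2 * r_max
    inlier_tol: float = 0.10
    min_support_ratio: float = 0.5
    min_fit_points: int = 10
    line_tol: float = 0.0015
    # at the pipeline's 1 mm subsampling a 1.5 mm line tube holds at most
    # ~4 points on a berry crown and 0-2 in a valley, so 3 is the largest
    # density-consistent requirement
    min_line_points: int = 3
    # upper bound on the norm of the mean support direction: rejects spheres
    # whose support huddles in a narrow cone (a noise-induced sphere tangent
    # to a flat leaf measures ~0.89) while even a partially seen berry cap
    # spreads far wider (<= 0.65 measured on rear-culled bunches)
    max_support_concentration: float = 0.8
    overlap_ratio: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")
        for name in ("inlier_tol", "min_support_ratio", "overlap_ratio"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.line_tol <= 0:
            raise ValueError("line_tol must be positive")

    @property
    def effective_fit_radius(self) -> float:
        return self.fit_radius if self.fit_radius is not None else 1.2 * self.r_max


@dataclass
class Berry:
    center: np.ndarray
    radius: float
    support: np.ndarray            # indices into the component cloud
    inlier_ratio: float
    n_line_points: int = 0
    raw_support_count: int = 0     # support size before removing points
                                   # already claimed by other berries

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class Verdict:
    accepted: bool
    reason: str                    # "accept" | "radius" | "support" | "valley" | "overlap"
    support: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    inlier_ratio: float = 0.0
    n_line_points: int = 0
    evict: List[int] = field(default_factory=list)  # accepted-berry list positions


def fit_sphere(points: np.ndarray):
    """Least-squares sphere fit.

    Algebraic linearization (||p||^2 = 2 c.p + (r^2 - ||c||^2)) solved by
    least squares, followed by one Gauss-Newton refinement of the geometric
    residuals. Returns ``(center, radius, rms_residual)``.

    Raises :class:`DegenerateFitError` for fewer than 4 points or a
    rank-deficient (coplanar) system.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (K, 3)")
    k = pts.shape[0]
    if k < 4:
        raise DegenerateFitError(f"sphere fit needs >= 4 points, got {k}")
    # center the data for conditioning; solve the 4x4 normal equations
    shift = pts.mean(axis=0)
    q = pts - shift
    a = np.empty((k, 4))
    a[:, :3] = 2.0 * q
    a[:, 3] = 1.0
    b = np.einsum("ij,ij->i", q, q)
    ata = a.T @ a
    ev = np.linalg.eigvalsh(ata)
    if ev[0] <= 1e-10 * max(ev[-1], 1e-30):
        raise DegenerateFitError("rank-deficient system (coplanar points)")
    sol = np.linalg.solve(ata, a.T @ b)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0 or not np.isfinite(r2):
        raise DegenerateFitError("non-positive squared radius")
    radius = float(np.sqrt(r2))
    # one Gauss-Newton step on the geometric residuals
    diff = q - center
    dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    good = dist > 1e-12
    if int(good.sum()) >= 4:
        e = dist[good] - radius
        jac = np.empty((e.shape[0], 4))
        jac[:, :3] = -diff[good] / dist[good, None]
        jac[:, 3] = -1.0
        jtj = jac.T @ jac
        jtj.flat[::5] += 1e-12
        try:
            step = np.linalg.solve(jtj, jac.T @ e)
            c_new = center - step[:3]
            r_new = radius - step[3]
            if r_new > 0:
                dn = q - c_new
                d_new = np.sqrt(np.einsum("ij,ij->i", dn, dn))
                if np.mean((d_new - r_new) ** 2) <= np.mean((dist - radius) ** 2):
                    center, radius, dist = c_new, float(r_new), d_new
        except np.linalg.LinAlgError:
            pass
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return center + shift, radius, rms


@njit(cache=True)
def _solve4(m, rhs):
    """4x4 Gaussian elimination with partial pivoting; flags tiny pivots."""
    a = np.empty((4, 5))
    a[:, :4] = m
    a[:, 4] = rhs
    scale = np.abs(m).max()
    if scale <= 0.0:
        return rhs, False
    for col in range(4):
        piv = col
        for r in range(col + 1, 4):
            if abs(a[r, col]) > abs(a[piv, col]):
                piv = r
        if abs(a[piv, col]) <= 1e-12 * scale:
            return rhs, False
        if piv != col:
            for c in range(5):
                tmp = a[col, c]
                a[col, c] = a[piv, c]
                a[piv, c] = tmp
        for r in range(col + 1, 4):
            f = a[r, col] / a[col, col]
            for c in range(col, 5):
                a[r, c] -= f * a[col, c]
    x = np.zeros(4)
    for r in range(3, -1, -1):
        s = a[r, 4]
        for c in range(r + 1, 4):
            s -= a[r, c] * x[c]
        x[r] = s / a[r, r]
    return x, True


@njit(cache=True)
def _fit_sphere_fast(pts, w):
    """Weighted algebraic sphere fit + one Gauss-Newton step.

    Same math as :func:`fit_sphere` with per-point weights (pass ones for
    the unweighted case). Returns (center(3,), radius, ok).
    """
    k = pts.shape[0]
    out = np.zeros(3)
    if k < 4:
        return out, 0.0, False
    sx = sy = sz = 0.0
    wsum = 0.0
    for i in range(k):
        sx += w[i] * pts[i, 0]; sy += w[i] * pts[i, 1]; sz += w[i] * pts[i, 2]
        wsum += w[i]
    if wsum <= 0.0:
        return out, 0.0, False
    sx /= wsum; sy /= wsum; sz /= wsum
    ata = np.zeros((4, 4))
    atb = np.zeros(4)
    for i in range(k):
        x = pts[i, 0] - sx; y = pts[i, 1] - sy; z = pts[i, 2] - sz
        b = x * x + y * y + z * z
        a0 = 2.0 * x; a1 = 2.0 * y; a2 = 2.0 * z
        wi = w[i]
        ata[0, 0] += wi * a0 * a0; ata[0, 1] += wi * a0 * a1
        ata[0, 2] += wi * a0 * a2; ata[0, 3] += wi * a0
        ata[1, 1] += wi * a1 * a1; ata[1, 2] += wi * a1 * a2; ata[1, 3] += wi * a1
        ata[2, 2] += wi * a2 * a2; ata[2, 3] += wi * a2
        ata[3, 3] += wi
        atb[0] += wi * a0 * b; atb[1] += wi * a1 * b
        atb[2] += wi * a2 * b; atb[3] += wi * b
    for r in range(4):
        for c in range(r):
            ata[r, c] = ata[c, r]
    sol, ok = _solve4(ata, atb)
    if not ok:
        return out, 0.0, False
    cx, cy, cz = sol[0], sol[1], sol[2]
    r2 = sol[3] + cx * cx + cy * cy + cz * cz
    if not (r2 > 0.0) or not np.isfinite(r2):
        return out, 0.0, False
    rad = np.sqrt(r2)
    # one Gauss-Newton refinement of the weighted geometric residuals
    jtj = np.zeros((4, 4))
    jte = np.zeros(4)
    sse0 = 0.0
    n_good = 0
    for i in range(k):
        dx = pts[i, 0] - sx - cx; dy = pts[i, 1] - sy - cy; dz = pts[i, 2] - sz - cz
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        if dist <= 1e-12:
            continue
        n_good += 1
        wi = w[i]
        e = dist - rad
        sse0 += wi * e * e
        j0 = -dx / dist; j1 = -dy / dist; j2 = -dz / dist
        jtj[0, 0] += wi * j0 * j0; jtj[0, 1] += wi * j0 * j1
        jtj[0, 2] += wi * j0 * j2; jtj[0, 3] -= wi * j0
        jtj[1, 1] += wi * j1 * j1; jtj[1, 2] += wi * j1 * j2; jtj[1, 3] -= wi * j1
        jtj[2, 2] += wi * j2 * j2; jtj[2, 3] -= wi * j2
        jtj[3, 3] += wi
        jte[0] += wi * j0 * e; jte[1] += wi * j1 * e
        jte[2] += wi * j2 * e; jte[3] -= wi * e
    if n_good >= 4:
        for r in range(4):
            for c in range(r):
                jtj[r, c] = jtj[c, r]
            jtj[r, r] += 1e-12
        step, ok2 = _solve4(jtj, jte)
        if ok2:
            nx = cx - step[0]; ny = cy - step[1]; nz = cz - step[2]
            nr = rad - step[3]
            if nr > 0.0:
                sse1 = 0.0
                for i in range(k):
                    dx = pts[i, 0] - sx - nx; dy = pts[i, 1] - sy - ny; dz = pts[i, 2] - sz - nz
                    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
                    e = dist - nr
                    sse1 += w[i] * e * e
                if sse1 <= sse0:
                    cx, cy, cz, rad = nx, ny, nz, nr
    out[0] = cx + sx; out[1] = cy + sy; out[2] = cz + sz
    return out, rad, True


@njit(cache=True)
def _fit_trim_fast(pts, source, sigma, r_min, r_max, inlier_tol, min_fit_points):
    """Source-weighted initial fit + up to 3 inlier-trimmed refits.

    ``pts`` is the whole-component neighborhood of ``source``. The initial
    fit weights points by a Gaussian of scale ``sigma`` around the source,
    biasing it toward the source's own berry; the unweighted trim refits
    then converge to that berry's shell. Because neither step depends on
    which points were already claimed by other berries, the sphere produced
    for a given source is independent of the acceptance order.
    """
    k = pts.shape[0]
    w = np.empty(k)
    inv = 1.0 / (2.0 * sigma * sigma)
    for i in range(k):
        dx = pts[i, 0] - source[0]; dy = pts[i, 1] - source[1]; dz = pts[i, 2] - source[2]
        w[i] = np.exp(-(dx * dx + dy * dy + dz * dz) * inv)
    center, rad, ok = _fit_sphere_fast(pts, w)
    if not ok:
        return center, rad, False
    ones = np.ones(k)
    if 0.5 * r_min <= rad <= 2.0 * r_max:
        for _ in range(3):
            tol = inlier_tol * max(rad, 1e-9)
            count = 0
            for i in range(k):
                dx = pts[i, 0] - center[0]; dy = pts[i, 1] - center[1]
                dz = pts[i, 2] - center[2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if abs(d - rad) <= tol:
                    count += 1
            if count < min_fit_points:
                break
            sub = np.empty((count, 3))
            j = 0
            for i in range(k):
                dx = pts[i, 0] - center[0]; dy = pts[i, 1] - center[1]
                dz = pts[i, 2] - center[2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if abs(d - rad) <= tol:
                    sub[j, 0] = pts[i, 0]; sub[j, 1] = pts[i, 1]; sub[j, 2] = pts[i, 2]
                    j += 1
            c_new, r_new, ok2 = _fit_sphere_fast(sub, ones[:count])
            if not ok2:
                break
            center, rad = c_new, r_new
    # the sphere must explain the surface patch it was seeded from: if the
    # source point is not an inlier of the final sphere, the fit drifted
    # onto some other structure and the candidate is discarded
    dx = source[0] - center[0]; dy = source[1] - center[1]; dz = source[2] - center[2]
    d_src = np.sqrt(dx * dx + dy * dy + dz * dz)
    if abs(d_src - rad) > inlier_tol * max(rad, 1e-9):
        return center, rad, False
    return center, rad, True


def _sphere_overlap(c_a, r_a, c_b, r_b) -> float:
    d = float(np.linalg.norm(np.asarray(c_a) - np.asarray(c_b)))
    return max(0.0, (r_a + r_b - d) / (2.0 * min(r_a, r_b)))


def evaluate_candidate(center, radius, coords: np.ndarray, tree: cKDTree,
                       cameras: CameraTrack, params: BerryParams,
                       accepted: List[Berry],
                       remaining: Optional[np.ndarray] = None) -> Verdict:
    """Hierarchical candidate checks, applied strictly in order 1 -> 4.

    ``coords``/``tree`` cover the whole component so partially removed
    berries still accumulate support evidence. ``remaining`` (boolean mask)
    marks unclaimed points; when given, the overlap stage compares the
    support a candidate could actually claim — unclaimed points plus the
    points a replaced berry would release — against the incumbent's claimed
    support, so a sphere straddling several already-claimed berry shells
    cannot inflate its support and evict a genuine berry.
    """
    center = np.asarray(center, dtype=np.float64)
    # (1) radius range
    if not (params.r_min <= radius <= params.r_max):
        return Verdict(False, "radius")
    # (2) support: inliers vs interior outliers within the sphere shell
    nearby = np.asarray(tree.query_ball_point(center, radius * (1.0 + params.inlier_tol)),
                        dtype=np.int64)
    if nearby.size == 0:
        return Verdict(False, "support")
    rel0 = coords[nearby] - center
    d = np.sqrt(np.einsum("ij,ij->i", rel0, rel0))
    inlier_mask = np.abs(d - radius) <= params.inlier_tol * radius
    n_in = int(inlier_mask.sum())
    n_out = int(nearby.size - n_in)
    ratio = n_in / (n_in + n_out)
    if n_in < params.min_fit_points or ratio < params.min_support_ratio:
        return Verdict(False, "support", inlier_ratio=ratio)
    support = nearby[inlier_mask]
    # support must wrap around the sphere, not huddle in a narrow tangent
    # cone the way a near-flat patch grazing the shell would
    dirs = rel0[inlier_mask] / d[inlier_mask, None]
    if np.linalg.norm(dirs.mean(axis=0)) > params.max_support_concentration:
        return Verdict(False, "support", inlier_ratio=ratio)
    # (3) valley test: enough support points on the line toward the camera
    cam = cameras.nearest(center)
    direction = cam - center
    norm = np.linalg.norm(direction)
    if norm <= 0:
        return Verdict(False, "valley", inlier_ratio=ratio)
    direction /= norm
    rel = rel0[inlier_mask]
    t = rel @ direction
    pr = rel - t[:, None] * direction
    perp = np.sqrt(np.einsum("ij,ij->i", pr, pr))
    on_line = (t >= 0) & (t <= radius + params.line_tol) & (perp <= params.line_tol)
    n_line = int(on_line.sum())
    if n_line < params.min_line_points:
        return Verdict(False, "valley", inlier_ratio=ratio, n_line_points=n_line)
    # (4) overlap with already accepted berries
    evict: List[int] = []
    claimable = np.ones(support.size, dtype=bool) if remaining is None \
        else remaining[support].copy()
    for pos, berry in enumerate(accepted):
        ov = _sphere_overlap(center, radius, berry.center, berry.radius)
        if ov > params.overlap_ratio:
            claim_plus = claimable | np.isin(support, berry.support)
            if int(claim_plus.sum()) > berry.support.size:
                evict.append(pos)
                claimable = claim_plus
            else:
                return Verdict(False, "overlap", support=support,
                               inlier_ratio=ratio, n_line_points=n_line)
    return Verdict(True, "accept", support=support, inlier_ratio=ratio,
                   n_line_points=n_line, evict=evict)


def find_berries(coords: np.ndarray, cameras: CameraTrack,
                 params: BerryParams | None = None,
                 seed: Optional[int] = None) -> List[Berry]:
    """Detect berries in one bunch-component point cloud.

    Loop: draw a source point uniformly from the remaining pool, gather its
    fit-radius neighborhood (within the pool), fit a sphere with one
    inlier-trimmed refit, evaluate; on acceptance remove the accepted
    support from the pool and reset the failure counter. Terminates when
    consecutive failures reach 2 x (#remaining) or the pool shrinks below
    ``min_fit_points``. Berries are returned sorted by support size
    (largest first).
    """
    params = params or BerryParams()
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coords must be a nonempty (N, 3) array")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    tree = cKDTree(coords)
    remaining = np.ones(coords.shape[0], dtype=bool)
    accepted: List[Berry] = []
    fails = 0
    fit_r = params.effective_fit_radius

    # sources are drawn in seeded random order, without replacement until the
    # pool changes: every remaining point gets its chance within the failure
    # budget, which stabilizes the detected set across seeds
    pool = np.flatnonzero(remaining)  # refreshed only when `remaining` changes
    queue = rng.permutation(pool)
    qi = 0
    while True:
        if pool.size < params.min_fit_points or fails >= 2 * pool.size:
            break
        if qi >= queue.size:
            queue = rng.permutation(pool)
            qi = 0
        source = int(queue[qi])
        qi += 1
        if not remaining[source]:
            continue
        nb = np.asarray(tree.query_ball_point(coords[source], fit_r), dtype=np.int64)
        if nb.size < params.min_fit_points:
            fails += 1
            continue
        center, radius, ok = _fit_trim_fast(coords[nb], coords[source],
                                            0.35 * params.r_max,
                                            params.r_min, params.r_max,
                                            params.inlier_tol, params.min_fit_points)
        if not ok:
            fails += 1
            continue
        verdict = evaluate_candidate(center, radius, coords, tree, cameras,
                                     params, accepted, remaining)
        if not verdict.accepted:
            fails += 1
            continue
        # final polish: refit on the full accepted support (which may span
        # more of the berry than the source neighborhood did); keep the
        # refined sphere only if it stays a valid berry
        if verdict.support.size >= params.min_fit_points:
            try:
                c_ref, r_ref, _ = fit_sphere(coords[verdict.support])
                if params.r_min <= r_ref <= params.r_max:
                    center, radius = c_ref, r_ref
            except DegenerateFitError:
                pass
        for pos in sorted(verdict.evict, reverse=True):
            evicted = accepted.pop(pos)
            remaining[evicted.support] = True
        support = verdict.support[remaining[verdict.support]]
        if support.size == 0:
            fails += 1
            continue
        accepted.append(Berry(center=center, radius=float(radius), support=support,
                              inlier_ratio=verdict.inlier_ratio,
                              n_line_points=verdict.n_line_points,
                              raw_support_count=int(verdict.support.size)))
        remaining[support] = False
        pool = np.flatnonzero(remaining)
        queue = rng.permutation(pool)
        qi = 0
        fails = 0

    accepted.sort(key=lambda b: -b.support.size)
    return accepted
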