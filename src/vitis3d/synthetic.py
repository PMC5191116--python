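"""Synthetic grapevine scenes with full ground truth.

Emulates the geometry of a multi-view-stereo reconstruction of a vineyard
row scanned from a track: berries of ~6 mm radius packed into ellipsoidal
bunches ("valley-ridge" surfaces), locally planar leaves, cylindrical
stems, ~1 mm surface sampling, Gaussian surface noise, isolated outliers,
dark background points, and a camera track 50-75 cm from the row with 15 cm
spacing at three heights. Points whose outward normal faces away from the
nearest camera are culled, emulating the one-sided coverage of a row
scanned from a single side.

Ground truth per point: class (0 = canopy, 1 = grape bunch), primitive kind,
bunch id; plus the list of true berries (center, radius, bunch id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .pointcloud import CameraTrack, PointCloud

# primitive kinds
KIND_BUNCH = 0
KIND_LEAF = 1
KIND_STEM = 2
KIND_OUTLIER = 3
KIND_BACKGROUND = 4


@dataclass
class SceneConfig:
    row_length: float = 1.0
    n_bunches: int = 4
    berries_per_bunch: Tuple[int, int] = (6, 10)
    berry_radius_mean: float = 0.006
    berry_radius_sd: float = 0.0005
    bunch_spacing: float = 0.25
    leaf_count: int = 30
    leaf_size: float = 0.018
    stem_count: int = 2
    stem_radius: float = 0.010
    stem_length: float = 0.5
    sampling_spacing: float = 0.001
    noise_sigma: float = 0.0002
    outlier_fraction: float = 0.002
    background_fraction: float = 0.05
    bunch_hsv: Tuple[float, float, float] = (90.0, 0.4, 0.45)
    bunch_hsv_jitter: Tuple[float, float, float] = (20.0, 0.1, 0.1)
    canopy_hsv: Tuple[float, float, float] = (110.0, 0.6, 0.55)
    canopy_hsv_jitter: Tuple[float, float, float] = (15.0, 0.15, 0.15)
    camera_distance: Tuple[float, float] = (0.5, 0.75)
    camera_step: float = 0.15
    camera_heights: Tuple[float, ...] = (1.1, 1.3, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("row_length", "bunch_spacing", "leaf_size", "stem_radius",
                     "sampling_spacing", "berry_radius_mean", "camera_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("outlier_fraction", "background_fraction"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass
class SyntheticScene:
    cloud: PointCloud                  # labels = true class per point
    cameras: CameraTrack
    kind: np.ndarray                   # per-point primitive kind
    bunch_ids: np.ndarray              # per-point bunch id, -1 outside bunches
    berries: List[Tuple[np.ndarray, float, int]]  # (center, radius, bunch id)
    config: Optional[SceneConfig] = None

    def __len__(self) -> int:
        return len(self.cloud)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit directions."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sample_sphere(center, radius: float, spacing: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Surface samples at approximately ``spacing`` point-to-point distance."""
    n = max(4, int(round(4.0 * np.pi * radius**2 / spacing**2)))
    dirs = _fibonacci_sphere(n) @ _random_rotation(rng).T
    return np.asarray(center) + radius * dirs


def _vogel_disk(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    r = np.sqrt(i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_bunch(n_berries: int, radius_dist: Tuple[str, float, float],
                   packing_gap: float, seed, spacing: float = 0.001,
                   max_attempts: int = 400):
    """Pack berries into an ellipsoidal bunch envelope and sample surfaces.

    ``radius_dist`` is ("normal", mean, sd) or ("uniform", low, high).
    Centers are placed by sequential random insertion: each new berry sits
    at a center-to-center distance within [r_i + r_j - overlap,
    r_i + r_j + packing_gap] of an existing berry and does not intrude
    deeper than the allowed overlap into any other. Surface points interior
    to another berry are discarded, producing the valley-ridge geometry.

    Returns ``(berries, points, owners, normals)`` where berries is a list
    of (center, radius), owners maps points to berry indices and normals
    are outward radial unit vectors.
    """
    if n_berries < 1:
        raise ValueError("n_berries must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kind, a, b = radius_dist
    def draw_radius() -> float:
        if kind == "normal":
            return float(np.clip(rng.normal(a, b), a - 3 * b if b else a, a + 3 * b if b else a))
        if kind == "uniform":
            return float(rng.uniform(a, b))
        raise ValueError(f"unknown radius distribution {kind!r}")

    radii = [draw_radius() for _ in range(n_berries)]
    mean_r = float(np.mean(radii))
    # envelope sized for ~30% packing fraction, elongated along z
    total = sum(r**3 for r in radii)
    ax = (total / (0.30 * 1.5)) ** (1.0 / 3.0)
    semi = np.array([ax, ax, 1.5 * ax])

    centers = [np.zeros(3)]
    for i in range(1, n_berries):
        r_new = radii[i]
        placed = False
        for _ in range(max_attempts):
            anchor = int(rng.integers(0, len(centers)))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            overlap = 0.25 * min(r_new, radii[anchor])
            d = radii[anchor] + r_new + rng.uniform(-overlap, packing_gap)
            cand = centers[anchor] + d * direction
            if ((cand / semi) ** 2).sum() > 1.0:
                continue
            ok = True
            for j, c in enumerate(centers):
                lim = radii[j] + r_new - 0.25 * min(r_new, radii[j])
                if np.linalg.norm(cand - c) < lim:
                    ok = False
                    break
            if ok:
                centers.append(cand)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"infeasible berry packing after {max_attempts} attempts "
                f"(berry {i + 1}/{n_berries})")

    pts_list, owner_list, nrm_list = [], [], []
    for i, (c, r) in enumerate(zip(centers, radii)):
        pts = sample_sphere(c, r, spacing, rng)
        keep = np.ones(len(pts), dtype=bool)
        for j, (c2, r2) in enumerate(zip(centers, radii)):
            if j == i:
                continue
            keep &= np.linalg.norm(pts - c2, axis=1) >= r2 - 0.3 * spacing
        pts = pts[keep]
        pts_list.append(pts)
        owner_list.append(np.full(len(pts), i, dtype=np.int64))
        nrm = (pts - c) / r
        nrm_list.append(nrm / np.linalg.norm(nrm, axis=1, keepdims=True))

    berries = [(centers[i], radii[i]) for i in range(n_berries)]
    points = np.vstack(pts_list)
    owners = np.concatenate(owner_list)
    normals = np.vstack(nrm_list)
    return berries, points, owners, normals


def _sample_leaf(center, radius: float, normal, spacing: float) -> np.ndarray:
    n = max(4, int(round(np.pi * radius**2 / spacing**2)))
    uv = _vogel_disk(n) * radius
    normal = np.asarray(normal) / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return np.asarray(center) + uv[:, 0, None] * t1 + uv[:, 1, None] * t2


def _sample_cylinder(base, axis, length: float, radius: float,
                     spacing: float, rng: np.random.Generator):
    axis = np.asarray(axis) / np.linalg.norm(axis)
    n = max(4, int(round(2.0 * np.pi * radius * length / spacing**2)))
    t = rng.uniform(0.0, length, size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(axis, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)
    radial = np.cos(theta)[:, None] * t1 + np.sin(theta)[:, None] * t2
    pts = np.asarray(base) + t[:, None] * axis + radius * radial
    return pts, radial


def _class_colors(n: int, hsv_mean, hsv_jitter, rng: np.random.Generator) -> np.ndarray:
    h = (rng.normal(hsv_mean[0], hsv_jitter[0], size=n) % 360.0) / 360.0
    s = np.clip(rng.normal(hsv_mean[1], hsv_jitter[1], size=n), 0.02, 1.0)
    v = np.clip(rng.normal(hsv_mean[2], hsv_jitter[2], size=n), 0.15, 1.0)
    return hsv_to_rgb(np.column_stack([h, s, v]))


def make_camera_track(row_length: float, distance: Tuple[float, float],
                      step: float, heights: Tuple[float, ...]) -> CameraTrack:
    xs = np.arange(-0.1, row_length + 0.1 + step / 2, step)
    y = -0.5 * (distance[0] + distance[1])
    positions = [np.array([x, y, h]) for h in heights for x in xs]
    return CameraTrack(positions=np.asarray(positions))


def generate_scene(config: SceneConfig | None = None) -> SyntheticScene:
    """Full synthetic row: bunches + leaves + stems + noise + outliers +
    background, with one-sided visibility culling. Deterministic per seed."""
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed)
    row_length = max(config.row_length, config.n_bunches * config.bunch_spacing)
    cameras = make_camera_track(row_length, config.camera_distance,
                                config.camera_step, config.camera_heights)

    pts_all, nrm_all, kind_all, bunch_all = [], [], [], []
    berries: List[Tuple[np.ndarray, float, int]] = []

    # grape bunches in the lower bunch zone
    bunch_centers = []
    for b in range(config.n_bunches):
        n_berries = int(rng.integers(config.berries_per_bunch[0],
                                     config.berries_per_bunch[1] + 1))
        blist, pts, owners, nrm = generate_bunch(
            n_berries, ("normal", config.berry_radius_mean, config.berry_radius_sd),
            packing_gap=0.002, seed=rng, spacing=config.sampling_spacing)
        offset = np.array([
            (b + 0.5) * config.bunch_spacing + rng.uniform(-0.1, 0.1) * config.bunch_spacing,
            rng.uniform(-0.02, 0.02),
            rng.uniform(0.70, 0.90),
        ])
        bunch_centers.append(offset)
        for c, r in blist:
            berries.append((c + offset, r, b))
        pts_all.append(pts + offset)
        nrm_all.append(nrm)
        kind_all.append(np.full(len(pts), KIND_BUNCH, dtype=np.int64))
        bunch_all.append(np.full(len(pts), b, dtype=np.int64))
    bunch_centers = np.asarray(bunch_centers)
    bunch_extent = 0.08  # generous bound on bunch envelope half-size

    # leaves in the canopy zone, clear of the bunches
    for _ in range(config.leaf_count):
        for _ in range(100):
            center = np.array([rng.uniform(0.0, row_length),
                               rng.uniform(-0.05, 0.05),
                               rng.uniform(0.85, 1.70)])
            clearance = bunch_extent + config.leaf_size + 0.01
            if np.linalg.norm(bunch_centers - center, axis=1).min() > clearance:
                break
        normal = rng.normal(size=3)
        normal[1] -= 1.0  # bias toward facing the camera side
        normal /= np.linalg.norm(normal)
        pts = _sample_leaf(center, config.leaf_size, normal, config.sampling_spacing)
        pts_all.append(pts)
        nrm_all.append(np.tile(normal, (len(pts), 1)))
        kind_all.append(np.full(len(pts), KIND_LEAF, dtype=np.int64))
        bunch_all.append(np.full(len(pts), -1, dtype=np.int64))

    # stems: near-vertical cylinders between the bunches
    for s in range(config.stem_count):
        x = (s + 1.0) * row_length / (config.stem_count + 1.0)
        if len(bunch_centers):
            # nudge away from the nearest bunch along the row
            dx = x - bunch_centers[:, 0]
            nearest = np.argmin(np.abs(dx))
            if abs(dx[nearest]) < bunch_extent + config.stem_radius + 0.01:
                x = bunch_centers[nearest, 0] + np.sign(dx[nearest] or 1.0) * (
                    bunch_extent + config.stem_radius + 0.02)
        base = np.array([x, 0.0, 0.4])
        axis = np.array([rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1), 1.0])
        pts, radial = _sample_cylinder(base, axis, config.stem_length,
                                       config.stem_radius,
                                       config.sampling_spacing, rng)
        pts_all.append(pts)
        nrm_all.append(radial)
        kind_all.append(np.full(len(pts), KIND_STEM, dtype=np.int64))
        bunch_all.append(np.full(len(pts), -1, dtype=np.int64))

    points = np.vstack(pts_all)
    normals = np.vstack(nrm_all)
    kind = np.concatenate(kind_all)
    bunch_ids = np.concatenate(bunch_all)

    # one-sided visibility: keep points facing their nearest camera
    cams = cameras.positions
    nearest_cam = cams[np.argmin(
        ((points[:, None, :] - cams[None, :, :]) ** 2).sum(axis=2), axis=1)] \
        if len(points) * len(cams) < 40_000_000 else _nearest_cam_blocked(points, cams)
    visible = ((nearest_cam - points) * normals).sum(axis=1) > 0
    points, normals = points[visible], normals[visible]
    kind, bunch_ids = kind[visible], bunch_ids[visible]

    # surface noise along the normal
    if config.noise_sigma > 0:
        points = points + normals * rng.normal(0.0, config.noise_sigma,
                                               size=(len(points), 1))

    n_surface = len(points)
    extra_pts, extra_kind = [], []
    n_out = int(round(config.outlier_fraction * n_surface))
    if n_out:
        lo = points.min(axis=0) - 0.05
        hi = points.max(axis=0) + 0.05
        extra_pts.append(rng.uniform(lo, hi, size=(n_out, 3)))
        extra_kind.append(np.full(n_out, KIND_OUTLIER, dtype=np.int64))
    n_bg = int(round(config.background_fraction * n_surface))
    if n_bg:
        bg = np.column_stack([
            rng.uniform(-0.1, row_length + 0.1, size=n_bg),
            rng.uniform(0.10, 0.40, size=n_bg),       # behind the row
            rng.uniform(0.2, 1.8, size=n_bg),
        ])
        extra_pts.append(bg)
        extra_kind.append(np.full(n_bg, KIND_BACKGROUND, dtype=np.int64))
    if extra_pts:
        points = np.vstack([points] + extra_pts)
        kind = np.concatenate([kind] + extra_kind)
        bunch_ids = np.concatenate([bunch_ids,
                                    np.full(sum(len(p) for p in extra_pts), -1,
                                            dtype=np.int64)])

    labels = (kind == KIND_BUNCH).astype(np.int64)

    colors = np.zeros((len(points), 3))
    m = kind == KIND_BUNCH
    colors[m] = _class_colors(int(m.sum()), config.bunch_hsv,
                              config.bunch_hsv_jitter, rng)
    m = (kind == KIND_LEAF) | (kind == KIND_STEM) | (kind == KIND_OUTLIER)
    colors[m] = _class_colors(int(m.sum()), config.canopy_hsv,
                              config.canopy_hsv_jitter, rng)
    m = kind == KIND_BACKGROUND
    if m.any():
        h = rng.uniform(0.0, 1.0, size=int(m.sum()))
        s = rng.uniform(0.0, 0.5, size=int(m.sum()))
        v = rng.uniform(0.01, 0.06, size=int(m.sum()))
        colors[m] = hsv_to_rgb(np.column_stack([h, s, v]))

    cloud = PointCloud(coords=points, colors=colors, labels=labels)
    return SyntheticScene(cloud=cloud, cameras=cameras, kind=kind,
                          bunch_ids=bunch_ids, berries=berries, config=config)


def _nearest_cam_blocked(points: np.ndarray, cams: np.ndarray) -> np.ndarray:
    out = np.empty_like(points)
    for start in range(0, len(points), 100_000):
        chunk = points[start:start + 100_000]
        idx = np.argmin(((chunk[:, None, :] - cams[None, :, :]) ** 2).sum(axis=2), axis=1)
        out[start:start + len(chunk)] = cams[idx]
    return out


def _occlusion_cull(points: np.ndarray, berries, viewpoints: np.ndarray,
                    shrink: float = 0.0003) -> np.ndarray:
    """Line-of-sight visibility mask.

    A point survives if the segment to at least one viewpoint misses every
    berry sphere (spheres shrunk by ``shrink`` so surface points are not
    blocked by the sphere they lie on; a ray crossing a berry interior —
    including the point's own rear side — is genuine occlusion)."""
    n = len(points)
    visible = np.zeros(n, dtype=bool)
    centers = np.array([c for c, r in berries])
    radii = np.array([r for c, r in berries])
    for v in viewpoints:
        cand = ~visible
        if not cand.any():
            break
        p = points[cand]
        d = v[None, :] - p                      # segment directions
        seg2 = np.einsum("ij,ij->i", d, d)
        blocked = np.zeros(len(p), dtype=bool)
        for c, r in zip(centers, radii):
            rr = max(r - shrink, 0.0)
            m = p - c[None, :]
            b = np.einsum("ij,ij->i", m, d)
            cc = np.einsum("ij,ij->i", m, m) - rr * rr
            disc = b * b - seg2 * cc
            hit = disc > 0
            if not hit.any():
                continue
            sq = np.sqrt(np.maximum(disc, 0.0))
            t_lo = (-b - sq) / seg2
            t_hi = (-b + sq) / seg2
            eps = 1e-6
            blocked |= hit & (t_hi > eps) & (t_lo < 1.0 - eps)
        vis_idx = np.flatnonzero(cand)[~blocked]
        visible[vis_idx] = True
    return visible


def generate_artificial_bunch(n_berries: int = 50,
                              diameter_range: Tuple[float, float] = (0.015, 0.020),
                              noise_sigma: float = 0.0,
                              seed: int = 0,
                              spacing: float = 0.0005,
                              camera_distance: float = 0.6,
                              cull: bool = False) -> SyntheticScene:
    """Desk-scale analog of a high-resolution scan of an artificial bunch.

    Berry diameters are uniform in ``diameter_range``; sampling is dense
    (0.5 mm) and, by default, covers the full berry surfaces the way an
    articulated-arm line scanner does. With ``cull=True`` the rear
    hemisphere (facing away from the camera) is removed instead, emulating
    a one-sided track reconstruction.
    """
    rng = np.random.default_rng(seed)
    lo, hi = diameter_range
    blist, pts, owners, nrm = generate_bunch(
        n_berries, ("uniform", lo / 2.0, hi / 2.0), packing_gap=0.002,
        seed=rng, spacing=spacing)
    cameras = CameraTrack(positions=np.array([
        [0.0, -camera_distance, 0.0],
        [0.15, -camera_distance, 0.0],
        [-0.15, -camera_distance, 0.0],
    ]))
    if cull:
        # one-sided track reconstruction: rear hemisphere removed
        cam = cameras.positions[0]
        visible = ((cam - pts) * nrm).sum(axis=1) > 0
    else:
        # all-around scan: keep line-of-sight surfaces only, the way an
        # articulated-arm scanner circling the bunch sees them
        views = camera_distance * _fibonacci_sphere(26)
        visible = _occlusion_cull(pts, blist, views)
    pts, nrm, owners = pts[visible], nrm[visible], owners[visible]
    if noise_sigma > 0:
        pts = pts + nrm * rng.normal(0.0, noise_sigma, size=(len(pts), 1))
    colors = _class_colors(len(pts), (90.0, 0.4, 0.45), (20.0, 0.1, 0.1), rng)
    labels = np.ones(len(pts), dtype=np.int64)
    cloud = PointCloud(coords=pts, colors=colors, labels=labels)
    berries = [(c, r, 0) for c, r in blist]
    return SyntheticScene(cloud=cloud, cameras=cameras,
                          kind=np.full(len(pts), KIND_BUNCH, dtype=np.int64),
                          bunch_ids=owners.copy() * 0, berries=berries)
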