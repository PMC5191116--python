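"""Normals, surface feature histograms and the 128-dim descriptor."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from vitis3d.features import (N_SFH_BINS, SfhParams, compute_features, compute_sfh,
                              estimate_normals, extract_features)
from vitis3d.pointcloud import CameraTrack, PointCloud
from vitis3d.preprocess import rgb_to_hsv
from vitis3d.synthetic import sample_sphere


def sfh_brute(coords, normals, valid, r_H):
    """Independent pure-Python SFH: all pairs, Darboux angles, 5^3 bins."""
    tree = cKDTree(coords)
    n = len(coords)
    hists = np.zeros((n, N_SFH_BINS))
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        nb = [j for j in tree.query_ball_point(coords[i], r_H) if valid[j]]
        count = 0
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                s, t = nb[a], nb[b]
                d = coords[t] - coords[s]
                dist = np.linalg.norm(d)
                if dist <= 0:
                    continue
                d = d / dist
                # source has the smaller angle between normal and connecting vector
                if normals[t] @ (-d) > normals[s] @ d:
                    s, t = t, s
                    d = -d
                u = normals[s]
                v = np.cross(u, d)
                nv = np.linalg.norm(v)
                if nv < 1e-12:
                    continue
                v = v / nv
                w = np.cross(u, v)
                f1 = v @ normals[t]
                f2 = u @ d
                f3 = np.arctan2(w @ normals[t], u @ normals[t])
                b1 = min(int((f1 + 1) / 2 * 5), 4)
                b2 = min(int((f2 + 1) / 2 * 5), 4)
                b3 = min(int((f3 + np.pi) / (2 * np.pi) * 5), 4)
                hists[i, b1 * 25 + b2 * 5 + b3] += 1
                count += 1
        if count:
            hists[i] /= count
            ok[i] = True
    return hists, ok


def plane_cloud(n=300, seed=0, extent=0.03):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, extent, (n, 2))
    return PointCloud(coords=np.column_stack([xy, np.zeros(n)]))


CAM_ABOVE = CameraTrack(positions=np.array([[0.015, 0.015, 0.5]]))


class TestEstimateNormals:
    def test_plane_normals_point_up(self):
        cloud = plane_cloud()
        normals, valid = estimate_normals(cloud, 0.003, CAM_ABOVE)
        # a few sparse corner points may lack the 3 neighbors needed
        assert valid.sum() >= 0.9 * len(cloud)
        np.testing.assert_allclose(normals[valid],
                                   np.tile([0, 0, 1.0], (int(valid.sum()), 1)),
                                   atol=1e-9)

    def test_sphere_normals_radial(self):
        rng = np.random.default_rng(1)
        pts = sample_sphere(np.zeros(3), 0.006, 0.0005, rng)
        cloud = PointCloud(coords=pts)
        cam = CameraTrack(positions=np.array([[0, 0, 1.0]]))
        normals, valid = estimate_normals(cloud, 0.003, cam)
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        # orientation flips the lower hemisphere; compare up to sign
        cosang = np.abs((normals[valid] * radial[valid]).sum(axis=1))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).max() < 5

    def test_two_point_cloud_undefined(self):
        cloud = PointCloud(coords=np.array([[0, 0, 0], [1, 1, 1.0]]))
        normals, valid = estimate_normals(cloud, 0.5, CAM_ABOVE)
        assert not valid.any()
        assert np.isnan(normals).all()

    def test_orientation_faces_camera(self):
        cloud = plane_cloud(seed=2)
        below = CameraTrack(positions=np.array([[0.015, 0.015, -0.5]]))
        n_up, _ = estimate_normals(cloud, 0.003, CAM_ABOVE)
        n_dn, _ = estimate_normals(cloud, 0.003, below)
        np.testing.assert_allclose(n_up, -n_dn, atol=1e-12)

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            estimate_normals(plane_cloud(), -1.0, CAM_ABOVE)


class TestComputeSfh:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        pts = sample_sphere(np.zeros(3), 0.006, 0.0015, rng)[:50]
        cloud = PointCloud(coords=pts)
        cam = CameraTrack(positions=np.array([[0, 0, 0.6]]))
        normals, valid = estimate_normals(cloud, 0.004, cam)
        got, gok = compute_sfh(cloud, normals, 0.009, valid)
        want, wok = sfh_brute(pts, np.nan_to_num(normals), valid, 0.009)
        np.testing.assert_array_equal(gok, wok)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_plane_mass_in_parallel_normal_bins(self):
        cloud = plane_cloud(n=50, seed=4, extent=0.012)
        normals, valid = estimate_normals(cloud, 0.004, CAM_ABOVE)
        sfh, ok = compute_sfh(cloud, normals, 0.009, valid)
        # parallel normals: f1 = 0 (middle bin), f3 = 0 (middle bin)
        mass = sfh.reshape(-1, 5, 5, 5)[ok][:, 2, :, 2].sum(axis=1)
        np.testing.assert_allclose(mass, 1.0, atol=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pts = sample_sphere(np.zeros(3), 0.006, 0.001, rng)
        cam = CameraTrack(positions=np.array([[0.0, 0.0, 0.6]]))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        shift = np.array([0.3, -0.2, 0.5])

        def descr(coords, cameras):
            cloud = PointCloud(coords=coords)
            normals, valid = estimate_normals(cloud, 0.003, cameras)
            return compute_sfh(cloud, normals, 0.009, valid)[0]

        h0 = descr(pts, cam)
        h1 = descr(pts @ q.T + shift,
                   CameraTrack(positions=cam.positions @ q.T + shift))
        assert np.abs(h1 - h0).max() <= 1e-9

    def test_sparse_points_flagged_invalid(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        cloud = PointCloud(coords=coords)
        normals = np.tile([0, 0, 1.0], (3, 1))
        sfh, ok = compute_sfh(cloud, normals, 0.009)
        assert not ok.any()
        assert (sfh == 0).all()

    def test_histograms_are_probability_vectors(self):
        rng = np.random.default_rng(6)
        pts = sample_sphere(np.zeros(3), 0.006, 0.001, rng)
        cloud = PointCloud(coords=pts)
        cam = CameraTrack(positions=np.array([[0, 0, 0.6]]))
        normals, valid = estimate_normals(cloud, 0.003, cam)
        sfh, ok = compute_sfh(cloud, normals, 0.009, valid)
        assert (sfh >= 0).all()
        np.testing.assert_allclose(sfh[ok].sum(axis=1), 1.0, atol=1e-9)


class TestSeparability:
    def test_sphere_vs_plane_nearest_centroid(self):
        """Berry-sized sphere patches vs planar patches must be separable
        by nearest-centroid on mean histograms (>= 95% of 200 patches)."""
        rng = np.random.default_rng(7)
        cam = CameraTrack(positions=np.array([[0, 0, 0.6]]))
        feats, labels = [], []
        for k in range(200):
            if k % 2:
                pts = sample_sphere(np.zeros(3), 0.006, 0.001, rng)
                pts = pts[pts[:, 2] > 0]  # camera-facing hemisphere
                labels.append(1)
            else:
                xy = rng.uniform(-0.009, 0.009, (250, 2))
                pts = np.column_stack([xy, np.zeros(len(xy))])
                labels.append(0)
            pts = pts + rng.normal(0, 0.0002, pts.shape)
            cloud = PointCloud(coords=pts)
            normals, valid = estimate_normals(cloud, 0.003, cam)
            sfh, ok = compute_sfh(cloud, normals, 0.009, valid)
            feats.append(sfh[ok].mean(axis=0))
        feats = np.array(feats)
        labels = np.array(labels)
        c0 = feats[labels == 0].mean(axis=0)
        c1 = feats[labels == 1].mean(axis=0)
        pred = (np.abs(feats - c1).sum(axis=1) < np.abs(feats - c0).sum(axis=1))
        acc = (pred == labels).mean()
        assert acc >= 0.95
        # between-class separation exceeds within-class spread
        between = np.abs(c1 - c0).sum()
        within = max(np.abs(feats[labels == 0] - c0).sum(axis=1).mean(),
                     np.abs(feats[labels == 1] - c1).sum(axis=1).mean())
        assert between > within


class TestComputeFeatures:
    def test_single_row_shape(self):
        cloud = PointCloud(coords=np.zeros((1, 3)), colors=np.array([[0.2, 0.4, 0.6]]))
        fm = compute_features(cloud, np.zeros((1, N_SFH_BINS)))
        assert fm.values.shape == (1, 128)

    def test_sfh_block_conserved_and_hsv_matches(self):
        rng = np.random.default_rng(8)
        pts = sample_sphere(np.zeros(3), 0.006, 0.001, rng)
        colors = rng.uniform(0, 1, (len(pts), 3))
        cloud = PointCloud(coords=pts, colors=colors)
        cam = CameraTrack(positions=np.array([[0, 0, 0.6]]))
        fm = extract_features(cloud, cam, SfhParams())
        np.testing.assert_allclose(fm.values[fm.valid, :N_SFH_BINS].sum(axis=1),
                                   1.0, atol=1e-9)
        hsv = rgb_to_hsv(colors)
        np.testing.assert_allclose(fm.values[:, 125], hsv[:, 0] / 360.0, atol=1e-12)
        np.testing.assert_allclose(fm.values[:, 126:], hsv[:, 1:], atol=1e-12)
        assert (fm.values[:, 125:] >= 0).all() and (fm.values[:, 125:] <= 1).all()

    def test_dimension_mismatch_rejected(self):
        cloud = PointCloud(coords=np.zeros((2, 3)), colors=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            compute_features(cloud, np.zeros((3, N_SFH_BINS)))
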