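"""Sphere fitting and the four-stage berry detector."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from vitis3d.findberries import (Berry, BerryParams, DegenerateFitError,
                                 evaluate_candidate, find_berries, fit_sphere)
from vitis3d.pointcloud import CameraTrack
from vitis3d.synthetic import generate_artificial_bunch, sample_sphere
from vitis3d.yieldreport import score_berries

CAM = CameraTrack(positions=np.array([[0.0, -0.6, 0.0]]))


class TestFitSphere:
    def test_exact_recovery_to_1e9(self):
        rng = np.random.default_rng(0)
        center = np.array([1.0, 2.0, 3.0])
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        c, r, rms = fit_sphere(center + 0.006 * dirs)
        assert np.abs(c - center).max() <= 1e-9
        assert abs(r - 0.006) <= 1e-9
        assert rms <= 1e-9

    def test_coplanar_points_degenerate(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(0, 1, (20, 2)), np.zeros(20)])
        with pytest.raises(DegenerateFitError):
            fit_sphere(pts)

    def test_too_few_points_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_sphere(np.eye(3))

    def test_noisy_hemisphere_radius_accuracy(self):
        """Monte-Carlo: 0.2 mm noise on a hemisphere keeps the radius
        estimate within 0.5 mm across 100 seeds."""
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            dirs = rng.normal(size=(150, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            dirs = dirs[dirs[:, 2] > 0]
            pts = 0.006 * dirs + rng.normal(0, 0.0002, (len(dirs), 3))
            _, r, _ = fit_sphere(pts)
            errs.append(abs(r - 0.006))
        assert max(errs) <= 0.0005


class TestEvaluateCandidate:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.pts = sample_sphere(np.zeros(3), 0.006, 0.001, rng)
        self.pts = self.pts[self.pts[:, 1] < 0.002]  # mostly camera-facing
        self.tree = cKDTree(self.pts)
        self.params = BerryParams(seed=0)

    def test_out_of_range_radius_rejected_first(self):
        v = evaluate_candidate(np.zeros(3), 0.015, self.pts, self.tree, CAM,
                               self.params, [])
        assert not v.accepted and v.reason == "radius"

    def test_clean_berry_accepted(self):
        v = evaluate_candidate(np.zeros(3), 0.006, self.pts, self.tree, CAM,
                               self.params, [])
        assert v.accepted and v.reason == "accept"
        assert v.support.size >= self.params.min_fit_points
        assert v.n_line_points >= self.params.min_line_points

    def test_valley_sphere_rejected(self):
        """Two berries side by side: a sphere centered in the gap has no
        surface points toward the camera and must fail the valley test."""
        rng = np.random.default_rng(3)
        c1 = np.array([-0.0063, 0, 0])
        c2 = np.array([0.0063, 0, 0])
        pts = np.vstack([sample_sphere(c1, 0.006, 0.001, rng),
                         sample_sphere(c2, 0.006, 0.001, rng)])
        tree = cKDTree(pts)
        # candidate in the waist between the berries, grazing both shells
        v = evaluate_candidate(np.zeros(3), 0.006, pts, tree, CAM,
                               BerryParams(seed=0, min_support_ratio=0.05), [])
        assert not v.accepted and v.reason == "valley"

    def test_overlap_smaller_support_rejected(self):
        incumbent = Berry(center=np.zeros(3), radius=0.006,
                          support=np.arange(100_000), inlier_ratio=0.95)
        v = evaluate_candidate(np.array([0.001, 0, 0]), 0.006, self.pts,
                               self.tree, CAM, self.params, [incumbent])
        assert not v.accepted and v.reason == "overlap"

    def test_overlap_larger_support_evicts(self):
        incumbent = Berry(center=np.zeros(3), radius=0.006,
                          support=np.arange(5), inlier_ratio=0.95)
        v = evaluate_candidate(np.array([0.001, 0, 0]), 0.006, self.pts,
                               self.tree, CAM, self.params, [incumbent])
        assert v.accepted and v.evict == [0]


class TestFindBerries:
    def test_single_clean_berry(self):
        rng = np.random.default_rng(4)
        pts = sample_sphere(np.array([0.0, 0.0, 0.0]), 0.006, 0.001, rng)
        berries = find_berries(pts, CAM, BerryParams(seed=1))
        assert len(berries) == 1
        assert abs(berries[0].radius - 0.006) <= 1e-4

    def test_planar_leaf_yields_nothing(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(-0.02, 0.02, (1500, 2))
        pts = np.column_stack([xy[:, 0], np.zeros(1500), xy[:, 1]])
        pts += rng.normal(0, 0.0001, pts.shape)
        assert find_berries(pts, CAM, BerryParams(seed=2)) == []

    def test_ten_berry_bunch_recovered_across_seeds(self):
        """Field-like 10-berry bunch: 10 +/- 1 berries over 20 seeds, all
        matched to true centers within 2 mm."""
        scene = generate_artificial_bunch(n_berries=10,
                                          diameter_range=(0.012, 0.012),
                                          noise_sigma=0.0002, spacing=0.001,
                                          seed=3, cull=True)
        ref = [(c, 2 * r) for c, r, _ in scene.berries]
        for seed in range(20):
            berries = find_berries(scene.cloud.coords, scene.cameras,
                                   BerryParams(seed=seed))
            assert 9 <= len(berries) <= 11
            ev = score_berries(berries, ref, match_dist=0.002)
            assert ev.false_positives == 0
            assert ev.true_positives == len(berries)

    def test_supports_disjoint_and_postconditions(self):
        scene = generate_artificial_bunch(n_berries=12,
                                          diameter_range=(0.012, 0.012),
                                          noise_sigma=0.0002, spacing=0.001,
                                          seed=6, cull=True)
        params = BerryParams(seed=0)
        berries = find_berries(scene.cloud.coords, scene.cameras, params)
        seen = set()
        for b in berries:
            s = set(b.support.tolist())
            assert s, "support must be nonempty"
            assert not (s & seen), "supports must be pairwise disjoint"
            seen |= s
            assert params.r_min <= b.radius <= params.r_max
            assert b.inlier_ratio >= params.min_support_ratio
            assert b.n_line_points >= params.min_line_points

    def test_deterministic_given_seed(self):
        scene = generate_artificial_bunch(n_berries=8,
                                          diameter_range=(0.012, 0.012),
                                          noise_sigma=0.0002, spacing=0.001,
                                          seed=7, cull=True)
        b1 = find_berries(scene.cloud.coords, scene.cameras, BerryParams(seed=5))
        b2 = find_berries(scene.cloud.coords, scene.cameras, BerryParams(seed=5))
        assert len(b1) == len(b2)
        for x, y in zip(b1, b2):
            np.testing.assert_array_equal(x.support, y.support)
            np.testing.assert_allclose(x.center, y.center)

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            find_berries(np.zeros((0, 3)), CAM, BerryParams())
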