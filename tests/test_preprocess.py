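"""Cleanup stages: HSV conversion, background removal, SOR, MLS, subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitis3d.pointcloud import PointCloud
from vitis3d.preprocess import (mls_smooth, remove_background, rgb_to_hsv, sor_filter,
                                subsample_min_distance)
from vitis3d.synthetic import KIND_BACKGROUND, SceneConfig, generate_scene


def _scalar_hsv(r, g, b):
    """Independent scalar hexcone conversion (textbook max/min formulas)."""
    cmax, cmin = max(r, g, b), min(r, g, b)
    delta = cmax - cmin
    if delta == 0:
        h = 0.0
    elif cmax == r:
        h = 60.0 * (((g - b) / delta) % 6)
    elif cmax == g:
        h = 60.0 * ((b - r) / delta + 2)
    else:
        h = 60.0 * ((r - g) / delta + 4)
    s = 0.0 if cmax == 0 else delta / cmax
    return h % 360.0, s, cmax


class TestRgbToHsv:
    def test_pure_red(self):
        np.testing.assert_allclose(rgb_to_hsv(np.array([[1.0, 0, 0]]))[0], [0, 1, 1])

    def test_achromatic_gray(self):
        np.testing.assert_allclose(rgb_to_hsv(np.array([[0.5, 0.5, 0.5]]))[0],
                                   [0, 0, 0.5])

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(0)
        rgb = rng.uniform(0, 1, (200, 3))
        rgb[0] = [0.2, 0.4, 0.6]
        got = rgb_to_hsv(rgb)
        want = np.array([_scalar_hsv(*row) for row in rgb])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_hsv(np.array([[1.2, 0, 0]]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ranges(self, seed):
        rgb = np.random.default_rng(seed).uniform(0, 1, (20, 3))
        hsv = rgb_to_hsv(rgb)
        assert (hsv[:, 0] >= 0).all() and (hsv[:, 0] < 360).all()
        assert (hsv[:, 1:] >= 0).all() and (hsv[:, 1:] <= 1).all()


class TestRemoveBackground:
    def test_all_black_removed(self):
        cloud = PointCloud(coords=np.random.default_rng(0).uniform(0, 1, (50, 3)),
                           colors=np.full((50, 3), 0.02))
        kept, removed = remove_background(cloud, 0.1)
        assert len(kept) == 0 and len(removed) == 50

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        cloud = PointCloud(coords=rng.uniform(0, 1, (50, 3)),
                           colors=rng.uniform(0, 1, (50, 3)))
        kept, removed = remove_background(cloud, 0.0)
        assert len(kept) == 50 and removed.size == 0

    def test_missing_colors_rejected(self):
        with pytest.raises(ValueError):
            remove_background(PointCloud(coords=np.zeros((3, 3))), 0.1)

    def test_removes_exactly_the_generated_background(self):
        scene = generate_scene(SceneConfig(seed=9, n_bunches=1, leaf_count=4,
                                           stem_count=1, row_length=0.3,
                                           bunch_spacing=0.3))
        _, removed = remove_background(scene.cloud, 0.1)
        np.testing.assert_array_equal(np.sort(removed),
                                      np.flatnonzero(scene.kind == KIND_BACKGROUND))


class TestSorFilter:
    @staticmethod
    def _brute_removed(coords, k, mult):
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        d.sort(axis=1)
        mean_d = d[:, 1:k + 1].mean(axis=1)
        return np.flatnonzero(mean_d > mean_d.mean() + mult * mean_d.std())

    def test_displaced_grid_point_removed(self):
        g = np.stack(np.meshgrid(*[np.arange(10) * 0.001] * 3), axis=-1).reshape(-1, 3)
        g[333] += 0.05
        cloud = PointCloud(coords=g)
        _, removed = sor_filter(cloud, k=6, sigma_mult=1.0)
        np.testing.assert_array_equal(removed, [333])

    def test_huge_sigma_is_identity(self):
        cloud = PointCloud(coords=np.random.default_rng(2).uniform(0, 0.1, (200, 3)))
        kept, removed = sor_filter(cloud, k=6, sigma_mult=1e9)
        assert removed.size == 0 and len(kept) == 200

    def test_matches_brute_force_oracle(self):
        coords = np.random.default_rng(3).uniform(0, 0.05, (400, 3))
        _, removed = sor_filter(PointCloud(coords=coords), k=8, sigma_mult=1.0)
        np.testing.assert_array_equal(removed, self._brute_removed(coords, 8, 1.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sor_filter(PointCloud(coords=np.zeros((5, 3))), k=6, sigma_mult=1.0)


class TestMlsSmooth:
    def test_plane_is_fixed_point(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 0.05, (400, 2))
        coords = np.column_stack([xy, np.zeros(400)])
        out = mls_smooth(PointCloud(coords=coords), radius=0.004, order=2)
        assert np.abs(out.coords - coords).max() <= 1e-9

    def test_quadratic_surface_fixed_for_order_two(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(-0.01, 0.01, (600, 2))
        z = 2.0 * xy[:, 0] ** 2 + 1.0 * xy[:, 1] ** 2 - 0.5 * xy[:, 0] * xy[:, 1]
        coords = np.column_stack([xy, z])
        out = mls_smooth(PointCloud(coords=coords), radius=0.004, order=2)
        assert np.abs(out.coords - coords).max() <= 1e-6

    def test_reduces_radial_noise_on_sphere(self):
        rng = np.random.default_rng(6)
        n = 4000
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        r = 0.006
        noisy = dirs * (r + rng.normal(0, 0.0002, (n, 1)))
        out = mls_smooth(PointCloud(coords=noisy), radius=0.002, order=2)
        rms_before = np.sqrt(np.mean((np.linalg.norm(noisy, axis=1) - r) ** 2))
        rms_after = np.sqrt(np.mean((np.linalg.norm(out.coords, axis=1) - r) ** 2))
        assert rms_after < rms_before

    def test_preserves_count_and_attributes(self):
        rng = np.random.default_rng(7)
        cloud = PointCloud(coords=rng.uniform(0, 0.02, (100, 3)),
                           colors=rng.uniform(0, 1, (100, 3)),
                           labels=rng.integers(0, 2, 100))
        out = mls_smooth(cloud, radius=0.004, order=1)
        assert len(out) == 100
        np.testing.assert_array_equal(out.colors, cloud.colors)
        np.testing.assert_array_equal(out.labels, cloud.labels)

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            mls_smooth(PointCloud(coords=np.zeros((5, 3))), radius=0.0)


class TestSubsample:
    def test_close_pair_keeps_first(self):
        coords = np.array([[0, 0, 0], [0.0005, 0, 0], [0.01, 0, 0]])
        out = subsample_min_distance(PointCloud(coords=coords), 0.001)
        np.testing.assert_array_equal(out.coords, coords[[0, 2]])

    def test_already_sparse_identity(self):
        coords = np.arange(30).reshape(10, 3) * 0.01
        out = subsample_min_distance(PointCloud(coords=coords), 0.001)
        np.testing.assert_array_equal(out.coords, coords)

    def test_min_distance_property_brute_force(self):
        coords = np.random.default_rng(8).uniform(0, 0.05, (10_000, 3))
        out = subsample_min_distance(PointCloud(coords=coords), 0.001)
        assert len(out) < len(coords)
        # O(N^2) verification in chunks
        kept = out.coords
        for start in range(0, len(kept), 2000):
            chunk = kept[start:start + 2000]
            d = np.linalg.norm(chunk[:, None, :] - kept[None, :, :], axis=2)
            d[np.arange(len(chunk)), start + np.arange(len(chunk))] = np.inf
            assert d.min() >= 0.001 - 1e-12

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=10, deadline=None)
    def test_output_is_subset_in_order(self, seed):
        coords = np.random.default_rng(seed).uniform(0, 0.01, (300, 3))
        out = subsample_min_distance(PointCloud(coords=coords), 0.001)
        # kept points appear in input order as a subsequence
        idx = []
        j = 0
        for row in out.coords:
            while j < len(coords) and not np.array_equal(coords[j], row):
                j += 1
            assert j < len(coords)
            idx.append(j)
            j += 1
        assert len(idx) == len(out)
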