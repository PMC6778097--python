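"""Phantom generator: rasterization oracle, ground truth, determinism,
two-modality tissue volumes."""

import numpy as np
import pytest

import lumenline as L
from lumenline.phantom import (
    BranchSpec,
    TubeSpec,
    arc_curve,
    make_oblique_cylinder,
    make_two_modality_phantom,
    make_tube,
    piecewise_linear_radius,
    random_class_map,
    slab_class_map,
    straight_curve,
    swelling_radius,
)


def brute_force_tube_mask(curve_fn, radius_fn, grid_shape, n_t=4000):
    """Independent rasterization oracle: per-voxel minimum distance to a
    densely sampled curve, checking against the local radius.

    Works voxel by voxel over the full grid with no spatial index,
    mirroring the tube definition directly.
    """
    t = np.linspace(0.0, 1.0, n_t)
    pts = curve_fn(t)
    radii = np.asarray(radius_fn(t))
    mask = np.zeros(grid_shape, dtype=bool)
    seg = pts[1:] - pts[:-1]
    seg_len2 = np.maximum(np.einsum("ij,ij->i", seg, seg), 1e-300)
    for i in range(grid_shape[0]):
        for j in range(grid_shape[1]):
            for k in range(grid_shape[2]):
                p = np.array([i, j, k], dtype=float)
                rel = p - pts[:-1]
                s = np.clip(np.einsum("ij,ij->i", rel, seg) / seg_len2, 0.0, 1.0)
                d2 = np.einsum("ij,ij->i", rel - s[:, None] * seg, rel - s[:, None] * seg)
                best = np.argmin(d2)
                r_local = radii[best] + s[best] * (radii[best + 1] - radii[best])
                if d2[best] <= r_local**2:
                    mask[i, j, k] = True
    return mask


class TestMakeTube:
    def test_straight_tube_slices_match_exhaustive_oracle(self):
        # small grid so the brute-force oracle is affordable
        spec = TubeSpec(
            curve=straight_curve((10.0, 10.0, 0.0), (10.0, 10.0, 19.0)),
            radius_profile=6.0,
            grid_shape=(21, 21, 20),
        )
        mask, _ = make_tube(spec)
        oracle = brute_force_tube_mask(spec.curve_fn(), spec.radius_fn(), spec.grid_shape)
        np.testing.assert_array_equal(mask.data, oracle)
        # every z-slice is the lattice disc of radius 6
        x, y = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
        disc = (x - 10.0) ** 2 + (y - 10.0) ** 2 <= 36.0
        for z in range(20):
            np.testing.assert_array_equal(mask.data[:, :, z], disc)

    def test_ground_truth_area_is_analytic_circle_area(self, straight_tube):
        _, truth = straight_tube
        np.testing.assert_allclose(truth.areas, np.pi * 100.0, rtol=1e-12)

    def test_swelling_tube_matches_oracle_and_area_trend(self):
        radius = swelling_radius(6.0, [(0.5, 6.0, 0.12)])
        spec = TubeSpec(
            curve=straight_curve((14.0, 14.0, 0.0), (14.0, 14.0, 39.0)),
            radius_profile=radius,
            grid_shape=(29, 29, 40),
        )
        mask, truth = make_tube(spec)
        oracle = brute_force_tube_mask(spec.curve_fn(), spec.radius_fn(), spec.grid_shape)
        np.testing.assert_array_equal(mask.data, oracle)
        # per-slice counts rise toward the bump and fall after it
        counts = mask.data.sum(axis=(0, 1)).astype(float)
        mid = len(counts) // 2
        assert (np.diff(counts[4:mid]) >= 0).all()
        assert (np.diff(counts[mid : len(counts) - 4]) <= 0).all()
        # ground-truth area follows pi r(t)^2
        np.testing.assert_allclose(truth.areas, np.pi * truth.radii**2, rtol=1e-12)

    def test_rasterized_area_converges_for_radius_8_and_up(self):
        for r in (8.0, 10.0, 14.0):
            n = int(2 * r) + 9
            c = (n - 1) / 2.0
            spec = TubeSpec(
                curve=straight_curve((c, c, 0.0), (c, c, 19.0)),
                radius_profile=r,
                grid_shape=(n, n, 20),
            )
            mask, _ = make_tube(spec)
            count = mask.data[:, :, 10].sum()
            assert abs(count - np.pi * r**2) / (np.pi * r**2) <= 0.05

    def test_centerline_points_are_foreground(self, swelling_tube, branch_tube):
        for mask, truth in (swelling_tube, branch_tube):
            idx = np.round(truth.centerline_points).astype(int)
            assert mask.data[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_deterministic_output(self):
        spec = TubeSpec(
            curve=arc_curve((16.0, 16.0, 4.0), 40.0, 15.0),
            radius_profile=piecewise_linear_radius([0, 0.5, 1], [4, 7, 4]),
            grid_shape=(32, 32, 52),
        )
        m1, t1 = make_tube(spec)
        m2, t2 = make_tube(spec)
        np.testing.assert_array_equal(m1.data, m2.data)
        np.testing.assert_array_equal(t1.centerline_points, t2.centerline_points)

    def test_subvoxel_radius_rejected(self):
        spec = TubeSpec(
            curve=straight_curve((16.0, 16.0, 0.0), (16.0, 16.0, 31.0)),
            radius_profile=1.5,
            grid_shape=(32, 32, 32),
        )
        with pytest.raises(ValueError, match="2 voxels"):
            make_tube(spec)

    def test_tube_exiting_grid_rejected(self):
        spec = TubeSpec(
            curve=straight_curve((4.0, 16.0, 0.0), (4.0, 16.0, 31.0)),
            radius_profile=8.0,
            grid_shape=(32, 32, 32),
        )
        with pytest.raises(ValueError, match="exits the grid"):
            make_tube(spec)

    def test_branch_radius_exceeding_parent_rejected(self):
        spec = TubeSpec(
            curve=straight_curve((24.0, 24.0, 4.0), (24.0, 24.0, 44.0)),
            radius_profile=5.0,
            grid_shape=(48, 48, 48),
            branch=BranchSpec(0.5, (1.0, 0.0, 0.0), 10.0, 8.0),
        )
        with pytest.raises(ValueError, match="branch radius"):
            make_tube(spec)

    def test_branch_attach_t_bounds(self):
        with pytest.raises(ValueError):
            BranchSpec(0.0, (1.0, 0.0, 0.0), 10.0, 3.0)


class TestObliqueCylinder:
    def test_angle_zero_equals_straight_tube(self):
        mask, truth = make_oblique_cylinder(0.0, 8.0, (48, 48, 48))
        c = truth.centerline_points
        assert np.allclose(c[:, 0], c[0, 0]) and np.allclose(c[:, 1], c[0, 1])
        x, y = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
        disc = (x - c[0, 0]) ** 2 + (y - c[0, 1]) ** 2 <= 64.0
        np.testing.assert_array_equal(mask.data[:, :, 24], disc)

    def test_per_slice_count_inflated_by_inverse_cosine(self, oblique30):
        mask, _ = oblique30
        counts = mask.data.sum(axis=(0, 1)).astype(float)
        interior = counts[25:70]  # away from the tube ends
        ratio = np.median(interior) / (np.pi * 100.0)
        assert ratio == pytest.approx(1.0 / np.cos(np.deg2rad(30.0)), rel=0.03)

    def test_ground_truth_area_independent_of_angle(self):
        _, truth = make_oblique_cylinder(45.0, 8.0, (96, 48, 64))
        np.testing.assert_allclose(truth.areas, np.pi * 64.0, rtol=1e-12)

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_oblique_cylinder(60.0, 8.0, (64, 64, 64))


class TestTwoModalityPhantom:
    def test_vanishing_noise_gives_class_relabeling(self):
        cm = slab_class_map((12, 12, 12), (0.25, 0.25, 0.25, 0.25))
        means = [10.0, 20.0, 30.0, 40.0]
        va, vb = make_two_modality_phantom(cm, means, [1e-9] * 4, means, [1e-9] * 4, seed=0)
        np.testing.assert_allclose(va.data, np.asarray(means)[cm], atol=1e-6)
        np.testing.assert_allclose(vb.data, np.asarray(means)[cm], atol=1e-6)

    def test_random_class_masses_within_binomial_bound(self):
        props = (0.4, 0.3, 0.2, 0.1)
        cm = random_class_map((64, 64, 64), props, seed=5)
        n = cm.size
        for lab, p in enumerate(props):
            observed = (cm == lab).sum()
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 3 * sigma

    def test_shared_noise_concentrates_joint_histogram_on_diagonal(self):
        cm = slab_class_map((24, 24, 24), (0.25, 0.25, 0.25, 0.25))
        means = [10.0, 20.0, 30.0, 40.0]
        va, vb = make_two_modality_phantom(
            cm, means, [1.0] * 4, means, [1.0] * 4, seed=3, shared_noise=True
        )
        np.testing.assert_allclose(va.data, vb.data)

    def test_same_seed_bit_identical(self):
        cm = random_class_map((16, 16, 16), (0.5, 0.3, 0.1, 0.1), seed=1)
        a1, b1 = make_two_modality_phantom(cm, [0, 1, 2, 3], [1] * 4, [0, 1, 2, 3], [1] * 4, seed=9)
        a2, b2 = make_two_modality_phantom(cm, [0, 1, 2, 3], [1] * 4, [0, 1, 2, 3], [1] * 4, seed=9)
        np.testing.assert_array_equal(a1.data, a2.data)
        np.testing.assert_array_equal(b1.data, b2.data)

    def test_absent_label_rejected(self):
        cm = np.zeros((8, 8, 8), dtype=int)  # only label 0 present
        with pytest.raises(ValueError, match="absent"):
            make_two_modality_phantom(cm, [0, 1], [1, 1], [0, 1], [1, 1], seed=0)

    def test_nonpositive_sigma_rejected(self):
        cm = slab_class_map((8, 8, 8), (0.5, 0.5))
        with pytest.raises(ValueError, match="sigmas"):
            make_two_modality_phantom(cm, [0, 1], [1, 0], [0, 1], [1, 1], seed=0)
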