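"""Iterative centerline extraction: initialization, tangents, oblique
slicing, relaxation formulas, convergence behavior."""

import warnings

import numpy as np
import pytest

import lumenline as L
from lumenline.centerline import (
    Centerline,
    CenterlineParams,
    PlanarSlice,
    extract_centerline,
    extract_slice,
    initial_centerline,
    relax_update,
    residual,
    slice_center,
    tangents,
)
from lumenline.volume_io import LumenMask
from conftest import interior_deviations, truth_lookup


class TestInitialCenterline:
    def test_straight_tube_centroids_on_axis(self, straight_tube):
        mask, _ = straight_tube
        c = initial_centerline(mask, sigma=20.0)
        np.testing.assert_allclose(c.points[:, 0], 32.0, atol=1e-9)
        np.testing.assert_allclose(c.points[:, 1], 32.0, atol=1e-9)
        np.testing.assert_allclose(c.points[:, 2], np.arange(80.0), atol=1e-6)

    def test_tilted_cylinder_centroids_on_axis(self, oblique30):
        # away from the end caps (whose oblique z-cuts bias the centroids),
        # per-z centroids of the elliptical sections sit on the tilted axis
        mask, truth = oblique30
        c = initial_centerline(mask, sigma=5.0)
        n = len(c.points)
        devs = interior_deviations(c.points[n // 3 : 2 * n // 3], truth)
        assert devs.max() < 0.5

    def test_degenerate_smoothing_returns_exact_centroids(self):
        data = np.zeros((6, 6, 3), dtype=bool)
        data[1, 1, 0] = data[2, 2, 1] = data[3, 3, 2] = True
        c = initial_centerline(LumenMask(data), sigma=0.0)
        np.testing.assert_allclose(
            c.points, [[1, 1, 0], [2, 2, 1], [3, 3, 2]], atol=1e-12
        )

    def test_interior_gap_interpolated(self):
        data = np.zeros((9, 9, 5), dtype=bool)
        for z, c in [(0, 2), (1, 3), (3, 5), (4, 6)]:
            data[c, c, z] = True
        c = initial_centerline(LumenMask(data), sigma=0.0)
        np.testing.assert_allclose(c.points[2], [4.0, 4.0, 2.0], atol=1e-12)

    def test_too_few_slices_rejected(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 1] = data[2, 2, 2] = True
        with pytest.raises(ValueError, match="3 z-slices"):
            initial_centerline(LumenMask(data))


class TestTangents:
    def test_straight_line_unit_tangent(self):
        pts = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        tf = tangents(Centerline(pts))
        np.testing.assert_allclose(tf.tangents, [[0, 0, 1]] * 10, atol=1e-12)

    def test_circle_tangent_orthogonal_to_radius(self):
        theta = np.linspace(0.0, np.pi, 400)
        pts = np.column_stack([np.cos(theta), np.zeros_like(theta), np.sin(theta)])
        tf = tangents(Centerline(pts))
        dots = np.abs(np.einsum("ij,ij->i", tf.tangents, pts))
        assert dots.max() < 1e-3

    def test_endpoint_stencil_matches_hand_formula(self):
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 1.0], [1.5, 5.0, 2.0]])
        tf = tangents(Centerline(pts))
        expected0 = (-3 * pts[0] + 4 * pts[1] - pts[2]) / 2.0
        expected2 = (3 * pts[2] - 4 * pts[1] + pts[0]) / 2.0
        np.testing.assert_allclose(tf.tangents[0], expected0 / np.linalg.norm(expected0), atol=1e-12)
        np.testing.assert_allclose(tf.tangents[2], expected2 / np.linalg.norm(expected2), atol=1e-12)

    def test_second_order_exact_on_quadratic_curve(self):
        """One-sided and central stencils reproduce the derivative of a
        quadratic exactly (second-order accuracy has no error term here)."""
        k = np.arange(7.0)
        pts = np.column_stack([0.5 * k**2 + k, 2 * k - 0.25 * k**2, k])
        deriv = np.column_stack([k + 1.0, 2 - 0.5 * k, np.ones_like(k)])
        tf = tangents(Centerline(pts))
        expected = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)
        np.testing.assert_allclose(tf.tangents, expected, atol=1e-12)

    def test_duplicate_points_inherit_nearest_tangent(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 1], [0, 0, 2]], dtype=float)
        tf = tangents(Centerline(pts))
        np.testing.assert_allclose(np.linalg.norm(tf.tangents, axis=1), 1.0, atol=1e-12)


class TestExtractSlice:
    def test_axis_aligned_slice_equals_stored_plane(self, straight_tube):
        mask, _ = straight_tube
        sl = extract_slice(mask, np.array([32.0, 32.0, 40.0]), np.array([0.0, 0.0, 1.0]), 20.0)
        fg = sl.grid >= 0.5
        # reconstruct the same window from the voxel grid
        stored = mask.data[12:53, 12:53, 40]
        assert fg.sum() == stored.sum()

    def test_disc_area_within_tolerance(self, straight_tube):
        mask, _ = straight_tube
        sl = extract_slice(mask, np.array([32.0, 32.0, 40.0]), np.array([0.0, 0.0, 1.0]), 21.0)
        area = (sl.grid >= 0.5).sum()
        assert abs(area - np.pi * 100) / (np.pi * 100) < 0.05

    def test_oblique_cylinder_orthogonal_section_not_elliptical(self, oblique30):
        mask, truth = oblique30
        mid = len(truth.centerline_points) // 2
        axis = truth.centerline_points[-1] - truth.centerline_points[0]
        axis = axis / np.linalg.norm(axis)
        sl = extract_slice(mask, truth.centerline_points[mid], axis, 20.0)
        area = (sl.grid >= 0.5).sum()
        assert area == pytest.approx(np.pi * 100.0, rel=0.05)
        # whereas the z-plane cut is inflated by 1/cos(30 deg)
        z = int(round(truth.centerline_points[mid][2]))
        naive = mask.data[:, :, z].sum()
        assert naive / area > 1.10

    def test_non_unit_tangent_rejected(self, straight_tube):
        mask, _ = straight_tube
        with pytest.raises(ValueError, match="unit"):
            extract_slice(mask, np.zeros(3), np.array([0.0, 0.0, 2.0]), 5.0)


class TestSliceCenter:
    @staticmethod
    def _make_slice(grid):
        n = grid.shape[0]
        return PlanarSlice(
            grid=grid.astype(float),
            in_plane_axes=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
            origin=np.zeros(3),
            spacing=1.0,
            normal=np.array([0.0, 0.0, 1.0]),
        )

    def test_centered_disc_maps_to_plane_origin(self):
        n = 21
        u, v = np.meshgrid(np.arange(n) - 10, np.arange(n) - 10, indexing="ij")
        grid = (u**2 + v**2 <= 25).astype(float)
        point = slice_center(self._make_slice(grid))
        np.testing.assert_allclose(point, [0.0, 0.0, 0.0], atol=1e-9)

    def test_two_components_selects_nearest_to_reference(self):
        n = 31
        u, v = np.meshgrid(np.arange(n) - 15, np.arange(n) - 15, indexing="ij")
        main = (u + 2) ** 2 + v**2 <= 16
        side = (u - 11) ** 2 + v**2 <= 9
        grid = (main | side).astype(float)
        point = slice_center(self._make_slice(grid), reference=(0.0, 0.0))
        # exhaustive centroid of the main disc only
        iu, iv = np.nonzero(main)
        expected = [(iu - 15.0).mean(), (iv - 15.0).mean(), 0.0]
        np.testing.assert_allclose(point, expected, atol=1e-9)

    def test_empty_slice_signals_gap(self):
        assert slice_center(self._make_slice(np.zeros((11, 11)))) is None


class TestRelaxAndResidual:
    def test_beta_zero_returns_candidates(self):
        c_j = np.array([[2.0, 0, 0], [2.0, 0, 1], [2.0, 0, 2]])
        c_i = np.zeros((3, 3))
        np.testing.assert_allclose(relax_update(c_j, c_i, beta=0.0, sigma=0.0), c_j)

    def test_midpoint_blend(self):
        c_j = np.array([[2.0, 0.0, 0.0]] * 3)
        c_i = np.zeros((3, 3))
        out = relax_update(c_j, c_i, beta=0.5, sigma=0.0)
        np.testing.assert_allclose(out, [[1.0, 0.0, 0.0]] * 3, atol=1e-12)

    def test_high_beta_accepted_for_noisy_masks(self):
        params = CenterlineParams(beta=0.9)
        assert params.beta == 0.9
        with pytest.raises(ValueError):
            CenterlineParams(beta=1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relax_update(np.zeros((3, 3)), np.zeros((4, 3)), beta=0.5)
        with pytest.raises(ValueError):
            residual(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_residual_identical_is_zero(self):
        pts = np.random.default_rng(0).random((5, 3))
        assert residual(pts, pts) == 0.0

    def test_residual_uniform_shift(self):
        pts = np.random.default_rng(1).random((7, 3))
        assert residual(pts, pts + [1.0, 0.0, 0.0]) == pytest.approx(1.0, abs=1e-12)

    def test_residual_hand_computed(self):
        a = np.array([[0.0, 0, 0], [0, 0, 1], [0, 0, 2]])
        b = np.array([[1.0, 0, 0], [0, 2, 1], [0, 0, 2]])
        assert residual(a, b) == pytest.approx(1.0, abs=1e-12)


class TestExtractCenterline:
    def test_straight_tube_terminates_at_first_check(self, straight_tube, straight_result):
        mask, _ = straight_tube
        res = straight_result
        assert res.converged
        assert len(res.residual_history) == 1
        dev = np.hypot(res.final.points[:, 0] - 32.0, res.final.points[:, 1] - 32.0)
        assert dev.max() < 0.5

    def test_bent_tube_converges_close_to_truth(self, bent_tube, bent_result):
        _, truth = bent_tube
        res = bent_result
        assert res.converged
        assert len(res.residual_history) <= 50
        devs = interior_deviations(res.final.points, truth)
        assert np.sqrt((devs**2).mean()) < 1.0

    def test_swelling_benchmark_converges(self, swelling_tube, swelling_result):
        _, truth = swelling_tube
        res = swelling_result
        assert res.converged
        devs = interior_deviations(res.final.points, truth)
        assert np.sqrt((devs**2).mean()) < 1.0

    def test_residuals_non_increasing_after_second_iteration(
        self, bent_result, swelling_result, branch_result, oblique30_result
    ):
        for res in (bent_result, swelling_result, branch_result, oblique30_result):
            rho = res.residual_history
            assert all(rho[i + 1] <= rho[i] + 1e-9 for i in range(1, len(rho) - 1))

    def test_final_points_inside_lumen(
        self, bent_tube, bent_result, branch_tube, branch_result
    ):
        for (mask, _), res in [(bent_tube, bent_result), (branch_tube, branch_result)]:
            idx = np.round(res.final.points).astype(int)
            assert mask.data[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_bifurcation_bulge_removed(self, branch_tube, branch_result, branchless_result):
        _, truth = branch_tube
        res = branch_result
        assert res.converged
        bulges = [interior_deviations(c.points, truth).max() for c in res.history]
        assert max(bulges) > 2.0  # the appendage drags early centerlines sideways
        assert bulges[-1] < 1.0  # the converged centerline tracks the parent
        assert len(res.residual_history) > len(branchless_result.residual_history)

    def test_rotation_equivariance(self, bent_tube, bent_result):
        mask, _ = bent_tube
        rotated = LumenMask(np.rot90(mask.data, k=1, axes=(0, 1)))
        res_rot = extract_centerline(rotated)
        p = bent_result.final.points
        ny = mask.data.shape[1]
        expected = np.column_stack([ny - 1 - p[:, 1], p[:, 0], p[:, 2]])
        disc = np.linalg.norm(res_rot.final.points - expected, axis=1)
        assert disc.max() < 0.5

    def test_non_convergence_warns_not_raises(self, branch_tube):
        mask, _ = branch_tube
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = extract_centerline(mask, CenterlineParams(max_iter=1))
        assert not res.converged
        assert len(res.residual_history) == 1
        assert any("converge" in str(w.message) for w in caught)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_centerline(LumenMask(np.zeros((5, 5, 5), dtype=bool)))
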