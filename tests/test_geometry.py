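"""Plane construction, least-squares fitting, and apex-ray projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vsf import (
    Plane,
    average_plane,
    fit_plane_least_squares,
    fit_plane_tls,
    parallel_plane_at_height,
    perpendicular_height,
    plane_from_three_points,
    point_plane_distance,
    project_point_along_apex_ray,
    project_points_along_apex_rays,
)
from vsf.errors import (
    AmbiguousSideError,
    CollinearPointsError,
    DegenerateConfigurationError,
    DegeneratePointError,
    RayParallelToPlaneError,
)

from conftest import random_rotation


class TestPlaneFromThreePoints:
    def test_z_plane(self):
        pl = plane_from_three_points((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert np.allclose(np.abs(pl.coefficients), [0, 0, 1, 0], atol=1e-15)

    def test_symmetric_diagonal_plane(self):
        pl = plane_from_three_points((1, 0, 0), (0, 1, 0), (0, 0, 1))
        s = np.sign(pl.a)
        assert np.allclose(s * pl.normal, np.ones(3) / np.sqrt(3))
        assert s * pl.d == pytest.approx(-1 / np.sqrt(3))

    def test_points_satisfy_equation(self):
        pts = [(3.0, -2.0, 7.5), (1.1, 4.4, -0.2), (-6.0, 0.5, 2.25)]
        pl = plane_from_three_points(*pts)
        for p in pts:
            assert point_plane_distance(p, pl) < 1e-9
        assert np.linalg.norm(pl.normal) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_raises(self):
        with pytest.raises(CollinearPointsError):
            plane_from_three_points((0, 0, 0), (1, 1, 1), (2, 2, 2))


class TestAveragePlane:
    def test_coplanar_points_recover_plane(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(-5, 5, (8, 2))
        pts = np.column_stack([xy, np.full(8, 3.0)])
        pl = average_plane(pts)
        assert np.allclose(np.abs(pl.coefficients), [0, 0, 1, 3], atol=1e-12)

    def test_symmetric_perturbation_averages_out(self):
        pts = np.array(
            [[1, 1, 1e-3], [-1, 1, -1e-3], [-1, -1, 1e-3], [1, -1, -1e-3]]
        )
        pl = average_plane(pts)
        assert abs(pl.d) < 1e-12
        assert abs(abs(pl.c) - 1) < 1e-5

    def test_matches_bruteforce_triple_enumeration(self):
        """Brute-force oracle: align and average all C(8,3)=56 triple planes."""
        from itertools import combinations

        rng = np.random.default_rng(11)
        pts = rng.uniform(-10, 10, (8, 3))
        apex = np.array([0.0, 0.0, -50.0])

        ref = pts.mean(axis=0) - apex
        coeffs = []
        for i, j, k in combinations(range(8), 3):
            n = np.cross(pts[j] - pts[i], pts[k] - pts[i])
            c = np.concatenate([n, [-n @ pts[i]]]) / np.linalg.norm(n)
            if c[:3] @ ref < 0:
                c = -c
            coeffs.append(c)
        assert len(coeffs) == 56
        mean = np.mean(coeffs, axis=0)
        expected = mean / np.linalg.norm(mean[:3])

        pl = average_plane(pts, apex=apex)
        assert np.allclose(pl.coefficients, expected, atol=1e-12)

    def test_all_collinear_raises(self):
        pts = np.outer(np.arange(5), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateConfigurationError):
            average_plane(pts)


class TestLeastSquaresFit:
    def test_exact_coplanar_zero_residual(self):
        # points on x + 2y - z = 4
        rng = np.random.default_rng(5)
        xy = rng.uniform(-5, 5, (8, 2))
        pts = np.column_stack([xy, xy[:, 0] + 2 * xy[:, 1] - 4])
        pl, diag = fit_plane_least_squares(pts)
        assert diag.sum_sq_perp_dist < 1e-18
        expected = np.array([1, 2, -1]) / np.sqrt(6)
        assert np.allclose(np.abs(pl.normal @ expected), 1.0, atol=1e-9)
        assert diag.n_triples_used == 56

    def test_two_ring_symmetry(self):
        theta = 2 * np.pi * np.arange(4) / 4
        ring = np.column_stack([np.cos(theta) * 5, np.sin(theta) * 5])
        pts = np.vstack(
            [np.column_stack([ring, np.full(4, 1.0)]),
             np.column_stack([ring, np.full(4, -1.0)])]
        )
        pl, diag = fit_plane_least_squares(pts)
        assert abs(abs(pl.c) - 1) < 1e-9
        assert abs(pl.d) < 1e-9
        assert diag.sum_sq_perp_dist == pytest.approx(8.0, rel=1e-9)

    def test_matches_closed_form_tls_on_noisy_ring(self):
        rng = np.random.default_rng(42)
        theta = 2 * np.pi * np.arange(8) / 8
        pts = np.column_stack(
            [45 * np.cos(theta), 45 * np.sin(theta), rng.normal(0, 5, 8)]
        )
        pl, diag = fit_plane_least_squares(pts)
        _, optimum = fit_plane_tls(pts)
        assert diag.sum_sq_perp_dist == pytest.approx(optimum, rel=1e-9)

    def test_collinear_cloud_raises(self):
        pts = np.outer(np.linspace(0, 1, 6), [1.0, -2.0, 0.5])
        with pytest.raises(DegenerateConfigurationError):
            fit_plane_least_squares(pts)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-20, 20, (8, 3)) * [1, 1, 0.1]
        rot = random_rotation(rng)
        shift = rng.uniform(-100, 100, 3)
        moved = pts @ rot.T + shift

        _, diag0 = fit_plane_least_squares(pts)
        _, diag1 = fit_plane_least_squares(moved)
        assert diag1.sum_sq_perp_dist == pytest.approx(
            diag0.sum_sq_perp_dist, rel=1e-9, abs=1e-12
        )


class TestDistancesAndHeights:
    def test_axis_distance(self):
        z0 = Plane(0, 0, 1, 0)
        assert point_plane_distance((0, 0, 5), z0) == pytest.approx(5.0)

    def test_point_on_plane(self):
        pl = plane_from_three_points((1, 2, 3), (4, 5, 9), (-1, 0, 2))
        assert point_plane_distance((1, 2, 3), pl) < 1e-12

    def test_diagonal_closed_form(self):
        pl = Plane.from_normal_offset([1, 1, 1], 0.0)
        assert point_plane_distance((1, 1, 1), pl) == pytest.approx(np.sqrt(3))

    def test_perpendicular_height_is_apex_distance(self):
        pl = Plane(0, 0, 1, -10)
        assert perpendicular_height(pl, (0, 0, 0)) == pytest.approx(10.0)


class TestParallelPlaneAtHeight:
    def test_axis_aligned_translation(self):
        base = Plane(0, 0, 1, -5)
        moved = parallel_plane_at_height(base, (0, 0, 0), 10.0)
        assert moved.signed_distance((0, 0, 10)) == pytest.approx(0.0, abs=1e-12)

    def test_height_equal_is_identity(self):
        base = Plane(0, 0, 1, -5)
        moved = parallel_plane_at_height(base, (0, 0, 0), 5.0)
        assert np.allclose(moved.coefficients, base.coefficients)

    def test_tilted_plane_offset(self):
        base = Plane.from_normal_offset([1, 1, 1], -9.0)
        moved = parallel_plane_at_height(base, (0, 0, 0), 10.0)
        # same side as the base (apex below), at signed offset -10 on the unit normal
        assert moved.d == pytest.approx(-10.0)
        assert point_plane_distance((0, 0, 0), moved) == pytest.approx(10.0)

    def test_apex_on_plane_raises(self):
        with pytest.raises(AmbiguousSideError):
            parallel_plane_at_height(Plane(0, 0, 1, 0), (1, 1, 0), 10.0)

    @settings(max_examples=40, derandomize=True)
    @given(
        h=st.floats(0.01, 500.0),
        d=st.floats(-200.0, 200.0).filter(lambda v: abs(v) > 1e-6),
    )
    def test_distance_contract_property(self, h, d):
        base = Plane(0, 0, 1, d)
        apex = np.zeros(3)
        moved = parallel_plane_at_height(base, apex, h)
        assert point_plane_distance(apex, moved) == pytest.approx(h, rel=1e-12)
        assert np.sign(moved.signed_distance(apex)) == np.sign(d)


class TestApexRayProjection:
    def test_halfway_scaling(self):
        out = project_point_along_apex_ray((2, 2, 2), (0, 0, 0), Plane(0, 0, 1, -1))
        assert np.allclose(out, [1, 1, 1])

    def test_point_on_plane_unchanged(self):
        target = Plane(0, 0, 1, -10)
        out = project_point_along_apex_ray((3, -4, 10), (0, 0, 0), target)
        assert np.allclose(out, [3, -4, 10])

    def test_forward_scaling(self):
        out = project_point_along_apex_ray((3, 0, 6), (0, 0, 0), Plane(0, 0, 1, -10))
        assert np.allclose(out, [5, 0, 10])

    def test_idempotent(self):
        target = Plane.from_normal_offset([1, 2, -1], 7.0)
        apex = np.array([10.0, -3.0, 2.0])
        once = project_point_along_apex_ray((1, 2, 4), apex, target)
        twice = project_point_along_apex_ray(once, apex, target)
        assert np.allclose(once, twice, atol=1e-12)

    def test_apex_point_raises(self):
        with pytest.raises(DegeneratePointError):
            project_point_along_apex_ray((1, 1, 1), (1, 1, 1), Plane(0, 0, 1, -1))

    def test_parallel_ray_raises(self):
        with pytest.raises(RayParallelToPlaneError):
            project_point_along_apex_ray((1, 0, 0), (0, 0, 0), Plane(0, 0, 1, -5))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(-10, 10, (6, 3)) + [0, 0, 30]
        apex = np.zeros(3)
        target = Plane.from_normal_offset([0.1, -0.2, 1.0], -20.0)
        batch = project_points_along_apex_rays(pts, apex, target)
        for p, q in zip(pts, batch):
            assert np.allclose(project_point_along_apex_ray(p, apex, target), q)


def test_zero_residual_recovery_up_to_sign():
    """A fitted plane on exactly coplanar input reproduces the generator plane."""
    rng = np.random.default_rng(17)
    rot = random_rotation(rng)
    xy = rng.uniform(-30, 30, (10, 2))
    pts = np.column_stack([xy, np.zeros(10)]) @ rot.T + [5.0, -2.0, 11.0]
    pl, diag = fit_plane_least_squares(pts)
    true_normal = rot[:, 2]
    assert abs(abs(pl.normal @ true_normal) - 1.0) < 1e-10
    assert diag.sum_sq_perp_dist < 1e-10
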