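"""Plane fitting, robust circle fitting, rotations, angles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acetaver.errors import DegenerateInputError, FitError
from acetaver.geometry import (
    Circle3D,
    Plane,
    RigidTransform,
    angle_between,
    circle_plane_intersection,
    fit_circle3d,
    fit_plane,
    plane_basis,
    rotate,
)


def _circle_points(center, radius, normal, n, rng=None, noise=0.0):
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    e1, e2 = plane_basis(normal)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = (
        np.asarray(center, float)
        + radius * np.cos(t)[:, None] * e1
        + radius * np.sin(t)[:, None] * e2
    )
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


class TestFitPlane:
    def test_exact_horizontal_points(self):
        pts = np.array([[0, 0, 5], [1, 0, 5], [0, 1, 5], [3, -2, 5]], float)
        plane = fit_plane(pts)
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-12
        assert np.max(np.abs(plane.signed_distance(pts))) < 1e-12

    def test_three_exact_points(self):
        pts = np.array([[0, 0, 0], [1, 0, 1], [0, 1, -1]], float)
        plane = fit_plane(pts)
        assert np.max(np.abs(plane.signed_distance(pts))) < 1e-12

    def test_noisy_plane_matches_covariance_eigenvector_oracle(self, rng):
        # independent oracle: smallest eigenvector of the point covariance
        normal_true = np.array([0.2, -0.4, 0.89])
        normal_true /= np.linalg.norm(normal_true)
        e1, e2 = plane_basis(normal_true)
        uv = rng.uniform(-50, 50, (200, 2))
        pts = uv[:, :1] * e1 + uv[:, 1:] * e2 + rng.normal(0, 0.2, (200, 3))
        plane = fit_plane(pts)
        cov = np.cov((pts - pts.mean(axis=0)).T)
        evals, evecs = np.linalg.eigh(cov)
        oracle = evecs[:, 0]
        assert angle_between(plane.normal, oracle) % 180 < 0.5 or \
            angle_between(plane.normal, -oracle) < 0.5

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            fit_plane(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_plane(np.array([[0, 0, 0], [1, 1, 1]], float))


class TestFitCircle3D:
    def test_exact_circle_recovered_to_machine_precision(self):
        pts = _circle_points([0, 0, 0], 25.0, [0, 0, 1], 100)
        c = fit_circle3d(pts)
        assert np.linalg.norm(c.center) < 1e-9
        assert abs(c.radius - 25.0) < 1e-9
        assert abs(abs(c.normal[2]) - 1.0) < 1e-9
        assert c.fit_report.n_outliers_removed == 0

    def test_axial_outliers_flagged_and_fit_unmoved(self, rng):
        pts = _circle_points([0, 0, 0], 25.0, [0, 0, 1], 100, rng, noise=0.05)
        clean = fit_circle3d(pts)
        spoiled = pts.copy()
        idx = rng.choice(100, 10, replace=False)
        spoiled[idx, 2] += 5.0  # displace 10% of points along the normal
        c = fit_circle3d(spoiled)
        assert c.fit_report.n_outliers_removed >= 9
        assert np.linalg.norm(c.center - clean.center) < 0.1
        assert abs(c.radius - clean.radius) < 0.1

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises((DegenerateInputError, FitError)):
            fit_circle3d(pts)

    def test_too_few_points_rejected(self):
        pts = _circle_points([0, 0, 0], 10.0, [0, 0, 1], 5)
        with pytest.raises(DegenerateInputError):
            fit_circle3d(pts)

    def test_rigid_equivariance_exact_points(self, rng):
        """Fitting transformed exact points gives the transformed circle to
        solver precision."""
        pts = _circle_points([3, -2, 7], 18.0, [0.4, 0.2, 0.89], 80)
        base = fit_circle3d(pts)
        for _ in range(5):
            T = RigidTransform.random(rng)
            c = fit_circle3d(T.apply(pts))
            assert np.linalg.norm(c.center - T.apply(base.center)) < 1e-9
            assert abs(c.radius - base.radius) < 1e-9
            moved_normal = T.rotation @ base.normal
            assert min(
                np.linalg.norm(c.normal - moved_normal),
                np.linalg.norm(c.normal + moved_normal),
            ) < 1e-9

    def test_rigid_equivariance_noisy_points(self, rng):
        """With measurement noise the refit agrees to the numeric-Jacobian
        convergence floor (~1e-6 mm), far below any anatomical scale."""
        pts = _circle_points([3, -2, 7], 18.0, [0.4, 0.2, 0.89], 80, rng, noise=0.1)
        base = fit_circle3d(pts)
        for _ in range(5):
            T = RigidTransform.random(rng)
            c = fit_circle3d(T.apply(pts))
            assert np.linalg.norm(c.center - T.apply(base.center)) < 1e-5
            assert abs(c.radius - base.radius) < 1e-5

    def test_geometric_refinement_does_not_worsen_algebraic_start(self, rng):
        from acetaver.geometry import _circle_residuals, _fit_circle_once

        pts = _circle_points([0, 0, 0], 25.0, [0, 0, 1], 60, rng, noise=0.8)
        circle, residuals = _fit_circle_once(pts)
        assert np.all(np.isfinite(residuals))
        # refit starting exactly at the refined solution changes nothing much
        again, res2 = _fit_circle_once(pts)
        assert np.sum(res2**2) <= np.sum(residuals**2) + 1e-12


class TestAngleBetween:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
        ],
    )
    def test_cardinal_cases(self, u, v, expected):
        assert angle_between(u, v) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            angle_between((0, 0, 0), (1, 0, 0))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.floats(0.01, 100),
        st.floats(0.01, 100),
    )
    def test_symmetric_and_scale_invariant(self, u, v, a, b):
        u, v = np.array(u), np.array(v)
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        assert angle_between(u, v) == pytest.approx(angle_between(v, u), abs=1e-9)
        # arccos loses ~sqrt(eps) near parallel vectors; 1e-5 deg is the floor
        assert angle_between(a * u, b * v) == pytest.approx(
            angle_between(u, v), abs=1e-5
        )


class TestRotate:
    def test_right_hand_rule(self):
        out = rotate(np.array([0.0, -1.0, 0.0]), (1, 0, 0), 90.0)
        assert np.allclose(out, [0, 0, -1], atol=1e-12)

    def test_zero_angle_is_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        assert np.allclose(rotate(pts, (0, 0, 1), 0.0), pts)

    def test_inverse_rotation_restores(self, rng):
        pts = rng.normal(size=(20, 3)) * 50
        once = rotate(pts, (0.6, 0.8, 0.0), 37.0, pivot=(5, 5, 5))
        back = rotate(once, (0.6, 0.8, 0.0), -37.0, pivot=(5, 5, 5))
        assert np.max(np.abs(back - pts)) < 1e-12

    def test_zero_axis_rejected(self):
        with pytest.raises(DegenerateInputError):
            rotate(np.array([1.0, 0.0, 0.0]), (0, 0, 0), 10.0)


class TestCirclePlaneIntersection:
    def test_two_crossings_on_tilted_circle(self):
        circle = Circle3D([0, 0, 0], 25.0, [1, 0, 0.2])
        plane = Plane([0, 0, 0], [0, 0, 1])
        pts = circle_plane_intersection(circle, plane)
        assert pts.shape == (2, 3)
        assert np.max(np.abs(pts[:, 2])) < 1e-9
        assert np.allclose(np.linalg.norm(pts, axis=1), 25.0, atol=1e-9)

    def test_plane_missing_circle(self):
        circle = Circle3D([0, 0, 0], 5.0, [1, 0, 0.1])
        plane = Plane([0, 0, 100], [0, 0, 1])
        assert len(circle_plane_intersection(circle, plane)) == 0

    def test_coplanar_rejected(self):
        circle = Circle3D([0, 0, 0], 5.0, [0, 0, 1])
        plane = Plane([0, 0, 0], [0, 0, 1])
        with pytest.raises(DegenerateInputError):
            circle_plane_intersection(circle, plane)
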