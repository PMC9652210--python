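"""Core 3D primitives: plane fitting, robust circle fitting, rotations.

The acetabular rim circle is the load-bearing primitive of the whole
measurement chain, so its fit is done carefully:

1. total-least-squares plane through the points,
2. projection into that plane,
3. algebraic (Kåsa) circle fit as a closed-form initial guess,
4. geometric refinement minimising the sum of squared 3D point-to-circle
   distances (Levenberg–Marquardt style trust region),
5. iterated outlier rejection on the 3D residuals using a scaled-MAD rule
   (default 3.5 scaled MADs, at most 5 rounds), refitting on the inliers.

The MAD rule is robust against the gross, one-sided outliers that
osteophytes and segmentation spill produce on real rims. Angles cross the
API in degrees; radians are internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, FitError

_MAD_SCALE = 1.4826  # consistency factor for Gaussian residuals


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=np.float64))
        n = np.asarray(self.normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise DegenerateInputError("plane normal must be non-zero")
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (points - self.point) @ self.normal

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)


@dataclass(frozen=True)
class FitReport:
    n_points: int
    n_outliers_removed: int
    rms_residual: float  # mm, over inliers
    n_iterations: int = 1


@dataclass(frozen=True)
class Circle3D:
    """Circle in 3D: centre (mm), radius (mm), unit normal of carrying plane."""

    center: np.ndarray
    radius: float
    normal: np.ndarray
    fit_report: FitReport | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=np.float64))
        n = np.asarray(self.normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if norm == 0 or not np.isfinite(norm):
            raise DegenerateInputError("circle normal must be non-zero")
        object.__setattr__(self, "normal", n / norm)
        if not (self.radius > 0):
            raise DegenerateInputError("circle radius must be positive")

    @property
    def plane(self) -> Plane:
        return Plane(self.center, self.normal)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic in-plane orthonormal basis (e1, e2)."""
        return plane_basis(self.normal)

    def points(self, angles_rad: np.ndarray) -> np.ndarray:
        e1, e2 = self.basis()
        a = np.atleast_1d(angles_rad)
        return (
            self.center
            + self.radius * np.cos(a)[:, None] * e1
            + self.radius * np.sin(a)[:, None] * e2
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise DegenerateInputError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise DegenerateInputError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    @staticmethod
    def about_axis(axis, angle_deg: float, pivot) -> "RigidTransform":
        """Right-hand-rule rotation about an axis through ``pivot``."""
        axis = _unit(axis, "rotation axis")
        pivot = np.asarray(pivot, dtype=np.float64)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        return RigidTransform(R, pivot - R @ pivot)

    @staticmethod
    def random(rng: np.random.Generator, max_translation: float = 100.0) -> "RigidTransform":
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, 3)
        return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# small vector helpers


def _unit(v, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=np.float64).reshape(3)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise DegenerateInputError(f"{what} must be non-zero and finite")
    return v / n


def plane_basis(normal) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane orthogonal to ``normal``."""
    n = _unit(normal, "plane normal")
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(n, helper))
    e2 = np.cross(n, e1)
    return e1, e2


def angle_between(u, v) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = _unit(u)
    v = _unit(v)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def rotate(subject, axis, angle_deg: float, pivot=(0.0, 0.0, 0.0)):
    """Rotate a mesh, landmark set, point array or vector about a pivoted axis.

    Right-hand rule about ``axis`` (which must be non-zero; it is normalised
    here). Returns the same type as the input.
    """
    from .mesh_io import LandmarkSet, TriangleMesh  # local import, avoids cycle

    T = RigidTransform.about_axis(axis, angle_deg, pivot)
    if isinstance(subject, TriangleMesh):
        return subject.transformed(T.apply(subject.vertices))
    if isinstance(subject, LandmarkSet):
        return subject.transformed(lambda p: T.apply(p).reshape(3))
    arr = np.asarray(subject, dtype=np.float64)
    out = T.apply(arr)
    return out.reshape(arr.shape)


def circle_plane_intersection(circle: Circle3D, plane: Plane) -> np.ndarray:
    """The (up to two) points where a 3D circle crosses a plane.

    Returns a (k, 3) array with k in {0, 1, 2}. Raises if the circle lies
    in the plane (infinitely many intersections).
    """
    e1, e2 = circle.basis()
    d0 = float(plane.signed_distance(circle.center)[0])
    A = float(e1 @ plane.normal)
    B = float(e2 @ plane.normal)
    M = float(np.hypot(A, B))
    if M < 1e-12:
        if abs(d0) < 1e-9:
            raise DegenerateInputError("circle lies in the plane")
        return np.empty((0, 3))
    c = -d0 / (circle.radius * M)
    if abs(c) > 1.0:
        return np.empty((0, 3))
    phi0 = np.arctan2(B, A)
    dt = np.arccos(np.clip(c, -1.0, 1.0))
    ts = np.unique([phi0 + dt, phi0 - dt])
    return circle.points(np.asarray(ts))


# ---------------------------------------------------------------------------
# fitting


def fit_plane(points) -> Plane:
    """Total-least-squares plane (minimum sum of squared orthogonal distances).

    The returned plane passes through the centroid; the normal is the
    singular vector of the centred coordinates with the smallest singular
    value. Its sign is unconstrained — anatomical callers orient it.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise DegenerateInputError("plane fit needs at least 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear (or coincident) points: the two smallest singular values vanish
    scale = max(s[0], 1.0)
    if s[1] <= 1e-12 * scale:
        raise DegenerateInputError("points are collinear; plane is undefined")
    return Plane(centroid, vt[2])


def _kasa_circle_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) circle fit in the plane: closed-form least squares."""
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]
    r2 = sol[2] + center @ center
    if not (r2 > 0) or not np.isfinite(r2):
        raise FitError("algebraic circle fit degenerate")
    return center, float(np.sqrt(r2))


def _circle_residuals(params: np.ndarray, pts: np.ndarray, frame) -> np.ndarray:
    """3D point-to-circle distances.

    params = (cx, cy, cz, p, q, r); the circle normal is the unit vector
    along n0 + p·t1 + q·t2 with (n0, t1, t2) the fixed orthonormal frame of
    the initial plane fit — a gauge-fixed parameterization that stays well
    conditioned around the optimum (no spherical-coordinate pole).
    """
    n0, t1, t2 = frame
    c = params[:3]
    r = params[5]
    n = n0 + params[3] * t1 + params[4] * t2
    n = n / np.linalg.norm(n)
    w = pts - c
    h = w @ n
    rho = np.linalg.norm(w - np.outer(h, n), axis=1)
    return np.sqrt(h**2 + (rho - r) ** 2)


def _fit_circle_once(pts: np.ndarray) -> tuple[Circle3D, np.ndarray]:
    """Plane + Kåsa + geometric refinement on a fixed point set."""
    plane = fit_plane(pts)
    e1, e2 = plane_basis(plane.normal)
    rel = pts - plane.point
    xy = np.column_stack([rel @ e1, rel @ e2])
    c2d, r0 = _kasa_circle_2d(xy)
    center0 = plane.point + c2d[0] * e1 + c2d[1] * e2
    frame = (plane.normal, e1, e2)
    x0 = np.array([*center0, 0.0, 0.0, r0])
    init_cost = float(np.sum(_circle_residuals(x0, pts, frame) ** 2))
    sol = least_squares(
        _circle_residuals, x0, args=(pts, frame), method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    # trust-region refinement can only improve on the algebraic start, but be
    # explicit: fall back to the initialization if the solver misbehaves
    x = sol.x if float(np.sum(sol.fun**2)) <= init_cost else x0
    residuals = _circle_residuals(x, pts, frame)
    n = frame[0] + x[3] * frame[1] + x[4] * frame[2]
    n = n / np.linalg.norm(n)
    if not (x[5] > 0):
        raise FitError("refined circle radius is non-positive")
    circle = Circle3D(x[:3], float(x[5]), n)
    return circle, residuals


def fit_circle3d(
    points,
    outlier_threshold_mads: float = 3.5,
    max_iterations: int = 5,
) -> Circle3D:
    """Robust 3D circle fit with iterated MAD outlier rejection.

    Points further than ``outlier_threshold_mads`` scaled MADs from the
    current circle are dropped and the circle is refit on the inliers,
    repeating until the inlier set is stable or ``max_iterations`` rounds.
    The returned :class:`Circle3D` carries a :class:`FitReport`.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.shape[0] < 6:
        raise DegenerateInputError("circle fit needs at least 6 points")
    if outlier_threshold_mads <= 0:
        raise DegenerateInputError("outlier threshold must be positive")

    mask = np.ones(len(pts), dtype=bool)
    circle, residuals = _fit_circle_once(pts)
    iterations = 1
    for _ in range(max_iterations):
        mad = np.median(np.abs(residuals - np.median(residuals)))
        scale = _MAD_SCALE * mad
        if scale <= 1e-12:  # essentially exact fit: nothing to reject
            break
        keep_local = residuals <= outlier_threshold_mads * scale
        if keep_local.all():
            break
        new_mask = mask.copy()
        new_mask[np.flatnonzero(mask)[~keep_local]] = False
        if new_mask.sum() < 6:
            raise FitError("outlier rejection removed too many points")
        if new_mask.sum() < 0.3 * len(pts):
            # refusing to reject a majority: residual structure this broad is
            # not outlier contamination, and cascading would collapse the fit
            break
        mask = new_mask
        circle, residuals = _fit_circle_once(pts[mask])
        iterations += 1

    n_out = int(len(pts) - mask.sum())
    report = FitReport(
        n_points=len(pts),
        n_outliers_removed=n_out,
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
        n_iterations=iterations,
    )
    return Circle3D(circle.center, circle.radius, circle.normal, report)
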