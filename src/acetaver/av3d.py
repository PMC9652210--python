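"""The 3D anteversion (AV) measurement.

The acetabular opening is summarised by the plane of the circle fitted to
the acetabular rim, oriented outward (away from the cup interior). The
anatomical reference is the anterior pelvic plane (APP) through ASISL,
ASISR and PT, oriented anteriorly. With α the angle between the two
oriented normals, the anteversion angle is

    AV = 90° − α.

AV is positive for anteverted cups (outward normal tipped anteriorly) and
negative for retroverted ones; the sign falls out of α crossing 90°.
Because both planes are intrinsic to the anatomy, AV is invariant under
rigid motion of the pelvis — the property that makes this the
pose-independent alternative to axial-slice measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .geometry import Circle3D, Plane, angle_between, fit_circle3d, fit_plane
from .mesh_io import LandmarkSet, TriangleMesh
from .rim import RimSelection, detect_rim


@dataclass(frozen=True)
class AVResult:
    """An anteversion measurement with its intermediate constructions."""

    angle_deg: float
    method: str  # "av3d" | "av2d_stem" | "av2d_tallroth"
    side: str  # "left" | "right"
    alpha_deg: float | None = None
    acetabular_plane: Plane | None = None
    reference_plane: Plane | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.angle_deg):
            raise ValidationError("AV angle is not finite")
        if self.method == "av3d":
            assert self.alpha_deg is not None
            if abs(self.angle_deg - (90.0 - self.alpha_deg)) > 1e-9:
                raise ValidationError("AV = 90 − α identity violated")


def anterior_pelvic_plane(landmarks: LandmarkSet, mesh: TriangleMesh | None = None) -> Plane:
    """Plane through ASISL, ASISR and PT, normal oriented anteriorly.

    In the supine LPS frame anterior is −Y, so the normal is flipped to have
    a negative Y component. For meshes in an arbitrary pose, pass the mesh:
    the pelvis lies posterior to its APP, so the normal is oriented away
    from the side of the plane holding the bulk of the mesh vertices.
    """
    asisl, asisr, pt = landmarks.require("ASISL", "ASISR", "PT")
    if np.allclose(asisl, asisr):
        raise DegenerateInputError("ASISL and ASISR coincide")
    plane = fit_plane(np.array([asisl, asisr, pt]))  # exact through 3 points
    normal = plane.normal
    if mesh is not None:
        side = np.sign(np.median(plane.signed_distance(mesh.vertices)))
        if side > 0:
            normal = -normal
        elif side == 0:
            raise DegenerateInputError("mesh centroid lies on the APP; cannot orient")
    elif normal[1] > 0:
        normal = -normal
    elif normal[1] == 0:
        raise DegenerateInputError(
            "APP normal has no anterior component; supply the mesh to orient it"
        )
    return Plane(plane.point, normal)


def acetabular_plane(rim_circle: Circle3D, cup_interior_point) -> Plane:
    """Plane of the rim circle, normal oriented outward (away from the cup)."""
    interior = np.asarray(cup_interior_point, dtype=np.float64).reshape(3)
    d = float(rim_circle.plane.signed_distance(interior)[0])
    if abs(d) < 1e-9:
        raise DegenerateInputError("cup interior point lies on the rim plane")
    normal = rim_circle.normal if d < 0 else -rim_circle.normal
    return Plane(rim_circle.center, normal)


def av_from_planes(acetabular: Plane, app: Plane) -> tuple[float, float]:
    """(AV, α) in degrees from the oriented acetabular and APP normals."""
    alpha = angle_between(acetabular.normal, app.normal)
    return 90.0 - alpha, alpha


def default_cup_interior_point(mesh: TriangleMesh, rim_circle: Circle3D) -> np.ndarray:
    """Centroid of mesh vertices within ~one rim radius of the rim centre.

    For a concave cup the ball around the rim centre is dominated by cup
    surface, so the centroid falls on the concave (interior) side.
    """
    d = np.linalg.norm(mesh.vertices - rim_circle.center, axis=1)
    near = mesh.vertices[d < 1.05 * rim_circle.radius]
    if len(near) == 0:
        raise DegenerateInputError("no mesh vertices near the rim centre")
    return near.mean(axis=0)


def compute_av3d(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    rim: RimSelection | None = None,
    side: str = "left",
    percentile: float | None = None,
    outlier_threshold_mads: float = 3.5,
) -> AVResult:
    """Full 3D AV pipeline: rim → circle → acetabular plane → AV = 90° − α.

    Without a ``rim`` the acetabular ridge is detected automatically from
    surface curvature, seeded by the femoral head centre of the requested
    side when present (FHC_L / FHC_R).
    """
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    if rim is None:
        seed_name = "FHC_L" if side == "left" else "FHC_R"
        seed = landmarks.get(seed_name)
        rim = detect_rim(mesh, seed=seed, percentile=percentile)
    circle = fit_circle3d(
        mesh.vertices[rim.indices], outlier_threshold_mads=outlier_threshold_mads
    )
    interior = default_cup_interior_point(mesh, circle)
    acetab = acetabular_plane(circle, interior)
    app = anterior_pelvic_plane(landmarks, mesh=mesh)
    av, alpha = av_from_planes(acetab, app)
    return AVResult(
        angle_deg=av,
        method="av3d",
        side=side,
        alpha_deg=alpha,
        acetabular_plane=acetab,
        reference_plane=app,
        provenance={
            "rim_source": rim.source,
            "rim_n_vertices": rim.n_vertices,
            "fit_report": circle.fit_report,
            "rim_circle": circle,
        },
    )
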