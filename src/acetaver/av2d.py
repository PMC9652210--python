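"""The 2D axial-slice comparator (Stem method; Tallroth variant).

This emulates the conventional measurement a radiologist performs on a
single axial CT image, realised here on a mesh cross-section:

* slice level — the axial plane closest to both femoral head centres
  (their mean Z);
* acetabular line — through the anterior and posterior margins of the
  bony acetabulum in that slice;
* reference line — through the two posterior pelvic margins (sciatic
  notch pair SN_L/SN_R, or the ischial tuberosities IT_L/IT_R); the
  Tallroth variant instead uses the line joining the femoral head
  centres;
* AV²ᴰ — the signed angle between the acetabular line and the
  perpendicular of the reference line, positive when the acetabular line
  tips medially (anteversion), negative for retroversion.

Unlike the 3D measurement, everything here depends on where the axial
plane cuts the pelvis — which is exactly the pose dependence the tilt
simulation in :mod:`acetaver.pose` quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateInputError,
    EmptySliceError,
    ExtractionError,
    ValidationError,
)
from .av3d import AVResult, compute_av3d
from .geometry import Circle3D, Plane, circle_plane_intersection
from .mesh_io import LandmarkSet, TriangleMesh
from .rim import RimSelection

#: Default capture radius (mm) when snapping seeds to slice contours.
DEFAULT_CAPTURE_RADIUS_MM = 10.0


@dataclass(frozen=True)
class AxialSlice:
    """Planar contours of a mesh cut by the plane z = z_level (scanner frame)."""

    z_level: float
    contours: tuple  # tuple of (k, 2) float arrays in the X–Y plane
    source: str = ""

    def all_points(self) -> np.ndarray:
        return np.concatenate(self.contours, axis=0)


def select_slice_level(landmarks: LandmarkSet) -> float:
    """Mean Z of the two femoral head centres: the paper-standard cut level."""
    fhc_l, fhc_r = landmarks.require("FHC_L", "FHC_R")
    return float((fhc_l[2] + fhc_r[2]) / 2.0)


def axial_slice(mesh: TriangleMesh, z_level: float) -> AxialSlice:
    """Intersect the mesh with the plane z = z_level; chain into contours."""
    section = mesh.to_trimesh().section(
        plane_origin=[0.0, 0.0, float(z_level)], plane_normal=[0.0, 0.0, 1.0]
    )
    if section is None or len(section.entities) == 0:
        raise EmptySliceError(f"slice plane z={z_level} does not intersect the mesh")
    contours = tuple(
        np.asarray(poly, dtype=np.float64)[:, :2] for poly in section.discrete
    )
    return AxialSlice(z_level=float(z_level), contours=contours)


def _nearest_on_segments(point2d: np.ndarray, contour: np.ndarray):
    """Closest point on a polyline (projected onto its segments)."""
    a = contour[:-1]
    b = contour[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", point2d - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - point2d, axis=1)
    k = int(np.argmin(d))
    return proj[k], float(d[k])


def extract_slice_landmarks(
    slc: AxialSlice,
    seeds,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS_MM,
) -> dict[str, np.ndarray]:
    """Snap projected 3D seed points to the nearest slice-contour point.

    ``seeds`` maps names to 3D (or 2D) points; 3D seeds are projected into
    the slice plane by dropping Z. A seed farther than ``capture_radius``
    (mm) from every contour raises :class:`ExtractionError` — the structure
    is not visible in this cut.
    """
    out: dict[str, np.ndarray] = {}
    for name, p in seeds.items():
        p2 = np.asarray(p, dtype=np.float64).reshape(-1)[:2]
        best, best_d = None, np.inf
        for contour in slc.contours:
            if len(contour) < 2:
                continue
            q, d = _nearest_on_segments(p2, contour)
            if d < best_d:
                best, best_d = q, d
        if best is None or best_d > capture_radius:
            raise ExtractionError(
                f"seed {name!r} is {best_d:.1f} mm from the nearest contour "
                f"(capture radius {capture_radius} mm)"
            )
        out[name] = best
    return out


def _signed_av2d(ar_ant, ar_post, ref_a, ref_b, side: str) -> float:
    ar_ant = np.asarray(ar_ant, dtype=np.float64).reshape(-1)[:2]
    ar_post = np.asarray(ar_post, dtype=np.float64).reshape(-1)[:2]
    ref_a = np.asarray(ref_a, dtype=np.float64).reshape(-1)[:2]
    ref_b = np.asarray(ref_b, dtype=np.float64).reshape(-1)[:2]
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    a = ar_ant - ar_post
    r = ref_b - ref_a
    if np.linalg.norm(a) < 1e-12:
        raise DegenerateInputError("acetabular margin points coincide")
    if np.linalg.norm(r) < 1e-12:
        raise DegenerateInputError("reference line points coincide")
    r = r / np.linalg.norm(r)
    # perpendicular of the reference line, oriented anteriorly (−Y in LPS)
    perp = np.array([-r[1], r[0]])
    if abs(perp[1]) < 1e-12:
        raise DegenerateInputError(
            "reference line runs anterior–posterior; its perpendicular has no"
            " anterior direction"
        )
    if perp[1] > 0:
        perp = -perp
    medial = np.array([-1.0, 0.0]) if side == "left" else np.array([1.0, 0.0])
    m = medial - (medial @ perp) * perp
    norm_m = np.linalg.norm(m)
    if norm_m < 1e-12:
        raise DegenerateInputError("medial direction is parallel to the reference"
                                   " perpendicular")
    m = m / norm_m
    return float(np.degrees(np.arctan2(a @ m, a @ perp)))


def measure_av2d_stem(ar_ant, ar_post, ref_a, ref_b, side: str = "left") -> float:
    """Stem-style AV²ᴰ: acetabular line vs perpendicular of the posterior
    pelvic margin line (sciatic notch or transischial), signed degrees.

    Positive values are anteversion (acetabular line tipped medially from
    the reference perpendicular), negative values retroversion.
    """
    return _signed_av2d(ar_ant, ar_post, ref_a, ref_b, side)


def measure_av2d_tallroth(ar_ant, ar_post, fhc_l, fhc_r, side: str = "left") -> float:
    """Tallroth-style AV²ᴰ: reference line through the femoral head centres."""
    return _signed_av2d(ar_ant, ar_post, fhc_l, fhc_r, side)


def _rim_seeds_from_circle(circle: Circle3D, z_level: float) -> dict[str, np.ndarray]:
    """Anterior/posterior acetabular margins: rim circle ∩ slice plane."""
    plane = Plane(np.array([0.0, 0.0, z_level]), np.array([0.0, 0.0, 1.0]))
    pts = circle_plane_intersection(circle, plane)
    if len(pts) < 2:
        raise ExtractionError("rim circle does not cross the slice plane twice")
    order = np.argsort(pts[:, 1])  # anterior = smaller Y in LPS
    return {"AR_ANT": pts[order[0]], "AR_POST": pts[order[1]]}


def compute_av2d(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    variant: str = "stem",
    side: str = "left",
    rim: RimSelection | None = None,
    rim_circle: Circle3D | None = None,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS_MM,
    z_level: float | None = None,
) -> AVResult:
    """Full 2D pipeline on a mesh: slice, read off the landmarks, measure.

    The acetabular margin seeds come from AR_ANT/AR_POST landmarks when
    present, otherwise from the intersection of the (fitted or supplied)
    rim circle with the slice plane; all surface seeds are snapped to the
    slice contours, mirroring how the margins are read off an axial image.
    """
    if variant not in ("stem", "tallroth"):
        raise ValidationError(f"unknown 2D variant {variant!r}")
    z = select_slice_level(landmarks) if z_level is None else float(z_level)
    slc = axial_slice(mesh, z)

    if "AR_ANT" in landmarks and "AR_POST" in landmarks:
        ar_seeds = {"AR_ANT": landmarks["AR_ANT"], "AR_POST": landmarks["AR_POST"]}
    else:
        if rim_circle is None:
            res3d = compute_av3d(mesh, landmarks, rim=rim, side=side)
            rim_circle = res3d.provenance["rim_circle"]
        ar_seeds = _rim_seeds_from_circle(rim_circle, z)
    snapped = extract_slice_landmarks(slc, ar_seeds, capture_radius=capture_radius)
    ar_ant, ar_post = snapped["AR_ANT"], snapped["AR_POST"]

    if variant == "tallroth":
        fhc_l, fhc_r = landmarks.require("FHC_L", "FHC_R")
        angle = measure_av2d_tallroth(ar_ant, ar_post, fhc_l[:2], fhc_r[:2], side=side)
        ref_names = ("FHC_L", "FHC_R")
    else:
        if "SN_L" in landmarks and "SN_R" in landmarks:
            ref_names = ("SN_L", "SN_R")
        elif "IT_L" in landmarks and "IT_R" in landmarks:
            ref_names = ("IT_L", "IT_R")
        else:
            raise ValidationError(
                "Stem reference needs SN_L/SN_R or IT_L/IT_R landmarks"
            )
        refs = extract_slice_landmarks(
            slc,
            {n: landmarks[n] for n in ref_names},
            capture_radius=capture_radius,
        )
        angle = measure_av2d_stem(
            ar_ant, ar_post, refs[ref_names[1]], refs[ref_names[0]], side=side
        )
    return AVResult(
        angle_deg=angle,
        method=f"av2d_{variant}",
        side=side,
        provenance={
            "z_level": z,
            "reference": ref_names,
            "ar_ant": ar_ant,
            "ar_post": ar_post,
        },
    )
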