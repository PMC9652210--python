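"""Pelvis pose relative to the scanner, and the virtual tilt experiment.

Two angles summarise how the pelvis lies on the CT table:

* λ (lambda) — anterior–posterior pelvic tilt: the signed angle, in the
  sagittal (Y–Z) plane, between the anterior direction (−Y) and the
  projection of the anterior-pelvic-plane normal.
* ρ (rho) — lateral pelvic tilt: the signed angle, in the coronal (X–Z)
  plane, between the inter-ASIS vector (ASISR→ASISL) and the transverse
  table axis +X; positive when the left ASIS sits cranial to the right.

Sign conventions are operational, fixed by construction rotations: λ of a
neutral pelvis rotated by θ about +X equals θ (so positive λ is anterior
tilt of the superior pelvis in LPS), and ρ of a neutral pelvis rotated by
θ about −Y equals θ.

``tilt_sweep`` is the virtual repositioning experiment: the pelvis (mesh
and landmarks together) is rigidly rotated in steps about the midpoint of
the femoral head centres, the axial slice is re-taken at the scanner
z-level of the rotated head centres, the 2D landmarks are re-read from
the new slice, and both AV measurements are recomputed. The 3D angle is
invariant; the 2D angle drifts with tilt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .av2d import compute_av2d, select_slice_level
from .av3d import compute_av3d
from .errors import AcetaverError, DegenerateInputError, DegeneratePoseError
from .geometry import Plane, rotate
from .mesh_io import LPS, LandmarkSet, ScannerFrame, TriangleMesh
from .rim import RimSelection, detect_rim


@dataclass(frozen=True)
class PoseAngles:
    """Pelvis pose: AP tilt λ and lateral tilt ρ, signed degrees."""

    lambda_deg: float
    rho_deg: float


@dataclass(frozen=True)
class TiltSweepRow:
    applied_tilt_deg: float
    axis: str  # "AP" | "lateral"
    av2d_deg: float  # NaN when flagged
    av3d_deg: float
    lambda_deg: float
    rho_deg: float
    ok: bool = True
    message: str = ""


def compute_lambda(app: Plane, frame: ScannerFrame = LPS) -> float:
    """AP pelvic tilt λ from the oriented (anterior) APP normal, degrees."""
    n = frame.coords(app.normal)
    if math.hypot(n[1], n[2]) < 1e-9:
        raise DegeneratePoseError(
            "APP normal is parallel to the transverse axis; lambda undefined"
        )
    return float(np.degrees(np.arctan2(-n[2], -n[1])))


def compute_rho(landmarks: LandmarkSet, frame: ScannerFrame = LPS) -> float:
    """Lateral pelvic tilt ρ from the inter-ASIS vector, degrees."""
    asisl, asisr = landmarks.require("ASISL", "ASISR")
    v = np.asarray(asisl) - np.asarray(asisr)
    if np.linalg.norm(v) < 1e-9:
        raise DegenerateInputError("ASISL and ASISR coincide")
    c = frame.coords(v)
    if math.hypot(c[0], c[2]) < 1e-9:
        raise DegeneratePoseError(
            "inter-ASIS vector is parallel to the sagittal axis; rho undefined"
        )
    return float(np.degrees(np.arctan2(c[2], c[0])))


#: Rotation axes realising the two tilt types (right-hand rule), chosen so
#: that the applied angle equals the resulting pose angle (λ or ρ).
_SWEEP_AXES = {"AP": np.array([1.0, 0.0, 0.0]), "lateral": np.array([0.0, -1.0, 0.0])}


def tilt_sweep(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    axis: str = "AP",
    range_deg: tuple[float, float] = (-10.0, 10.0),
    step_deg: float = 1.0,
    side: str = "left",
    variant: str = "stem",
    rim: RimSelection | None = None,
    percentile: float | None = None,
    capture_radius: float = 15.0,
    frame: ScannerFrame = LPS,
) -> list[TiltSweepRow]:
    """Virtually repositioned measurements over a range of pelvic tilts.

    The rim is delineated once on the input mesh (vertex indices are
    pose-invariant) and carried through every pose, as a fixed manual rim
    would be. Within each pose the 2D acetabular margins are re-derived
    from the fitted rim circle's crossing of the new slice plane and
    snapped to the slice contours — re-reading the tilted scan rather than
    rotating old 2D points, which would wrongly make AV²ᴰ pose-invariant.
    Slice or extraction failures at extreme tilt flag the row instead of
    aborting the sweep.
    """
    if axis not in _SWEEP_AXES:
        raise DegenerateInputError(f"unknown sweep axis {axis!r}; use AP or lateral")
    lo, hi = float(range_deg[0]), float(range_deg[1])
    if hi < lo or step_deg <= 0:
        raise DegenerateInputError("invalid sweep range or step")
    n_steps = int(round((hi - lo) / step_deg))
    angles = lo + step_deg * np.arange(n_steps + 1) if hi > lo else np.array([lo])

    if rim is None:
        seed_name = "FHC_L" if side == "left" else "FHC_R"
        rim = detect_rim(mesh, seed=landmarks.get(seed_name), percentile=percentile)
    fhc_l, fhc_r = landmarks.require("FHC_L", "FHC_R")
    pivot = (np.asarray(fhc_l) + np.asarray(fhc_r)) / 2.0
    rot_axis = _SWEEP_AXES[axis]

    rows: list[TiltSweepRow] = []
    for theta in angles:
        m = rotate(mesh, rot_axis, float(theta), pivot)
        lm = rotate(landmarks, rot_axis, float(theta), pivot)
        # 2D margin seeds are re-derived per pose; drop the neutral ones
        lm_2d = LandmarkSet({k: v for k, v in lm.items() if k not in ("AR_ANT", "AR_POST")})
        res3d = compute_av3d(m, lm, rim=rim, side=side)
        lam = compute_lambda(res3d.reference_plane, frame)
        rho = compute_rho(lm, frame)
        try:
            res2d = compute_av2d(
                m,
                lm_2d,
                variant=variant,
                side=side,
                rim_circle=res3d.provenance["rim_circle"],
                capture_radius=capture_radius,
                z_level=select_slice_level(lm),
            )
            rows.append(
                TiltSweepRow(float(theta), axis, res2d.angle_deg, res3d.angle_deg, lam, rho)
            )
        except AcetaverError as exc:
            rows.append(
                TiltSweepRow(
                    float(theta), axis, float("nan"), res3d.angle_deg, lam, rho,
                    ok=False, message=str(exc),
                )
            )
    return rows


def sweep_to_dataframe(rows: list[TiltSweepRow]):
    """Tilt-sweep rows as a pandas DataFrame (one row per step)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "applied_tilt_deg": [r.applied_tilt_deg for r in rows],
            "axis": [r.axis for r in rows],
            "av2d_deg": [r.av2d_deg for r in rows],
            "av3d_deg": [r.av3d_deg for r in rows],
            "lambda_deg": [r.lambda_deg for r in rows],
            "rho_deg": [r.rho_deg for r in rows],
            "ok": [r.ok for r in rows],
        }
    )
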