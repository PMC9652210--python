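"""Parametric hemipelvis phantom with exact ground truth, and a cohort
simulator.

The phantom is deliberately non-anatomical: a rounded slab ("body") with a
spherical-cap cup sunk into one face, so that every quantity the
measurement chain estimates — the rim circle, the anterior pelvic plane,
the anteversion angle, the slice crossing points — has a closed form.
Correctness of the chain, not realism, is the point.

Geometry. The anterior pelvic plane of the phantom is exactly Y = 0 in
the LPS frame (ASISL/ASISR/PT are placed in it), so its anterior normal
is (0, −1, 0). The cup's outward axis is

    n = (s·cos A·cos i,  −sin A,  −cos A·sin i)

with A the true anteversion, i the true inclination and s = ±1 the side
sign (left +1). Since n·(0,−1,0) = sin A, the angle α between the
acetabular and anterior normals is 90° − A for *any* inclination, so
AV = 90° − α recovers A identically — the ground truth is exact by
construction, not by numerical accident.

The rim is the sharp crest where the cap meets the flat face: a circle of
the requested radius, centred on the cup centre, normal n. A fillet
parameter rounds the slab's other edges so their curvature stays well
below the crest's, which is what gives curvature-based rim detection a
realistic difficulty knob (and, with vertex noise, a realistic failure
mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .av3d import acetabular_plane, av_from_planes
from .errors import ValidationError
from .geometry import Circle3D, Plane, circle_plane_intersection
from .mesh_io import LandmarkSet, TriangleMesh


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic hemipelvis.

    Defaults put the phantom at the cohort-mean anatomy reported for
    healthy adult acetabula: anteversion 16.1°, inclination 45°, rim
    radius 25 mm.
    """

    true_av_deg: float = 16.1
    true_inclination_deg: float = 45.0
    rim_radius_mm: float = 25.0
    cup_depth_fraction: float = 1.0  # 1.0 = full hemisphere
    body_extent_mm: float = 65.0  # slab radius around the cup
    body_depth_mm: float = 45.0
    fillet_radius_mm: float = 4.0
    asis_half_spacing_mm: float = 120.0
    pt_drop_mm: float = 90.0  # PT sits this far caudal of the ASIS line
    cup_lateral_mm: float = 80.0
    cup_posterior_mm: float = 15.0
    cup_caudal_mm: float = 65.0
    vertex_noise_sd_mm: float = 0.0
    n_theta: int = 192  # angular mesh resolution
    side: str = "left"
    rng_seed: int = 0

    def __post_init__(self):
        if not (self.rim_radius_mm > 0):
            raise ValidationError("rim radius must be positive")
        if not (-40.0 < self.true_av_deg < 50.0):
            raise ValidationError("true AV must lie in (−40°, 50°)")
        if self.vertex_noise_sd_mm < 0:
            raise ValidationError("vertex noise SD must be non-negative")
        if not (0.1 <= self.cup_depth_fraction <= 1.0):
            raise ValidationError("cup depth fraction must lie in [0.1, 1]")
        if self.rim_radius_mm + 2 * self.fillet_radius_mm >= self.body_extent_mm:
            raise ValidationError("cup larger than the body extent")
        if self.body_depth_mm <= self.cup_depth_fraction * self.rim_radius_mm + 2:
            raise ValidationError("body too shallow for the cup")
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")
        if self.n_theta < 24:
            raise ValidationError("n_theta too small for a usable mesh")


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form ground truth for one phantom."""

    rim_circle: Circle3D
    app: Plane
    true_av_deg: float
    cup_interior_point: np.ndarray
    spec: PhantomSpec = field(compare=False, default=None)

    def recomputed_av(self) -> float:
        """AV reassembled from the truth planes; equals true_av_deg."""
        acetab = acetabular_plane(self.rim_circle, self.cup_interior_point)
        av, _ = av_from_planes(acetab, self.app)
        return av

    def slice_crossings(self, z_level: float) -> np.ndarray:
        """Analytic rim-circle crossings of the axial plane z = z_level."""
        plane = Plane(np.array([0.0, 0.0, float(z_level)]), np.array([0.0, 0.0, 1.0]))
        return circle_plane_intersection(self.rim_circle, plane)


def _cup_axis(spec: PhantomSpec) -> np.ndarray:
    s = 1.0 if spec.side == "left" else -1.0
    A = np.deg2rad(spec.true_av_deg)
    i = np.deg2rad(spec.true_inclination_deg)
    return np.array([s * np.cos(A) * np.cos(i), -np.sin(A), -np.cos(A) * np.sin(i)])


def _lathe_profile(spec: PhantomSpec) -> list[tuple[float, float]]:
    """(r, w) polyline of the solid's boundary, apex → crest → rim of slab →
    wall → bottom centre, in the cup frame (w along the outward cup axis)."""
    R = spec.rim_radius_mm
    d = spec.cup_depth_fraction * R  # cap depth
    Rs = (R * R + d * d) / (2 * d)  # cap sphere radius
    cw = Rs - d  # cap sphere centre on the axis
    R_out = spec.body_extent_mm
    D = spec.body_depth_mm
    f = spec.fillet_radius_mm

    prof: list[tuple[float, float]] = [(0.0, -d)]  # apex of the cup
    psi_max = np.arccos(np.clip(cw / Rs, -1.0, 1.0))
    n_bowl = max(12, int(round(spec.n_theta / 8)))
    for psi in np.linspace(0, psi_max, n_bowl + 1)[1:]:
        prof.append((Rs * np.sin(psi), cw - Rs * np.cos(psi)))  # ends at crest (R, 0)
    n_plate = max(4, int(round((R_out - f - R) / (2 * np.pi * R_out / spec.n_theta))))
    for r in np.linspace(R, R_out - f, n_plate + 1)[1:]:
        prof.append((r, 0.0))
    n_fillet = 6
    for t in np.linspace(0, np.pi / 2, n_fillet + 1)[1:]:
        prof.append((R_out - f + f * np.sin(t), -f + f * np.cos(t)))
    n_wall = max(4, int(round((D - 2 * f) / (2 * np.pi * R_out / spec.n_theta))))
    for w in np.linspace(-f, -(D - f), n_wall + 1)[1:]:
        prof.append((R_out, w))
    for t in np.linspace(np.pi / 2, 0, n_fillet + 1)[1:]:
        prof.append((R_out - f + f * np.sin(t), -(D - f) - f * np.cos(t)))
    n_bot = max(4, int(round((R_out - f) / (2 * np.pi * R_out / spec.n_theta))))
    for r in np.linspace(R_out - f, 0.0, n_bot + 1)[1:-1]:
        prof.append((r, -D))
    prof.append((0.0, -D))  # bottom centre
    return prof


def _revolve(profile, n_theta: int):
    """Revolve an axis-to-axis (r, w) profile into a closed triangle mesh."""
    thetas = 2 * np.pi * np.arange(n_theta) / n_theta
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    verts = [np.array([[0.0, 0.0, profile[0][1]]])]
    ring_start = [None]  # vertex index where each profile row starts
    idx = 1
    for r, w in profile[1:-1]:
        verts.append(np.column_stack([r * cos_t, r * sin_t, np.full(n_theta, w)]))
        ring_start.append(idx)
        idx += n_theta
    verts.append(np.array([[0.0, 0.0, profile[-1][1]]]))
    bottom_idx = idx
    v = np.concatenate(verts, axis=0)

    faces = []
    j = np.arange(n_theta)
    jn = (j + 1) % n_theta
    # apex fan
    r0 = ring_start[1]
    faces.append(np.column_stack([np.zeros(n_theta, int), r0 + j, r0 + jn]))
    # quad strips between consecutive rings
    for k in range(1, len(profile) - 2):
        a, b = ring_start[k], ring_start[k + 1]
        faces.append(np.column_stack([a + j, b + j, b + jn]))
        faces.append(np.column_stack([a + j, b + jn, a + jn]))
    # bottom fan
    rl = ring_start[len(profile) - 2]
    faces.append(np.column_stack([rl + j, np.full(n_theta, bottom_idx), rl + jn]))
    f = np.concatenate(faces, axis=0)

    tm = trimesh.Trimesh(v, f, process=False)
    if tm.volume < 0:  # make winding outward
        f = f[:, ::-1].copy()
    return v, f


def _cup_frame(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis for the cup axis (independent of side)."""
    helper = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(helper, n)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _posterior_wall_points(spec: PhantomSpec, center, n, e1, e2) -> dict[str, np.ndarray]:
    """Two posterior reference points on the slab wall at the slice level."""
    R_out, D, f = spec.body_extent_mm, spec.body_depth_mm, spec.fillet_radius_mm
    thetas = 2 * np.pi * np.arange(720) / 720
    ring = R_out * (np.outer(np.cos(thetas), e1) + np.outer(np.sin(thetas), e2))
    nz = n[2]
    if abs(nz) < 1e-6:
        raise ValidationError("cup axis has no longitudinal component; cannot place"
                              " posterior wall landmarks")
    w = -ring[:, 2] / nz  # wall height putting the point at the slice level
    valid = (w <= -f) & (w >= -(D - f))
    pts = center + ring + np.outer(w, n)
    pts = pts[valid]
    if len(pts) < 2:
        raise ValidationError("no valid posterior wall points at the slice level")
    order = np.argsort(-pts[:, 1])  # most posterior (largest Y) first
    first = pts[order[0]]
    for k in order[1:]:
        if abs(pts[k][0] - first[0]) >= 20.0:
            second = pts[k]
            break
    else:
        raise ValidationError("posterior wall points are not laterally separated")
    left, right = (first, second) if first[0] > second[0] else (second, first)
    return {"SN_L": left, "SN_R": right}


def make_phantom(
    spec: PhantomSpec = PhantomSpec(),
) -> tuple[TriangleMesh, LandmarkSet, PhantomTruth]:
    """Build the phantom mesh, its landmark set and its exact ground truth.

    Deterministic for a fixed spec (including the noise seed).
    """
    s = 1.0 if spec.side == "left" else -1.0
    n = _cup_axis(spec)
    e1, e2 = _cup_frame(n)
    center = np.array([s * spec.cup_lateral_mm, spec.cup_posterior_mm, -spec.cup_caudal_mm])

    profile = _lathe_profile(spec)
    v_local, faces = _revolve(profile, spec.n_theta)
    # cup frame -> patient frame
    M = np.column_stack([e1, e2, n])
    vertices = v_local @ M.T + center

    if spec.vertex_noise_sd_mm > 0:
        rng = np.random.default_rng(spec.rng_seed)
        vertices = vertices + rng.normal(0.0, spec.vertex_noise_sd_mm, vertices.shape)
    mesh = TriangleMesh(vertices, faces)

    rim_circle = Circle3D(center, spec.rim_radius_mm, n)
    app = Plane(np.zeros(3), np.array([0.0, -1.0, 0.0]))
    d = spec.cup_depth_fraction * spec.rim_radius_mm
    truth = PhantomTruth(
        rim_circle=rim_circle,
        app=app,
        true_av_deg=spec.true_av_deg,
        cup_interior_point=center - 0.5 * d * n,
        spec=spec,
    )

    lm = LandmarkSet(
        {
            "ASISL": [spec.asis_half_spacing_mm, 0.0, 0.0],
            "ASISR": [-spec.asis_half_spacing_mm, 0.0, 0.0],
            "PT": [0.0, 0.0, -spec.pt_drop_mm],
            "FHC_L" if spec.side == "left" else "FHC_R": center,
            "FHC_R" if spec.side == "left" else "FHC_L": center * np.array([-1, 1, 1]),
        }
    )
    crossings = truth.slice_crossings(center[2])
    if len(crossings) == 2:
        order = np.argsort(crossings[:, 1])
        lm["AR_ANT"] = crossings[order[0]]
        lm["AR_POST"] = crossings[order[1]]
    for name, p in _posterior_wall_points(spec, center, n, e1, e2).items():
        lm[name] = p
    return mesh, lm, truth


# ---------------------------------------------------------------------------
# cohort simulator


@dataclass(frozen=True)
class SexEffect:
    """Sex-specific 3D anteversion distributions (degrees).

    Defaults are the male/female cohort moments reported for healthy adult
    hips: male 14.0 (5.4)°, female 18.4 (5.6)°; 68 of 129 subjects male.
    """

    male_mean: float = 14.0
    male_sd: float = 5.4
    female_mean: float = 18.4
    female_sd: float = 5.6
    male_fraction: float = 68.0 / 129.0


@dataclass(frozen=True)
class TiltModel:
    """Pose-angle distributions on the regression parameterisation scale.

    λ here lives on the scale the published bias regression uses (values
    near 65°, i.e. measured from the table's vertical axis), not on the
    deviation-from-neutral convention of :func:`acetaver.pose.compute_lambda`.
    The default mean is chosen so the generated mean 2D−3D bias is 5.8°.
    """

    lambda_mean: float = 65.07
    lambda_sd: float = 7.0
    rho_mean: float = 0.0
    rho_sd: float = 3.0


@dataclass(frozen=True)
class BiasModel:
    """Linear pose-bias model: Δ = b0 + b_λ·λ + b_ρ·ρ + b_int·λ·ρ + ε.

    Coefficient defaults are the published right-side multiple regression
    (b0 = −36.643, b_λ = 0.474, b_ρ = −0.318, no interaction); the noise
    SD 3.45° puts the model's R² near 0.5 under the default tilt model,
    and gives SD(Δ) ≈ 4.9°.
    """

    b0: float = -36.643
    b_lambda: float = 0.474
    b_rho: float = -0.318
    b_interaction: float = 0.0
    noise_sd: float = 3.45


#: Population BMI-class frequencies used by the cohort simulator.
BMI_CLASS_PROBS = {"<18.5": 6.0 / 129.0, "18.5-25": 54.0 / 129.0, ">25": 69.0 / 129.0}


def make_cohort(
    n_subjects: int = 129,
    sex_effect: SexEffect = SexEffect(),
    tilt_model: TiltModel = TiltModel(),
    bias_model: BiasModel = BiasModel(),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort table with two hemipelvises per subject.

    Per hemipelvis: AV³ᴰ is drawn from the sex-specific normal, the pose
    angles λ and ρ from the tilt model, and AV²ᴰ = AV³ᴰ − Δ with
    Δ = b0 + b_λ·λ + b_ρ·ρ + b_int·λ·ρ + ε. Columns: subject_id, side,
    sex, bmi_class, av3d_deg, av2d_deg, lambda_deg, rho_deg.
    """
    if n_subjects < 4:
        raise ValidationError("cohort needs at least 4 subjects")
    for sd in (sex_effect.male_sd, sex_effect.female_sd, tilt_model.lambda_sd,
               tilt_model.rho_sd):
        if sd <= 0:
            raise ValidationError("distribution SDs must be positive")
    if bias_model.noise_sd < 0:
        raise ValidationError("bias noise SD must be non-negative")
    rng = np.random.default_rng(rng_seed)
    n_male = int(round(n_subjects * sex_effect.male_fraction))
    sexes = ["male"] * n_male + ["female"] * (n_subjects - n_male)
    classes = list(BMI_CLASS_PROBS)
    probs = np.array(list(BMI_CLASS_PROBS.values()))
    rows = []
    for subject in range(n_subjects):
        sex = sexes[subject]
        bmi_class = classes[rng.choice(len(classes), p=probs)]
        mean, sd = (
            (sex_effect.male_mean, sex_effect.male_sd)
            if sex == "male"
            else (sex_effect.female_mean, sex_effect.female_sd)
        )
        for side in ("left", "right"):
            av3d = rng.normal(mean, sd)
            lam = rng.normal(tilt_model.lambda_mean, tilt_model.lambda_sd)
            rho = rng.normal(tilt_model.rho_mean, tilt_model.rho_sd)
            delta = (
                bias_model.b0
                + bias_model.b_lambda * lam
                + bias_model.b_rho * rho
                + bias_model.b_interaction * lam * rho
                + (rng.normal(0.0, bias_model.noise_sd) if bias_model.noise_sd else 0.0)
            )
            rows.append(
                {
                    "subject_id": subject,
                    "side": side,
                    "sex": sex,
                    "bmi_class": bmi_class,
                    "av3d_deg": av3d,
                    "av2d_deg": av3d - delta,
                    "lambda_deg": lam,
                    "rho_deg": rho,
                }
            )
    return pd.DataFrame(rows)


def vary(spec: PhantomSpec, **changes) -> PhantomSpec:
    """A copy of a phantom spec with the given fields replaced."""
    return replace(spec, **changes)
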