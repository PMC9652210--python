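# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate convention and units

All geometry lives in the DICOM patient frame for a supine subject
(LPS): X to the patient's left, Y posterior (vertical on the table),
Z cranial; anterior is −Y. Units are millimetres throughout. STL files
carry no unit metadata, so millimetres are a documented contract, not a
checked one. Angles cross every API boundary in degrees; internals use
radians.

## The 3D anteversion measurement

The acetabular opening is modelled as a plane: the carrying plane of a
circle fitted to the bony rim, oriented outward (away from the cup
interior, which defaults to the centroid of mesh vertices within ~one
rim radius of the rim centre). The anatomical reference is the anterior
pelvic plane (APP) through ASISL, ASISR and PT, oriented anteriorly —
when the mesh is supplied the orientation uses the mesh itself (the
pelvis lies posterior to its APP), which keeps the measurement
well-defined in any pose. With α the angle between the oriented
normals, AV = 90° − α. Anteverted cups give AV > 0; a retroverted cup
tips its outward normal posteriorly, pushing α past 90° and AV
negative — the sign needs no extra convention.

The measurement is the *direct* 3D angle between plane normals, not a
projection into the transverse plane; it therefore differs by
construction from Murray-style 2D "anatomical anteversion" definitions.

Pose invariance is structural: both planes are intrinsic to the bone,
so any rigid motion cancels. The acceptance suite verifies ~1e-6°-level
invariance with a fixed rim and < 0.3° with full curvature
re-detection over 100 random rigid poses.

## Rim delineation

Per-vertex curvature is the discrete mean-curvature magnitude from the
cotangent Laplacian with mixed Voronoi vertex areas; boundary vertices
get 0, zero-area triangles are skipped with a warning. The estimator is
validated against analytic values on a sphere (H = 1/R) and a cylinder
(H = 1/2R) at 10% tolerance.

`select_rim` implements the basic rule: threshold the field at a
percentile (default 90), split super-threshold vertices into connected
components on the mesh graph, keep components that encircle their own
best-fit axis. Two refinements proved necessary in practice:

* **Ring test.** Angular coverage alone cannot distinguish a rim loop
  from a filled blob (any 2D cluster spans 360° around its own
  centroid), so a candidate must also have a hole: the 10th percentile
  of its in-plane radii must exceed 0.4× the 90th. This rejects the
  high-curvature blobs that vertex noise creates where triangles are
  small.
* **Noise handling and threshold selection** (`detect_rim`, the
  pipeline default). Vertex noise of standard deviation σ inflates
  discrete curvature by ~σ/h² (h the edge length) and can drown the
  crest, so detection curvature is computed on a Laplacian-smoothed
  copy (10 iterations, λ = 0.5) while the returned indices refer to the
  original geometry — the circle is always fitted to unsmoothed
  vertices. Because the percentile that isolates the crest depends on
  how much of the surface is curved or noisy, a ladder of percentiles
  (97 → 80) is scanned; each candidate is trimmed to the upper half of
  its own curvature (the crest is the maximum of its band), gated on
  robust circle-fit quality (RMS < 5% of radius), and the candidate
  nearest the seed (the femoral head centre, i.e. the cup centre) wins.
  An explicit percentile disables the ladder; a manual rim vertex list
  bypasses detection entirely, mirroring manually reviewed
  delineations.

## Robust circle fit

`fit_circle3d` = total-least-squares plane (SVD) → projection → Kåsa
algebraic circle fit (closed form) → geometric refinement minimising
Σ‖pᵢ − nearest circle point‖² with Levenberg–Marquardt → iterated
outlier rejection. The normal is parameterised by tangent-plane offsets
around the initial plane normal (no spherical-coordinate pole), and the
solver runs at tol = 1e-15; on exact inputs the fit is
machine-precise, on noisy inputs reproducibility across poses is
limited to ~1e-7 mm by the finite-difference Jacobian. Outliers are
points beyond 3.5 scaled MADs of the residual distribution, iterated to
a stable inlier set (max 5 rounds); if a round would discard more than
70% of the points the structure is not outlier contamination and
iteration stops. The MAD rule is robust to the gross, one-sided
displacements that osteophytes produce. At 2500 rim points with 0.5 mm
noise the fit recovers a 25 mm radius within 0.03 mm and the axis
within 0.12°; 10% of points displaced 5 mm move the estimate by
< 0.02 mm / 0.06°.

## The 2D comparator

The axial slice is taken at the mean Z of the two femoral head centres
(the cut "closest to both heads"). Slice landmarks are obtained by
snapping projected 3D seed points to the nearest point on the slice
contours (segment projection, capture radius 10 mm by default) — a
deterministic stand-in for a radiologist's reading. The acetabular
margin seeds come from supplied AR_ANT/AR_POST landmarks or, absent
those, from the fitted rim circle's crossings of the slice plane. The
reference line is the posterior pelvic margin pair: the sciatic-notch
landmarks SN_L/SN_R by default, the ischial tuberosities IT_L/IT_R as
the transischial alternative (descriptions of the method differ on
which; both are supported and the sciatic-notch pair is the default).
The Tallroth variant uses the femoral-head-centre line instead. The
angle is signed from the anteriorly-oriented perpendicular of the
reference line, positive when the acetabular line tips medially
(anteversion); the `side` argument fixes which direction is medial.

## Pose angles and the tilt experiment

λ is the signed angle between the anterior direction and the
YZ-projection of the APP normal; ρ the signed angle between the
inter-ASIS vector and +X in the XZ-plane, positive with the left ASIS
cranial. Signs are fixed operationally: rotating a neutral pelvis by θ
about +X gives λ = θ (anterior tilt positive in this convention);
rotating about −Y gives ρ = θ. Degenerate poses (APP normal along X;
ASIS line along Y) raise errors rather than returning meaningless
values.

`tilt_sweep` rotates mesh and landmarks together about the midpoint of
the femoral head centres, re-slices at the (unchanged) head-centre
level, re-derives the 2D landmarks per pose from the fitted rim circle
and contour snapping — re-reading the tilted scan, since rotating the
old 2D points would wrongly make the 2D angle invariant — and records
AV2D, AV3D, λ, ρ per step. The sweep uses a 15 mm capture radius: at
±10° tilt the posterior-margin seeds legitimately travel up to ~10 mm
in-slice on slanted posterior surfaces. Rows whose slice or extraction
fails are flagged, not fatal. On the default phantom, ±10° of AP tilt
spans ~20° of AV2D (increasing toward posterior tilt) with AV2D
anti-monotone in λ; lateral tilt spans ~10°; AV3D stays constant to
~1e-12°.

## The phantom

The generator is deliberately non-anatomical: a lathe-built rounded
slab with a spherical-cap cup, so that every quantity in the chain has
a closed form. The cup's outward axis is
n = (s·cosA·cosi, −sinA, −cosA·sini) with A the anteversion, i the
inclination, s the side sign; since n·(0,−1,0) = sinA, the ground
truth AV = 90° − α holds identically for any inclination — exactness
by construction, not numerical accident. The rim is the sharp crest
where cap meets face (circle of the requested radius); a fillet
parameter rounds all other edges so detection has a realistic
difficulty knob. Landmarks (APP triple, femoral head centres, slice
margins, posterior wall points) are placed analytically; Gaussian
vertex noise is seeded. Defaults: AV 16.1°, inclination 45°, rim
radius 25 mm, body radius 65 mm, 192 angular samples (~19k vertices).
AV 16.1° is the reported cohort mean for healthy adult acetabula; with
45° inclination the phantom's own 2D reading is
atan(tan 16.1°/cos 45°) ≈ 22.2°, reproducing the classic ~6° 2D
overestimate.

What the phantom does *not* emulate: real pelvic anatomy (iliac wings,
foramina), partial or osteophytic rims, anisotropic CT resolution, or
segmentation artefacts. Passing tests therefore demonstrate
correctness of the measurement chain on well-posed geometry, not
robustness to pathological morphology — abnormal rims are expected to
need manual review, and the manual rim override exists for exactly
that.

## The cohort simulator

Each of n subjects contributes two hemipelvises. AV3D is drawn from
sex-specific normals (male 14.0 SD 5.4°, 68/129 of subjects; female
18.4 SD 5.6°) — the reported cohort moments for healthy adults; the
mixture reproduces an overall mean ≈ 16.1° SD ≈ 5.9°. Pose angles are
λ ~ N(65.07°, 7°) and ρ ~ N(0°, 3°); λ here lives on the published
bias-regression parameterisation scale (measured from the table's
vertical axis, hence values near 65°), which is distinct from
`compute_lambda`'s deviation-from-neutral convention. The 2D value is
AV2D = AV3D − Δ with Δ = b0 + b_λ·λ + b_ρ·ρ + b_int·λ·ρ + ε; defaults
b0 = −36.643, b_λ = 0.474, b_ρ = −0.318, b_int = 0, σ_ε = 3.45° give
E[Δ] = −5.8°, SD[Δ] ≈ 4.9° and a regression R² ≈ 0.5 — the documented
cohort-level bias structure. Because AV3D and Δ are generated
independently, the simulated AV2D's SD (~7.6°) exceeds a real cohort's
(~6°), where tilt and anatomy are not independent; the simulator
targets the Δ regression structure, not the full joint distribution.

## Statistics layer

Group summaries use the sample SD (n−1); a single observation reports
SD as missing. t-tests are Welch's by default (pooled-variance Student
available and verified against the closed form); p-values are two-sided
and reported at machine precision. OLS goes through statsmodels with an
explicit rank check that names collinear columns; interactions are
elementwise products. `run_bias_analysis` works per side — the two
hemipelvises of a subject are treated as independent within a side,
with no mixed-model correction (a deliberate simplification, noted as
a caveat) — and no multiple-testing correction is applied.

## Problem sizes

The test suite and acceptance script use the default 19k-vertex
phantom, 100 random poses for the invariance check, 50 noisy phantoms
for recovery, 21-step tilt sweeps, 50-seed circle-fit batches at 2500
points, and 50–100 replicate cohorts of 129 subjects for the
statistical recoveries; the whole suite runs in a few minutes on one
core.
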