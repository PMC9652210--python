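# acetaver

Pose-independent 3D measurement of acetabular anteversion from pelvis
surface meshes.

## The problem

The anteversion (AV) angle of the acetabulum — how far the hip socket
opens toward the front — guides the diagnosis of hip dysplasia and
retroversion and the planning of pelvic osteotomies and arthroplasty.
The conventional measurement reads the angle off a single axial CT
image, which silently folds the patient's pelvic tilt on the scanner
table into the number: the same acetabulum can read anywhere over a
>10° range depending on how the pelvis happened to lie. This package
implements a fully three-dimensional measurement that is invariant
under patient positioning, together with the conventional 2D
measurement for comparison, a virtual tilt experiment that quantifies
the 2D method's pose bias, and the statistics to analyse that bias in
a cohort.

It is aimed at researchers in orthopaedic morphometry working with
CT-derived bone surface meshes (STL, millimetres, DICOM patient frame);
segmentation from DICOM voxels is upstream and out of scope.

## The measurement

Given a triangle mesh of a hemipelvis and three anatomical landmarks:

1. **Rim delineation.** The acetabular ridge is a sharp crest, so it is
   found as a connected, ring-shaped component of high discrete mean
   curvature (cotangent Laplacian, mixed Voronoi areas). A manual rim
   vertex list may be supplied instead.
2. **Rim circle.** A robust 3D circle fit — total-least-squares plane,
   algebraic (Kåsa) initialisation, geometric refinement minimising the
   sum of squared point-to-circle distances, iterated MAD outlier
   rejection — defines the acetabular plane, oriented outward.
3. **Anterior pelvic plane (APP)** through the left and right anterior
   superior iliac spines (ASISL, ASISR) and the most anterior point of
   the pubic tubercles (PT), oriented anteriorly.
4. **The angle.** With α the angle between the two oriented normals,

   **AV = 90° − α**,

   positive for anteversion, negative for retroversion. Both planes are
   intrinsic to the bone, so AV is unchanged by any rigid motion of the
   pelvis.

The 2D comparator emulates the axial-slice reading: in the slice
closest to both femoral head centres, the angle between the acetabular
margin line and the perpendicular of a posterior reference line (the
posterior pelvic margins; or the femoral-head-centre line in the
Tallroth variant). Pelvic pose is summarised by λ (AP tilt, from the
APP normal) and ρ (lateral tilt, from the inter-ASIS line).

## Worked example

Everything is testable without clinical data through a parametric
phantom with exact ground truth:

```bash
acetaver phantom --av 16.1 --seed 7 --out ph.stl \
    --landmarks-out lm.json --truth-out truth.json
# phantom: true AV 16.1 deg, 18818 vertices, 37632 faces -> ph.stl

acetaver av3d --mesh ph.stl --landmarks lm.json --side left --out av3d.csv
# AV3D (left): 16.10 deg  (alpha 73.90 deg, rim 130 vertices)

acetaver av2d --mesh ph.stl --landmarks lm.json --variant tallroth --out av2d.csv
# AV2D/tallroth (left): 22.20 deg (slice z = -65.0 mm)

acetaver tilt-sim --mesh ph.stl --landmarks lm.json --axis AP \
    --range -10 10 --step 2 --out sweep.csv
# AP sweep -10..+10 deg: AV2D spans 13.5..33.7 deg, AV3D spans 3.31e-12 deg
```

Reading the numbers: the 3D method recovers the phantom's built-in
16.1° anteversion (the automatically delineated rim had 130 vertices
and α = 73.9°, so AV = 90 − 73.9 = 16.1). The 2D reading of the very
same bone is 22.2° — a built-in geometric overestimate of about 6°
caused by the cup's ~45° inclination (for this phantom the slice angle
has the closed form atan(tan AV / cos inclination)). Sweeping the
pelvis through ±10° of AP tilt moves the 2D reading across a 20° range
while the 3D angle changes by ~3e-12°.

Cohort-level analysis of the 2D−3D discrepancy:

```bash
acetaver make-cohort --n 129 --seed 1 --out cohort.csv
# cohort: 258 hemipelvises from 129 subjects -> cohort.csv
acetaver cohort-stats --table cohort.csv --out report.json
# left: n=129  mean Δ=-6.44 (4.48) deg;  Δ ~ -34.600 + 0.436·λ + -0.413·ρ  (R²=0.441)
# right: n=129  mean Δ=-6.18 (4.49) deg;  Δ ~ -34.779 + 0.437·λ + -0.248·ρ  (R²=0.451)
```

(Δ = AV3D − AV2D; its regression on the pose angles λ and ρ recovers
the coefficients the cohort was generated with.)

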