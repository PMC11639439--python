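# Methods

## Scope and data model

The pipeline estimates how volumetric BMD (mg hydroxyapatite per cm³)
and cortical geometry in the proximal femur vary with age and BMI, per
sex, from calibrated QCT volumes and periosteal/endosteal surface
meshes. It assumes cross-sectional data (each donor scanned once), a
linear covariate model at every spatial position, and femurs free of
gross deformity. Both femurs of a donor enter as separate cases with no
within-donor correlation correction; an optional donor-cluster-robust
variance is available as a sensitivity toggle (off by default) and the
non-independence is a known limitation of the default analysis.

## Synthetic phantom

The generator stands in for a cadaver QCT study and defines the study
conditions the tests run under.

**Geometry.** A right-femur template composed of analytic primitives —
head sphere, neck round-cone, shaft cylinder, greater/lesser trochanter
ellipsoids — blended with a polynomial smooth-min (blend radius 7 mm)
into a single signed-distance field (SDF). The SDF is evaluated on a
regular grid; the femur mask is its negative set at voxel centers and
both surfaces come from marching cubes of the same field (periosteal at
level 0, endosteal at level `sdf + t(x)` where `t` is the local cortical
thickness), so meshes and mask are consistent by construction. Template
dimensions (head radius 23 mm, neck radius 13 mm, neck-shaft angle 130°,
shaft radius 14.5 mm, …) are fabricated plausible adult values, not
population measurements; everything scales through
`FemurPhantomParams.scaled`. Left femurs are exact sagittal mirrors of
the right template — volume, meshes and landmarks are mirrored after
realization, so left/right pairs are bit-identical reflections.

**Cortical thickness map** `t(x)`: per-sector values (head 1.0, superior
neck 1.8, inferior neck 3.2, trochanter 2.2, shaft 4.5 mm) blended by a
softmax over the primitive SDFs and a sigmoid on the superior in-plane
coordinate, so transitions are smooth. A grid too coarse to hold one
voxel across the thinnest shell raises a warning flag in the truth
record rather than an error.

**Density model.** Trabecular BMD at position x is
`age·q(x) + BMI·s(x) + b(x)`; the cortical shell elevates the intercept
`b` by 480 mg/cm³ over the 320 mg/cm³ trabecular base through a smooth
shell indicator. Default effect fields encode the qualitative aging
pattern the analysis should find: `q` ≈ −3.5 mg/cm³/yr in the superior
neck, ≈ +0.1 in the inferior neck, −1.2 elsewhere; `s` peaks at
2.6 mg/cm³ per BMI point in the medial shaft endocortex over a 0.4 base.
Magnitudes are configurable; the residual scatter defaults to 30 mg/cm³.

**Acquisition.** HU = 0.8·BMD − 20 by default, additive Gaussian HU
noise, voxel spacing (1.1, 1.1, 0.7) mm — a mid-range clinical QCT
grid. The spacing matters: with coarse isotropic voxels a 1.5 mm
sampling sphere holds fewer than five voxel centers and the dismissal
rule (below) would empty the atlas. A six-chamber calibration rod
(0–800 mg/cm³, 9 mm chamber radius, 24 mm pitch, resin body at −80 HU)
is voxelized either as a free-standing slab or stamped into every slice
of a case volume; an optional per-slice intercept drift emulates
tube-current modulation.

**What the phantom does not emulate:** trabecular microarchitecture,
partial-volume blur and beam hardening, anatomical shape variation
beyond uniform scaling (three discrete sizes in pipeline runs), and
nonlinear age effects. Passing tests therefore demonstrate correctness
of the measurement and inference chain under the stated model, not
robustness to real anatomical variability or scanner physics.

## Calibration

Chambers are detected per axial slice by thresholding above the rod
body (default body + 30 HU), connected components filtered by
equivalent radius and circularity, with a Hough-circle fallback;
chambers order left-to-right by increasing nominal concentration.
Means are taken over pixels whose centers lie strictly within 80 % of
the detected radius, excluding the partial-volume rim. The applied
mapping is the direct concentration-on-HU least-squares line (the
forward HU-on-concentration fit is reported alongside; the two differ
under noise). Calibration is slice-local to absorb current modulation;
slices where detection fails inherit the nearest valid slice's line and
are counted in the run report.

## Coordinate frame

All estimators use mesh geometry only, making the frame equivariant
under rigid transforms (verified to 0.5°/0.2 mm).

- **Shaft axis**: total-least-squares line through centroids of ~10
  cross-sections in the distal 5–45 % of the rough PCA extent; the
  distal end is the one with smaller off-axis spread. Stored pointing
  distally, matching the z-station ordering.
- **Head sphere**: seeded at the vertex farthest from the shaft axis
  (the head protrudes farther than the greater trochanter), then
  iterated algebraic sphere fits (Coope linearization) on a ±12 %
  radius band. Residual RMS above 15 % of the radius is an unreliable
  fit.
- **Neck axis**: through the head center; direction re-fit from
  cross-section centroids in a band 1.1–1.6 head radii from the center,
  iterated 8 times. A joint refinement then re-aims the neck axis at
  the closest-approach midpoint and shifts the shaft axis through it,
  so the axes intersect exactly.
- **Cutting plane**: orthogonal to the neck axis at the most lateral
  station (3 mm steps) before the forward relative cross-section-area
  growth exceeds 15 % per station — the greater-trochanteric flare. The
  threshold and step are assumptions (no published value) and are
  config-exposed; a flat profile falls back to the most lateral station
  with a flag.
- **Lesser trochanter**: vertex maximizing medial-posterior protrusion
  off the shaft axis, searched distal of the axis intersection within
  the proximal half of the shaft; medial is defined by the head-center
  offset, posterior by side-dependent handedness.
- **Distal crop**: lesser-trochanter level plus 0.9·V^(1/3) along the
  shaft axis, V the mask volume above the lesser trochanter (cube root
  makes the offset scale with femur size); clamped with a flag if the
  mesh ends sooner.

On generator output the chain achieves ~0.7 mm head-center error,
axes within ~2°, landmark within ~1.6 mm.

## Point cloud

39 z-stations: 0–12 along the neck axis (z0 head-surface piercing, z5
head center, z12 cutting plane), 13–38 along the shaft axis (z13 most
superior shaft level, z15 cutting plane at the superior neck surface,
z28 lesser trochanter, z38 crop), intermediate stations equidistant
between anchors. Extreme shaft stations are nudged 1.5 mm off the
tangent planes to avoid degenerate sections. Twelve directions per
station at 30°: φ=0 points superior (projected shaft axis) on neck
planes and lateral (projected neck axis) on shaft planes; rotation is
counterclockwise viewed from proximal on a right femur — left femurs
are mirrored first, never re-signed. On shaft planes direction index 7
(nominal 210°) is re-aimed at the lesser trochanter's azimuth (measured
once in the z28 plane) and indices 8–11 re-spaced equally to 360°.

r=1 is the farthest ray-mesh intersection (greater-trochanter rays can
cross the surface several times); on shaft stations z13–27 the cutting
plane substitutes for the surface when hit first. Radial counts per
(φ, z) are `max(1, round(L_ref / 4 mm))` on the reference geometry and
frozen, giving 1899 points on the default template — the same order as
the ~1700–1800 positions such atlases use in practice; the r=0 axis
point is emitted once per station. The 4 mm spacing (rather than a
denser grid) was chosen so the default cloud matches that published
scale; it is config-exposed. Points outside a particular femur are
flagged, never dropped, so the (z, φ, ordinal) index set is identical
across femurs by construction.

## BMD sampling

Sphere radius = 1.5 mm · (V/V_ref)^(1/3) with V the volume above the
lesser trochanter — sphere volume tracks femur volume, so cloud
coverage is size-invariant (verified to <1 %). Membership is
voxel-center-in-sphere with no partial-voxel weighting, clipped to the
femur mask; this makes the five-voxel minimum an exact count and the
mean bit-reproducible by brute-force enumeration (tested on 500 random
draws). Spheres with fewer than five qualifying voxels are dismissed;
points dismissed in strictly more than 20 % of cases are removed from
the atlas. The five-voxel count applies after mask clipping (the rule's
sentence structure reads most naturally that way; counting before
clipping would only matter for spheres already straddling the surface).

## Regressions

Per-point OLS with design [age, BMI, 1], implemented directly (closed
form with t-distribution p-values) and cross-checked against
statsmodels in the tests. Defaults: minimum 10 usable cases per fit
(no published value exists; configurable), α = 0.05 strict, no
multiple-testing correction. Points failing to fit are recorded, not
silently dropped. ROI summaries average non-dismissed points per case
before fitting; dismissed points are excluded rather than imputed.
Default ROI boundaries are fabricated z-index ranges (head 0–7, neck
8–12, greater trochanter 13–19, intertrochanteric 20–28, shaft 29–38)
and fully overridable. Relative differences divide slopes by the
prediction at age 20 / BMI 25.

## Cortical geometry

Per (φ, z) direction, the farthest intersection with each of the
periosteal and endosteal meshes gives the outer and inner radius;
thickness is their difference. Rays missing either mesh or with inner
beyond outer are invalid. The femoral head is excluded (sub-voxel
cortex defeats endosteal segmentation there); the endosteal surface is
an input contract — ground truth from the generator here, an external
cortical-bone-mapping tool on real data. Quadrants: anterior
(60–120°), inferior/medial (150–210°), posterior (240–300°),
superior/lateral (330–30°), averaged over neck z 9–12 and diaphysis
z 33–38. Profiles are interpolated with a cubic periodic interpolating
spline (not smoothing) through the 12 control values.

## Numerical choices

- Ray casting is a vectorized Möller–Trumbore all-hits query with
  triangles prefiltered to those crossing the station plane; no spatial
  index is required at these mesh sizes.
- Cross-section areas/centroids use the shoelace formula per closed
  intersection loop in an in-plane basis; loops below 1e−9 area are
  discarded.
- Sphere fits use Coope's linear least squares; line fits use SVD
  principal directions.
- Pixel/voxel membership rules are strict inequalities throughout
  (chamber fraction, sphere radius, significance threshold, removal
  fraction), so boundary cases are deterministic.
- Degenerate inputs raise typed errors naming the offending quantity
  (collinear covariate, empty averaging region, out-of-order anchors);
  the pipeline wraps them in stage-named errors with the case id.

## Problem sizes

The test suite and examples run the full chain at the default grid
(~1M voxels per case) with populations of up to 60 cases per sex for
parameter-recovery checks, 2000 independent points for the test-size
simulation, and 3-donor paired runs for end-to-end orchestration —
sizes chosen so each property is measured with comfortable statistical
margin while the whole suite stays quick on one core.

## Known limitations

Axis estimators are tuned for adult morphology; pediatric or severely
deformed femurs are out of scope. The cutting-plane threshold and the
reference radial spacing are assumptions where no published value
exists. The generator's uniform-scale shape variation cannot probe
correspondence quality under real shape variability, and the default
analysis inherits the two-femurs-per-donor non-independence discussed
above.
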