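# Methods

## Problem and model

`footprintmorph` quantifies the 3D morphology of muscle-attachment
footprints from CT. The measurement model follows the radiopaque-paint
protocol: each attachment is painted with barium-sulfate paint on a
dissected specimen, the limb is CT-scanned after each dissection step, bone
and paint are segmented from the Hounsfield-unit (HU) images, repeat
reconstructions of the same bone are rigidly aligned, and the paint's
contact area is traced onto the bone surface. Each footprint is summarised
by its area, its area-weighted centroid, a best-fit plane, and a
*breakthrough point* — the intersection of the line through the centroid
along the plane normal with the footprint surface — which serves as the
single-point attachment proxy for musculoskeletal models. Cohort variation
is reported descriptively as the mean with the **population** standard
deviation (divisor *n*) and the coefficient of variation CV = 100·STD/mean.

## Synthetic specimens

No raw cadaveric geometry is available, so every downstream stage is
exercised on synthetic specimens with analytically known ground truth.

* **Bones** are unions of implicit primitives (spheres and capsules). The
  phantom femur places the head center a mechanical-axis length
  (default 405 mm) cranial of the transepicondylar-axis (TEA) midpoint,
  uses a 17.85 mm shaft radius and a 91.65 mm TEA — the cohort means of the
  reference study — so the morphometric stage can be validated against its
  construction parameters. Meshes come from marching cubes of the signed
  distance function (default pitch 1 mm), which is sub-voxel accurate on
  smooth implicit surfaces.
* **Paint patches** are regions of a host primitive's parametric surface:
  spherical caps (area 2πr²(1−cos θ), centroid on the axis at
  r(1+cos θ)/2 — closed form), and rectangles or irregular blob polygons in
  the unrolled coordinates of a cylinder barrel. The unrolling is an
  isometry, so the planar polygon area *is* the surface area, exactly.
  Where a region partially runs under another primitive (e.g. a shaft
  region reaching the head), ground truth is restricted to the exposed part
  via a dense deterministic surface grid; placements less than half exposed
  are rejected. The patch *mesh* is a thin shell offset 0.15 mm outward
  from the painted bone faces — paint and bone interblend on real CT, so
  the footprint is defined on the bone surface itself.
* **Voxelization** assigns air (−1000 HU), soft tissue (40 HU, within
  12 mm of bone), cortical bone (1200 HU) and paint (2600 HU, a 1.2 mm
  band outside the bone surface inside the patch region), plus optional
  Gaussian HU noise, all deterministic per seed. Bone (1200) and paint
  (2600) both exceed the 250 HU bone window and are separable at 2000 HU.
* **Cohorts** default to 4 specimens (three left, one mirrored right), with
  patch areas log-normal around their base value at a requested CV
  (default 33%, the reference study's mean attachment-area CV; log-normal
  keeps areas positive at high CV), positional jitter on the surface
  (SD 3 mm), and a global specimen size factor (CV 5%). All specimens share
  the base seed for seed-dependent patch shapes, so requesting CV = 0
  yields bit-identical truth areas. Repeat "scans" apply small rigid
  perturbations (SD 0.3°, 0.5 mm) before voxelization, emulating
  repositioning between dissection steps.

The generator does **not** emulate trabecular texture, beam hardening,
scanner artifacts, partial-volume blur beyond voxel discretisation, or
soft-tissue heterogeneity. Passing tests therefore demonstrate the
correctness of the geometry and statistics pipeline, not robustness to
scanner physics.

## Segmentation

Thresholding uses the inclusive window [250, 3000] HU (the conventional
reading of the established cortical-bone window). Paint is separated by a
secondary threshold (≥ 2000 HU) whose seed set is dilated by one voxel and
re-intersected with the primary mask, assigning partial-volume interface
voxels to the paint; bone is the set difference, so the two labels always
partition the primary mask. Isosurfaces are extracted by marching cubes at
level 0.5 after a Gaussian anti-aliasing filter (σ = 0.8 voxel): raw binary
marching cubes produces a staircase surface whose area overestimates smooth
anatomy by ~8%, while the filtered isosurface stays within half a voxel of
the mask boundary and recovers a 20 mm sphere's area to 0.1% and its volume
to 1% at 1 mm spacing. Structures smaller than ~27 voxels are extracted
unfiltered (the filter could erase them); a single voxel meshes to its
trilinear isosurface, the octahedron of area √3 mm². Sharp edges are
rounded within about one voxel, so mask/mesh volume agreement is
anatomical-scale: within 5% for convex phantoms ≥ 20 mm. The
largest-connected-component rule stands in for the manual exclusion of
stray calcifications and can be disabled (`keep="all"`).

## Registration, deviation, coherent models

Registration is landmark-initialised ICP (the original workflow used
proprietary software without stating its algorithm): a least-squares rigid
(Kabsch) fit on ≥ 3 landmark pairs, refined by iterating exact
nearest-point matching of area-uniform surface samples (default 2000) with
weighted Kabsch updates until the mean distance improves by < 1e-4 mm or
100 iterations. Nearest-point queries prune candidates with a k-d tree on
triangle centroids and evaluate exact point–triangle distances, with a
guaranteed-radius fallback (oversized triangles are internally subdivided
to keep that radius tight); the result is exact, matching brute force to
machine precision. A known 10°/5 mm transform is recovered to < 0.05° and
< 0.05 mm.

Deviation analysis is one-directional (test → reference), unsigned, on
area-uniform samples, reported as mean ± population STD — matching how
repeat-scan reconstructions are compared against the first-scan reference.

`merge_and_clean` welds coincident vertices (1e-6 mm), closes boundary
loops of ≤ 200 edges by centroid fans (larger holes are genuinely missing
geometry and stay open; non-simple rims are skipped rather than patched
with non-manifold fans), and applies Taubin smoothing with volume
restoration by rescaling about the centroid (drift ≪ 1%). In the pipeline
the coherent model per bone is the cleaned, smoothed *reference*
reconstruction: repeat scans produce closed shells that overlap the
reference everywhere rather than extending it, so stitching them would
double the surface; the repeats instead contribute the deviation
quantification and carry their scan's paint marks into the reference frame
through their bones' transforms.

## Anatomical frame and femoral morphometrics

The femoral frame follows the ISB convention: origin at the TEA midpoint,
y toward the head center (cranial), z the component of the medial→lateral
epicondylar direction orthogonal to y, x = y × z (anterior). The textual
definition of the z-axis in the source protocol is ambiguous (the plane it
names is not unique); the standard ISB resolution is implemented. Because z
is built from the anatomically labeled medial→lateral direction it points
laterally on either side, and mirrored (left) specimens automatically land
in the same frame coordinates as right ones — no separate sign convention
is needed for cohort statistics.

Morphometrics: MA = |head center − TEA midpoint| (the only definition
computable from the protocol's named landmarks, and consistent with its own
frame); TEA = inter-epicondylar distance; FHD = diameter of an algebraic
least-squares sphere through the head-surface points, with two robust
trimming passes (3σ) to reject neck/junction contamination; SD = equal-area
diameter 2√(A/π) of the cross-section at 50% MA along y — the location and
caliper convention are otherwise unstated, and the equal-area diameter is
rotation-invariant and robust to non-circular sections. Cross-section loops
are filled and unioned via shapely, so spurious specks cannot double-count.

## Footprint tracing

A bone face belongs to a footprint when (1) its centroid is within ε
(default 0.5 mm, the scale of the observed inter-scan segmentation
deviation) of the paint surface, (2) the nearest paint point does not lie
on the paint's open rim, and (3) the paint is in direct contact
(< 0.25 mm) or overhead — the displacement within 45° of the face normal.
A pure ε-ball rule would also capture faces laterally *beside* the paint
rim and systematically dilate the footprint by ~√(ε² − h²) ≈ 0.5 mm beyond
the painted boundary (≈ 6% area for a 30° cap); the rim and normal-cone
tests express "paint overlying the face" and reduce the bias to boundary
quantization (± half a face, zero-mean). Footprint area is non-decreasing
in ε. Small connected components (< 5% of the largest, by area) are
dropped as spurious contacts. Overlapping marks are resolved by assigning
contested faces to the nearer paint, with lexicographic name order breaking
exact ties.

The best-fit plane minimises the area-weighted squared orthogonal distance
of face centroids (smallest eigenvector of the area-weighted covariance),
its normal oriented outward (along the mean face normal). The breakthrough
point is the nearest intersection of the centroid's plane-normal line with
the footprint (Möller–Trumbore over the submesh); if the line misses
(annular footprints), the nearest surface point is returned with a fallback
flag. Either way the point lies on the footprint surface to 1e-6 mm.

Subdivision assigns whole faces by centroid side (faces are never split),
so children partition the parent exactly and areas are conserved to the
last bit, at the cost of cut lines ragged by up to one face width.
"Divided three times in length" is read as *three equal-length parts*; the
vastus-intermedius rule is one halving plane (through the most proximal
point, most distal point and the mid-edge point) crossed with length-wise
thirds, giving the stated six parts. The thinnest-part rule scans interior
cut positions (25 candidates in the middle 60% of the chord, slab width 5%
of the length) for the minimal across-chord spread.

## Statistics and report tables

All summaries use the population STD (divisor *n*), which exactly
reproduces the reference study's printed Tables from its printed
per-specimen values. Report rendering rounds half away from zero to two
decimals after removing binary representation noise (so decimal ties like
405.375 round up as they would on paper); internal values stay unrounded.
Two printed summaries are not derivable from printed inputs and are
documented rather than reproduced: the femur-only deviation mean (prints
0.48; the printed per-scan values give 0.47) and the surface-area CV STD
(prints 1.55; the printed CV column gives 1.56) — both evidently computed
from unrounded source data.

## Problem sizes and determinism

Default study conditions: 4 specimens, 1 mm voxel spacing (the protocol's
slice thickness), 33% target area CV, 0.5 mm tracing ε. The bundled test
and acceptance runs use a femur/tibia-fibula/patella scene with six
representative attachments, two scans per specimen at 1.5 mm spacing, 2000
deviation samples, and 20+ random patches at 0.4 mm mesh pitch for
ground-truth recovery (narrow 4–6 mm strips need sub-half-mm faces to keep
boundary quantization under 3%). Every random draw flows from an explicit
seed (NumPy `default_rng` / `SeedSequence.spawn`); the full pipeline writes
byte-identical report CSVs across repeat runs with the same seed.

## Known limitations

* Footprint accuracy through the full voxel pipeline is bounded by the
  voxel size (~±1 voxel at the paint/bone interface, where labeling is
  inherently ambiguous); the 3% recovery guarantee applies to the clean
  mesh path.
* Phantom bones are unions of smooth primitives: no condylar grooves,
  trabecular structure or cortical-thickness variation, and landmark
  placement is exact by construction — real landmark digitisation error is
  not modeled.
* The hole filler only closes simple rims; pathological non-manifold
  boundaries are left open with a warning.
* No inferential statistics (the workflow reports descriptive variation
  only), no non-rigid registration, no DICOM handling.
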