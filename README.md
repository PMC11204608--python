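# footprintmorph

CT-based 3D morphometry of muscle-attachment footprints on bone surfaces.

Muscle attachments ("footprints") are commonly reduced to single points in
musculoskeletal models, discarding their real areal extent and its
between-subject variation. One way to measure footprints in 3D is to dissect
a specimen, paint each attachment with radiopaque barium-sulfate paint, CT
scan the limb after each dissection step, and reconstruct bone and paint
from the Hounsfield-unit (HU) images. `footprintmorph` implements that
workflow as a reusable, fully tested pipeline:

1. **Synthetic specimens** — phantom bones built from implicit primitives
   (spheres, capsules) with paint patches whose surface area and centroid
   are known analytically, voxelized into CT-like HU volumes; cohorts with
   controlled log-normal between-specimen area variation (requested CV),
   positional jitter and left/right mirroring.
2. **Segmentation** — inclusive HU-window thresholding (bone window
   250–3000 HU), separation of the barium paint by a secondary threshold
   (default 2000 HU), and anti-aliased marching-cubes isosurfacing.
3. **Surface processing** — landmark-initialised ICP registration of
   repeat-scan reconstructions, unsigned point-to-surface deviation
   analysis (mean ± population STD), welding/hole-filling/Taubin smoothing
   into one coherent model per bone.
4. **Anatomy metrics** — bone volume, surface area and center of gravity by
   the divergence theorem; the ISB femoral frame (origin at the
   transepicondylar-axis midpoint, y cranial toward the head center,
   z lateral, x anterior); femoral morphometrics MA, TEA, FHD
   (least-squares sphere fit) and SD (equal-area mid-shaft diameter).
5. **Footprint analysis** — automated tracing of the paint contact area
   onto the bone surface, footprint area, area-weighted centroid, best-fit
   plane, the *breakthrough point* (where the centroid's plane-normal line
   pierces the footprint — the single-point proxy for musculoskeletal
   models), and the subdivision rules for linear and wrap-around
   attachments (thirds, plane splits, the 2×3 vastus-intermedius rule,
   thinnest-part cuts).
6. **Variation statistics** — population summaries mean ± STD (divisor *n*)
   and CV% per bone metric and attachment, rendered as 2-decimal report
   tables.

## Worked example

Trace a painted spherical cap (half-angle 30°) on a 25 mm femoral head and
derive its footprint quantities:

```python
import footprintmorph as fm
from footprintmorph.synthetic import make_synthetic_bone, make_paint_patch

femur = make_synthetic_bone("femur")           # 405 mm mechanical axis
patch = make_paint_patch(femur, "cap", {"primitive": "head", "half_angle_deg": 30.0})
fp = fm.trace_contact_area(femur.mesh, patch.mesh, epsilon=0.5)
print(f"truth area  {patch.truth_area:.1f} mm^2")
print(f"traced area {fp.area:.1f} mm^2")
print(f"breakthrough {fp.breakthrough_point.round(2)}")
morph = fm.measure_femur(femur.mesh, femur.landmarks)
print(f"MA {morph.MA:.1f}  TEA {morph.TEA:.2f}  FHD {morph.FHD:.2f}  SD {morph.SD:.2f}")
```

prints

```
truth area  526.1 mm^2
traced area 522.9 mm^2
breakthrough [4.0e-02 4.3e+02 0.0e+00]
MA 405.0  TEA 91.65  FHD 50.00  SD 35.69
```

The analytic cap area is `2*pi*r^2*(1-cos(30°)) = 526.1 mm²`; the traced
footprint recovers it to well under 1%, and the breakthrough point lands on
the cap apex at `(0, 405+25, 0)`. The full pipeline (`footprintmorph run --seed 9
--out run/`) segments a seeded 4-specimen synthetic knee cohort, aligns the
repeat scans, traces every attachment and writes deviation, bone-morphology,
femoral and attachment summary tables as CSV.

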