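# cobbcurve

Automated Cobb-angle measurement on anteroposterior spine radiographs.

The Cobb angle is the standard scalar measure of scoliotic curvature: the
angle between the superior endplate of the uppermost involved vertebra and
the inferior endplate of the lowest involved vertebra of a curve.
Equivalently — because the angle between two lines equals the angle between
their perpendiculars — it is the angle between the tangents to the spinal
midline at those two levels, which is the formulation this package
measures. A Cobb angle above 10° is diagnostic of scoliosis; 10–25° is
graded mild, 25–45° moderate, and above 45° severe.

`cobbcurve` is aimed at researchers evaluating automated scoliosis
quantification. It implements the measurement chain downstream of vertebra
detection, plus everything needed to validate it without clinical data:

1. **imageprep** — read 8/16-bit grayscale PNG/TIFF, standardize to the
   900 × 1900-pixel working frame by aspect-preserving letterboxing
   (stretching would bias every angle), optional contrast enhancement
   (percentile windowing, gamma, CLAHE).
2. **detect** — an ordered superior→inferior vertebra-box sequence, either
   from annotation files (JSON / CSV / YOLO-style labels) or from a
   classical detector (Otsu threshold → morphological opening → connected
   components → area/aspect gates → lateral outlier guard), with optional
   Hough-transform endplate-tilt refinement.
3. **midline** — ordinary least-squares fit of the lateral position as a
   polynomial of the vertical coordinate, x = f(y) = a₀ + a₁y + … + aₙyⁿ
   (degree chosen from the data by default), inflection points as the real
   roots of f″, and partition of the spine into inflection-bounded curve
   segments with apex and lateral side.
4. **cobbmeas** — one Cobb angle per segment,
   θ = |atan f′(y_upper) − atan f′(y_lower)|, end-vertebra selection,
   thoracic/lumbar labeling, an endplate-tilt cross-check, and an
   annotated overlay rendering.
5. **classify** — the decision tree over the two largest angles
   (no scoliosis / thoracic / lumbar / thoracolumbar / combined) and the
   severity grading.
6. **evalstats** — manual-vs-automated comparison tables: average/min/max
   summaries, difference reports, paired t (or Wilcoxon) tests.
7. **phantom** — a synthetic spine-phantom generator whose Cobb angles are
   known in closed form, the ground-truth oracle for everything above.

## Worked example

Generate a double-curve phantom (requested angles 30° superior and 20°
inferior, one inflection, mild noise), then measure it end to end through
image standardization, classical detection, the midline fit and
classification:

```sh
cobbcurve phantom --curves 2 --angle-up 30 --angle-low 20 \
    --n-vertebrae 14 --noise-sigma 0.02 --seed 7 --out-dir demo
cobbcurve measure demo/phantom.png --report demo/report.json \
    --overlay demo/overlay.png
```

The report (abridged):

```json
{
 "classification": "thoracolumbar",
 "severity": "moderate",
 "measurements": [
  {"region": "thoracic", "angle_deg": 30.0, "upper_vertebra": 0,
   "lower_vertebra": 7, "side": 1},
  {"region": "lumbar", "angle_deg": 20.0, "upper_vertebra": 7,
   "lower_vertebra": 13, "side": -1}
 ],
 "model": {"degree": 3, "rms_residual": 0.023}
}
```

Both requested angles are recovered to the 0.01° print precision. The two
curves exceed 10° and deviate toward opposite sides, so the classifier
reports thoracolumbar scoliosis; the larger angle (30°) falls in the
25–45° band, hence moderate severity. `demo/overlay.png` shows the
detected boxes (green), the fitted midline and the tangent lines at the
segment boundaries (red) with the angle labels.

Library use mirrors the CLI:

```python
import cobbcurve as cc

spec = cc.spec_from_angles(2, angle_up=30, angle_low=20, n_vertebrae=14)
image, boxes, truth = cc.generate_phantom(spec)
seq = cc.detect_classical(image)
model = cc.fit_midline(cc.centers(seq))
measurements = cc.measure_spine(model, seq)
```

## Limitations

No vertebral-rotation assessment, no sagittal-plane (kyphosis/lordosis)
angles, no anatomical labeling (T1…L5), and no learned detector — the
detection interface is pluggable so an external model's boxes can be fed
in via annotation files. See `docs/methods.md` for the model details,
conventions and numerical choices.
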