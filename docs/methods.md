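# Methods

## Measurement model

The spine on an anteroposterior radiograph is treated as a single-valued
curve of the vertical image coordinate: lateral position
x = f(y) = a₀ + a₁y + … + aₙyⁿ, y increasing downward
(superior → inferior). The polynomial is fitted to the vertebral box
centers by ordinary least squares. Since the column is quasi-vertical,
x-as-a-function-of-y is the only single-valued parameterization; fitting
y = g(x) would fail for any spine with a vertical tangent segment.

A curve segment is a maximal span over which the midline bends in one
direction; its boundaries are the domain endpoints and the inflection
points (real roots of f″ inside the fitted span). The Cobb angle of a
segment is

  θ = |atan f′(y_upper) − atan f′(y_lower)|,

the angle between the midline tangents at its boundaries. This coincides
with the classical endplate construction because the angle between two
lines equals the angle between their perpendiculars. The end vertebrae
reported with each angle are those whose center heights are nearest the
segment boundaries, distance ties broken toward the segment interior.

Tangents are evaluated at the segment boundaries by default; a
`tangent_at="vertebra"` mode evaluates them at the end-vertebra center
heights instead, for users who prefer the measurement anchored to
vertebral levels. The two coincide on noise-free phantoms to within the
boundary/vertebra offset.

### Side and region conventions

Each segment carries a lateral side sign: the sign of the apex's deviation
from the chord joining the midline's values at the two span endpoints
(+1 toward image right). The apex is the root of f′ inside the segment
(the point of vertical tangent) or, failing that, the boundary with the
smaller |f′|. When the apex lies on the chord — which happens exactly when
it falls on a span endpoint — the sign of the segment's maximal chord
deviation is used; an identically-zero deviation (a straight spine)
resolves to +1 by convention. The chord rule was chosen over the sign of
f″ deliberately: consecutive inflection-bounded segments alternate f″ sign
by construction, which would make a "both curves toward the same side"
classification outcome structurally unreachable.

Because the pipeline carries no anatomical labels, thoracic/lumbar regions
are assigned by the apex's vertebra-rank fraction: with two segments the
superior apex is thoracic and the inferior lumbar; with one (or more than
two) segments a fraction below 0.5 reads thoracic, otherwise lumbar. Extra
segments beyond two are retained in the report; the two largest angles
feed classification.

### Classification and severity

The decision tree over the upper and lower angle: no angle above the 10°
diagnostic threshold (strict inequality) → no scoliosis; exactly one above
→ thoracic if the upper angle is the greater, else lumbar; both above →
thoracolumbar when the sides differ, combined when they agree. The
same-side→combined assignment is the reverse of common clinical usage
(where a single long same-direction curve is usually called
thoracolumbar); a `clinical_convention` switch swaps the two labels and is
off by default. Severity is graded on the maximum reported angle with
upper-inclusive half-open bands — none (0, 10], mild (10, 25], moderate
(25, 45], severe (45, ∞) — resolving the overlap of the conventional
"10–25°" and "25–45°" phrasings consistently with the strict diagnostic
threshold; `band_convention="lower"` moves the shared endpoints 25 and 45
into the higher band.

## Fitting: conditioning and degree selection

The fit runs on y affinely rescaled to [−1, 1] (numpy's `Polynomial.fit`
window); exposed coefficients are converted back to pixel coordinates. At
the 1900-px frame a raw degree-6 Vandermonde is numerically hopeless; the
rescaled basis keeps all downstream evaluation (Horner, derivatives via
the chain rule) stable.

The degree is selected from the data by default: starting from
min(6, n − 2), the leading coefficient of the rescaled LS fit is t-tested
against zero at α = 0.01 and insignificant leading terms dropped one
degree at a time. Rationale: Cobb angles are read from tangent slopes at
the span *ends*, exactly where excess polynomial capacity inflates the
slope variance; on 17 centers with 2-px jitter a fixed degree-5 fit
produces endpoint-slope errors of several degrees and spurious
inflections, while the backward-eliminated degree tracks the true
curvature order. On exact polynomial centers the selector returns the
generating degree (spurious higher terms are numerically zero and
dropped, true leading terms have vanishing standard error), so exact
recovery is unaffected. Degrees 1–6 can always be forced explicitly; six
supports up to three inflections with one transitional curve beyond the
classic thoracic + lumbar pattern.

Inflections are located by a 1-px sign-change scan of f″ refined by
bisection to 10⁻⁶ px; roots within 0.5 px of a domain endpoint are dropped
as boundary-degenerate. (The phantom's analytic ground truth finds the
same roots independently via the companion matrix on the rescaled basis.)

## Image standardization

Inputs are rescaled so intensities lie in [0, 1] by container bit depth,
then letterboxed into the 900 × 1900 working frame: an aspect-preserving
resize (bilinear, anti-aliased when shrinking) followed by symmetric
zero-padding. Letterboxing rather than stretching is the single most
important geometry decision — anisotropic scaling by factor s would remap
every tangent slope by s and bias every angle. Pad offsets and scale are
recorded so detections map back to original coordinates (round trip within
0.51 px, pixel-center convention).

Contrast enhancement stands in for the interactive window/level adjustment
of a DICOM viewer: `window` (linear stretch of the 2nd–98th intensity
percentiles, default), `gamma`, and `clahe` (8 × 8 tile grid). Parameters
are user-supplied; automatic selection is out of scope. Window and gamma
are globally order-preserving; CLAHE is locally adaptive and only
polarity-preserving (bone stays brighter than adjacent background).

## Classical detection

Global Otsu threshold (or user threshold) → 3 × 3 morphological opening →
connected components → area gate in [0.25, 4] × a reference area → aspect
gate (width/height ∈ [0.8, 4.0]) → vertical sort → lateral outlier guard
(reject centroids deviating > 60 px from the running median of up to four
neighbors). The area reference is the *area-weighted* median component
area (the area of the component containing the median foreground pixel):
on low-contrast noisy images small noise specks outnumber the vertebrae
and would drag a plain median far below any real body.

Centers are excess-intensity-weighted centroids — the center of mass of
max(I − threshold, 0) over each component — rather than binary-mask
centroids, which quantize at the pixel grid and produce ~0.4-px errors
varying smoothly along the column (enough to masquerade as real curvature
to the degree selector). The weighted centroid is unbiased for a blurred
symmetric body.

Endplate refinement runs a straight-line Hough transform (1 px × 1°
resolution, orientations within ±30° of horizontal) on the
gradient-magnitude edge map of each box window, padded vertically by half
the box height; the strongest peak in the upper/lower half gives the
upper/lower endplate tilt (positive = right side lower). The endplate
route is a cross-check, not the primary method: endplate identification is
the classical weak point, and on phantoms with vertebra tilts consistent
with the curve it agrees with the midline-tangent angle to within a couple
of degrees.

## The phantom generator

A phantom is a column of 12–17 bright quasi-rectangular vertebral bodies
(default 110 × 70 px, 30 px spacing, intensities 0.8 on 0.2) whose centers
lie on a generating polynomial midline inside the 900 × 1900 frame,
rendered with Gaussian blur (default σ = 1 px), optional additive Gaussian
noise, and optional per-vertebra rotation of the rendered rectangle.
Axis-aligned bodies are rendered with exact partial-pixel coverage so the
image-domain centroid sits on the generating curve to well under 0.1 px.
Annotation boxes are axis-aligned (matching what a box detector outputs)
even when the rendered body is tilted; the tilt information lives in the
midline and the endplates, not the boxes. All intensities stay in [0, 1]
internally; quantization to 8/16 bits happens only at file write.
Identical spec + seed gives bit-identical images and annotations, and with
all jitters at zero the boxes and ground truth are seed-independent.

Ground truth is computed symbolically from the generating coefficients —
differentiation, companion-matrix roots of f″, tangent angles at the
boundaries — with no fitting involved, and uses the same segmentation
conventions as the measurement path so truth and estimate are directly
comparable. `spec_from_angles` constructs curves with *requested* angles
in closed form: a quadratic with boundary slopes ∓tan(A/2) for a single
curve of angle A; for a double curve (A_up, A_low), a cubic whose
derivative is a parabola attaining tangent angle θ₁ = −min(A_up, A_low)/2
at its interior extremum (the inflection) and θ₁ + A_up, θ₁ + A_low at the
span ends — the extremum position and curvature follow from the two end
constraints, and both segment angles equal the request exactly.

`center_jitter_sigma` perturbs the *placed* boxes around the true curve
(emulating detector localization error) while the ground truth stays on
the curve; `spacing_jitter` (default 0) perturbs the uniform vertical
placement.

### What the phantom does and does not emulate

It reproduces the geometry the pipeline consumes — an ordered bright-body
column on a smooth polynomial midline with 0–3 inflections, controllable
blur/noise/contrast — and gives every downstream stage an exact oracle.
It does **not** contain ribs, pedicles, the pelvis, vertebral rotation, 3D
projection effects, or intensity inhomogeneity. Passing phantom tests
therefore validates the measurement mathematics and the detector's
geometric behaviour, not robustness to real anatomical clutter; on
clinical images the detection stage is the component expected to need a
learned replacement (the interface accepts external boxes for exactly this
reason).

## Evaluation statistics

The comparison module mirrors the standard agreement analysis for paired
manual/automated designs: per-column average/min/max, summary-level and
signed per-case differences, and a paired two-tailed t-test with the exact
closed-form p from the t distribution (all-zero differences report t = 0,
p = 1). The t-test is the default because the design is paired and the
measurements continuous; a Wilcoxon signed-rank alternative is provided
for heavy-tailed difference distributions.

## Problem sizes and numerical choices

The validation suite uses 100 noise-free random polynomial phantoms
(degrees ≤ 5, amplitude-bounded to keep boxes in frame) for exact
recovery — every angle within 10⁻⁶ degrees of the analytic value — and
200 seventeen-vertebra phantoms with angles uniform in [15°, 50°] and
2-px center jitter for noisy recovery, where ≥ 95% of estimates land
within 3° of truth (observed ≈ 98–99%). Duplicate annotation boxes merge
at IoU > 0.8 (ties to the larger area); sequences need at least 3 boxes;
angles are reported to 0.01° in JSON; overlay rendering and reports are
byte-deterministic for fixed inputs (no timestamps in the report body).

## Known limitations

Vertebral rotation/twisting is not assessed, and heavily overlapping boxes
from twisted vertebrae are only handled by the IoU merge, not by a
de-overlap model. Severity is graded on the maximum angle across regions.
The classifier's thoracolumbar/combined naming follows the implemented
decision tree, not dominant clinical usage, unless `clinical_convention`
is set. DICOM input is out of scope (convert to PNG/TIFF first).
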