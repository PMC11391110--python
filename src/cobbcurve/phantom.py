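"""Synthetic spine phantoms with analytically known Cobb angles.

A phantom is a column of bright quasi-rectangular "vertebral bodies"
whose centers lie on a generating polynomial midline x_true(y), rendered
onto a dark background with controllable Gaussian blur, additive noise
and contrast.  Because the midline is known in closed form, every
downstream quantity — box centers, inflection points, tangent angles,
per-segment Cobb angles, lateral sides — has an exact analytic value, so
the whole measurement pipeline can be verified without clinical images.

Ground-truth Cobb angles come from :func:`analytic_cobb`, which operates
purely on the generating coefficients (differentiation and companion-
matrix root finding, no fitting).  The curve-segmentation conventions
(endpoint-guarded inflections, chord-deviation side sign, apex-fraction
region labels) mirror the measurement modules so that truth and estimate
are directly comparable.

:func:`spec_from_angles` constructs generating curves with *requested*
Cobb angles in closed form: a quadratic whose boundary slopes are
-/+tan(A/2) for a single curve of angle A, and a cubic whose quadratic
derivative attains prescribed tangent angles at the span ends and its
interior extremum (the inflection) for a double curve.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.polynomial import Polynomial
from scipy.ndimage import gaussian_filter

from .cobbmeas import assign_regions
from .detect import VertebraBox

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomSpecError",
    "analytic_cobb",
    "layout_phantom",
    "generate_phantom",
    "write_annotations",
    "spec_from_angles",
    "random_polynomial_spec",
]

#: Maximum generating-polynomial degree.
MAX_DEGREE = 6
#: Inflection roots within this distance (px) of a span endpoint are
#: dropped as boundary-degenerate.
ENDPOINT_GUARD_PX = 0.5


class PhantomSpecError(ValueError):
    """A phantom spec field violates its invariants."""


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic spine.

    ``curve_coefficients`` are c_0..c_d of the midline x_true(y) in raw
    pixel coordinates (y downward).  Intensities are in [0, 1];
    quantization happens only at file write.  ``tilts`` optionally rotates
    individual rendered vertebra rectangles (degrees, positive = right
    side lower); annotation boxes stay axis-aligned.  ``center_jitter_sigma``
    perturbs the placed box centers around the true curve, emulating
    detector localization error; the ground truth is unaffected.
    """

    curve_coefficients: Sequence[float] = (450.0,)
    n_vertebrae: int = 12
    vertebra_size: Tuple[float, float] = (110.0, 70.0)
    spacing: float = 30.0
    image_size: Tuple[int, int] = (900, 1900)
    noise_sigma: float = 0.0
    blur_sigma: float = 1.0
    foreground: float = 0.8
    background: float = 0.2
    seed: int = 0
    spacing_jitter: float = 0.0
    center_jitter_sigma: float = 0.0
    tilts: Optional[Sequence[float]] = None

    def validate(self) -> None:
        if self.n_vertebrae < 3:
            raise PhantomSpecError(f"n_vertebrae must be >= 3, got {self.n_vertebrae}")
        if len(self.curve_coefficients) - 1 > MAX_DEGREE:
            raise PhantomSpecError(
                f"curve_coefficients: degree {len(self.curve_coefficients) - 1} "
                f"exceeds the maximum {MAX_DEGREE}"
            )
        if self.noise_sigma < 0:
            raise PhantomSpecError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.blur_sigma < 0:
            raise PhantomSpecError(f"blur_sigma must be >= 0, got {self.blur_sigma}")
        for name in ("foreground", "background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PhantomSpecError(f"{name} must be in [0, 1], got {v}")
        w, h = self.vertebra_size
        if w <= 0 or h <= 0:
            raise PhantomSpecError(f"vertebra_size must be positive, got {self.vertebra_size}")
        W, H = self.image_size
        col_h = self.n_vertebrae * h + (self.n_vertebrae - 1) * self.spacing
        if col_h > H:
            raise PhantomSpecError(
                f"n_vertebrae/vertebra_size/spacing: column height {col_h:.0f} px "
                f"exceeds image height {H}"
            )
        ys = self._center_ys()
        xs = self.curve(ys)
        if np.any(xs - w / 2 < 0) or np.any(xs + w / 2 > W):
            raise PhantomSpecError(
                "curve_coefficients: vertebra boxes extend outside image bounds "
                f"(x range [{xs.min() - w / 2:.1f}, {xs.max() + w / 2:.1f}] vs width {W})"
            )
        if self.tilts is not None and len(self.tilts) != self.n_vertebrae:
            raise PhantomSpecError("tilts must have one entry per vertebra")

    @property
    def polynomial(self) -> Polynomial:
        return Polynomial(np.asarray(self.curve_coefficients, dtype=float))

    def curve(self, y):
        return self.polynomial(np.asarray(y, dtype=float))

    def _center_ys(self) -> np.ndarray:
        w, h = self.vertebra_size
        col_h = self.n_vertebrae * h + (self.n_vertebrae - 1) * self.spacing
        y0 = (self.image_size[1] - col_h) / 2 + h / 2
        return y0 + np.arange(self.n_vertebrae) * (h + self.spacing)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["curve_coefficients"] = [float(c) for c in self.curve_coefficients]
        if self.tilts is not None:
            d["tilts"] = [float(t) for t in self.tilts]
        return d


@dataclass
class GroundTruth:
    """Analytic ground truth of a phantom.

    ``segment_angles`` holds one (region, angle_deg, side) triple per
    inflection-bounded span of the generating curve, computed by
    differentiation alone.  ``box_centers`` are the exact on-curve
    centers (unjittered)."""

    inflection_ys: List[float]
    segment_angles: List[Tuple[str, float, int]]
    box_centers: List[Tuple[float, float]]

    @property
    def max_angle(self) -> float:
        return max(a for _, a, _ in self.segment_angles)

    def to_dict(self) -> dict:
        return {
            "inflection_ys": [float(y) for y in self.inflection_ys],
            "segment_angles": [
                {"region": r, "angle_deg": float(a), "side": int(s)}
                for r, a, s in self.segment_angles
            ],
            "box_centers": [[float(x), float(y)] for x, y in self.box_centers],
        }


def _real_roots_in(poly: Polynomial, lo: float, hi: float, guard: float) -> List[float]:
    """Real roots of poly strictly inside (lo+guard, hi-guard), via the
    companion matrix on a [-1,1]-rescaled basis for conditioning."""
    coefs = np.trim_zeros(poly.coef, "b")
    if len(coefs) <= 1:
        return []
    scaled = Polynomial(poly.coef).convert(domain=[lo, hi], window=[-1, 1], kind=Polynomial)
    roots = scaled.roots()
    out = [
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 and lo + guard < r.real < hi - guard
    ]
    return sorted(out)


def analytic_cobb(
    curve_coefficients: Sequence[float], y_span: Tuple[float, float]
) -> GroundTruth:
    """Exact Cobb-angle ground truth for a polynomial midline over a span.

    Inflections are the real roots of the second derivative inside the
    span (roots within 0.5 px of an endpoint dropped); each consecutive
    boundary pair forms a segment whose Cobb angle is
    |atan f'(y_i) - atan f'(y_{i+1})| in degrees.  Sides use the chord-
    deviation rule at the segment apex; regions use the apex-fraction
    rule.  Degree 0 yields a single 0-degree segment.
    """
    y_top, y_bot = float(y_span[0]), float(y_span[1])
    if y_top >= y_bot:
        raise ValueError("y_span must be non-degenerate (y_top < y_bottom)")
    p = Polynomial(np.asarray(curve_coefficients, dtype=float))
    d1, d2 = p.deriv(1), p.deriv(2)
    inflections = _real_roots_in(d2, y_top, y_bot, ENDPOINT_GUARD_PX)
    boundaries = [y_top] + inflections + [y_bot]
    x_top, x_bot = p(y_top), p(y_bot)

    def chord(y):
        t = (y - y_top) / (y_bot - y_top)
        return x_top + t * (x_bot - x_top)

    segs = []
    fracs = []
    span = abs(float(x_bot) - float(x_top)) + abs(float(x_top)) + 1.0
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        angle = float(abs(np.degrees(np.arctan(d1(a)) - np.arctan(d1(b)))))
        apex_candidates = _real_roots_in(d1, a, b, 0.0)
        if apex_candidates:
            apex = apex_candidates[0]
        else:
            apex = a if abs(d1(a)) <= abs(d1(b)) else b
        dev = float(p(apex) - chord(apex))
        if abs(dev) < 1e-9 * span:
            # degenerate apex deviation: use the maximal chord deviation
            grid = np.linspace(a, b, 65)
            devs = p(grid) - chord(grid)
            dev = float(devs[np.argmax(np.abs(devs))])
        side = 1 if dev >= 0 else -1
        segs.append((angle, side, apex))
        fracs.append((apex - y_top) / (y_bot - y_top))
    regions = assign_regions(fracs)
    return GroundTruth(
        inflection_ys=inflections,
        segment_angles=[(r, a, s) for r, (a, s, _) in zip(regions, segs)],
        box_centers=[],
    )


def layout_phantom(
    spec: PhantomSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[List[VertebraBox], GroundTruth]:
    """Place the vertebra boxes and compute the analytic ground truth,
    without rendering an image."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ys = spec._center_ys()
    if spec.spacing_jitter > 0:
        ys = ys + rng.normal(0.0, spec.spacing_jitter, size=ys.shape)
        ys = np.sort(ys)
    xs = spec.curve(ys)
    truth = analytic_cobb(spec.curve_coefficients, (float(ys[0]), float(ys[-1])))
    truth.box_centers = [(float(x), float(y)) for x, y in zip(xs, ys)]
    if spec.center_jitter_sigma > 0:
        xs = xs + rng.normal(0.0, spec.center_jitter_sigma, size=xs.shape)
        yj = ys + rng.normal(0.0, spec.center_jitter_sigma, size=ys.shape)
        ys = np.sort(yj)
    w, h = spec.vertebra_size
    boxes = [
        VertebraBox(
            index=i,
            x_min=float(x - w / 2),
            y_min=float(y - h / 2),
            x_max=float(x + w / 2),
            y_max=float(y + h / 2),
        )
        for i, (x, y) in enumerate(zip(xs, ys))
    ]
    return boxes, truth


def _rect_corners(cx, cy, w, h, tilt_deg):
    t = np.deg2rad(tilt_deg)
    c, s = np.cos(t), np.sin(t)
    out = []
    for dx, dy in ((-w / 2, -h / 2), (w / 2, -h / 2), (w / 2, h / 2), (-w / 2, h / 2)):
        out.append((cx + dx * c - dy * s, cy + dx * s + dy * c))
    return out


def generate_phantom(
    spec: PhantomSpec,
) -> Tuple[np.ndarray, List[VertebraBox], GroundTruth]:
    """Render the phantom image and return (image, boxes, truth).

    The image is a (H, W) float array in [0, 1]: one bright (possibly
    tilted) rectangle per vertebra on the background level, Gaussian-
    blurred, with additive Gaussian noise.  Identical spec + seed give
    bit-identical outputs; with jitters at 0 the boxes and truth do not
    depend on the seed at all.
    """
    from skimage.draw import polygon  # local: keeps import cost off the fast path

    rng = np.random.default_rng(spec.seed)
    boxes, truth = layout_phantom(spec, rng)
    W, H = spec.image_size
    img = np.full((H, W), spec.background, dtype=float)
    w, h = spec.vertebra_size
    for i, b in enumerate(boxes):
        tilt = float(spec.tilts[i]) if spec.tilts is not None else 0.0
        cx, cy = b.center
        if tilt == 0.0:
            # exact partial-pixel coverage: keeps the rendered centroid
            # free of pixel-quantization bias
            # pixel j spans [j - 0.5, j + 0.5] (pixel-center convention,
            # matching regionprops centroids)
            cols = np.clip(
                np.minimum(b.x_max, np.arange(W) + 0.5)
                - np.maximum(b.x_min, np.arange(W) - 0.5),
                0.0, 1.0,
            )
            rows = np.clip(
                np.minimum(b.y_max, np.arange(H) + 0.5)
                - np.maximum(b.y_min, np.arange(H) - 0.5),
                0.0, 1.0,
            )
            cover = np.outer(rows, cols)
            img = np.maximum(img, spec.background + (spec.foreground - spec.background) * cover)
        else:
            corners = _rect_corners(cx, cy, w, h, tilt)
            rr, cc = polygon(
                [p[1] for p in corners], [p[0] for p in corners], shape=img.shape
            )
            img[rr, cc] = spec.foreground
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0), boxes, truth


def write_annotations(
    boxes: Sequence[VertebraBox], path, format: str = "json", image_size=(900, 1900)
) -> None:
    """Write boxes as JSON, CSV, or YOLO-style normalized label lines.

    Round-trips losslessly with ``detect.read_boxes`` for JSON/CSV and to
    the printed 6-decimal precision for YOLO.
    """
    boxes = list(boxes)
    if not boxes:
        raise ValueError("cannot write an empty box list")
    if format == "json":
        payload = {
            "image_size": [int(image_size[0]), int(image_size[1])],
            "boxes": [b.to_dict() for b in boxes],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["index", "x_min", "y_min", "x_max", "y_max", "confidence"])
            for b in boxes:
                writer.writerow(
                    [b.index, repr(b.x_min), repr(b.y_min), repr(b.x_max), repr(b.y_max), b.confidence]
                )
    elif format == "yolo":
        W, H = image_size
        with open(path, "w") as fh:
            for b in boxes:
                cx = 0.5 * (b.x_min + b.x_max) / W
                cy = 0.5 * (b.y_min + b.y_max) / H
                fh.write(
                    f"0 {cx:.6f} {cy:.6f} {(b.x_max - b.x_min) / W:.6f} "
                    f"{(b.y_max - b.y_min) / H:.6f}\n"
                )
    else:
        raise ValueError(f"unknown annotation format {format!r}; supported: json, csv, yolo")


def spec_from_angles(
    n_curves: int,
    angle_up: float = 0.0,
    angle_low: float = 0.0,
    **spec_kwargs,
) -> PhantomSpec:
    """Construct a phantom whose ground-truth Cobb angles equal the
    requested values exactly.

    ``n_curves`` 0 -> straight spine (all angles 0);  1 -> a single
    C-curve of ``angle_up`` degrees from a quadratic midline whose
    boundary slopes are -/+tan(angle_up / 2);  2 -> an S-shaped double
    curve (``angle_up`` superior, ``angle_low`` inferior) from a cubic
    whose derivative is a parabola attaining prescribed tangent angles at
    the span ends and at its interior minimum, which is the inflection.
    Remaining keyword arguments pass through to :class:`PhantomSpec`.
    """
    base = PhantomSpec(**spec_kwargs)
    ys = base._center_ys()
    y_top, y_bot = float(ys[0]), float(ys[-1])
    W = base.image_size[0]
    if n_curves == 0:
        coefs = [W / 2.0]
    elif n_curves == 1:
        if not (0 < angle_up < 178):
            raise ValueError("angle_up must be in (0, 178) degrees")
        s = np.tan(np.radians(angle_up / 2.0))
        L = y_bot - y_top
        ym = 0.5 * (y_top + y_bot)
        # f(y) = (s/L)(y - ym)^2 + C, boundary slopes -/+ s
        p = Polynomial([(-ym), 1.0]) ** 2 * (s / L)
        grid = np.linspace(y_top, y_bot, 64)
        vals = p(grid)
        p = p + (W / 2.0 - 0.5 * (vals.min() + vals.max()))
        coefs = p.coef
    elif n_curves == 2:
        if not (0 < angle_up < 90 and 0 < angle_low < 90):
            raise ValueError("angles must be in (0, 90) degrees for a double curve")
        th1 = -np.radians(min(angle_up, angle_low)) / 2.0  # tangent at the inflection
        th0 = th1 + np.radians(angle_up)
        th2 = th1 + np.radians(angle_low)
        v1 = np.tan(th1)
        r = (np.tan(th0) - v1) / (np.tan(th2) - v1)
        sr = np.sqrt(r)
        y_star = (y_top + sr * y_bot) / (1.0 + sr)
        alpha = (np.tan(th0) - v1) / (y_top - y_star) ** 2
        dy = Polynomial([-y_star, 1.0])
        p = dy**3 * (alpha / 3.0) + dy * v1
        grid = np.linspace(y_top, y_bot, 128)
        vals = p(grid)
        p = p + (W / 2.0 - 0.5 * (vals.min() + vals.max()))
        coefs = p.coef
    else:
        raise ValueError("n_curves must be 0, 1 or 2")
    spec = PhantomSpec(**{**spec_kwargs, "curve_coefficients": [float(c) for c in coefs]})
    spec.validate()
    return spec


def random_polynomial_spec(
    rng: np.random.Generator,
    degree: Optional[int] = None,
    max_amplitude_frac: float = 0.18,
    **spec_kwargs,
) -> PhantomSpec:
    """Random polynomial phantom with a bounded lateral amplitude.

    Coefficients are drawn in a [-1, 1]-rescaled basis over the vertebral
    span, then the lateral deviation is normalized to a random amplitude
    (up to ``max_amplitude_frac`` of the image width) about the image
    center, which keeps every box inside the frame.
    """
    base = PhantomSpec(**spec_kwargs)
    ys = base._center_ys()
    y_top, y_bot = float(ys[0]), float(ys[-1])
    W = base.image_size[0]
    if degree is None:
        degree = int(rng.integers(1, 6))
    raw = Polynomial(
        rng.normal(0.0, 1.0, size=degree + 1), domain=[y_top, y_bot], window=[-1, 1]
    )
    grid = np.linspace(y_top, y_bot, 256)
    vals = raw(grid)
    dev = vals - vals.mean()
    peak = np.abs(dev).max()
    amp = rng.uniform(0.3, 1.0) * max_amplitude_frac * W
    scale = amp / peak if peak > 1e-12 else 0.0
    p = (raw - vals.mean()) * scale + W / 2.0
    coefs = p.convert().coef
    coefs = np.pad(coefs, (0, degree + 1 - len(coefs)))
    spec = PhantomSpec(**{**spec_kwargs, "curve_coefficients": [float(c) for c in coefs]})
    spec.validate()
    return spec
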