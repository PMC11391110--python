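"""Cobb-angle measurement from the fitted midline.

The Cobb angle of a curve segment is the angle between the tangents to the
spinal midline at the segment's two boundaries.  Because the angle between
two lines equals the angle between their perpendiculars, this tangent-line
formulation coincides with the classical endplate construction (the angle
between the superior endplate of the uppermost involved vertebra and the
inferior endplate of the lowest).  The tangent's deviation from the
vertical image axis at height y is atan(f'(y)); a segment's Cobb angle is
the absolute difference of its two boundary tangent angles.

Region labels (thoracic/lumbar) are assigned by the apex position's
vertebra-rank fraction, since the pipeline carries no anatomical labels:
an apex in the superior half of the column is thoracic, inferior half
lumbar; with exactly two segments the superior one is thoracic and the
inferior one lumbar.

:func:`cobb_from_endplates` provides the endplate-tilt construction as an
independent cross-check when Hough-refined endplates are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image, ImageDraw

from . import midline as ml
from .detect import VertebraSequence
from .imageprep import as_standard_image

logger = logging.getLogger(__name__)

__all__ = [
    "CobbMeasurement",
    "tangent_angle",
    "cobb_angle",
    "select_end_vertebrae",
    "assign_regions",
    "measure_spine",
    "cobb_from_endplates",
    "render_overlay",
]


@dataclass
class CobbMeasurement:
    """One Cobb angle with its end vertebrae and anatomical region."""

    angle_deg: float
    region: str
    upper_vertebra_index: int
    lower_vertebra_index: int
    y_upper: float
    y_lower: float
    side: int
    method: str = "midline_tangent"

    def __post_init__(self):
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValueError(f"Cobb angle out of range: {self.angle_deg}")
        if self.y_upper >= self.y_lower:
            raise ValueError("y_upper must be above (smaller than) y_lower")

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "angle_deg": round(float(self.angle_deg), 2),
            "upper_vertebra": int(self.upper_vertebra_index),
            "lower_vertebra": int(self.lower_vertebra_index),
            "y_upper": round(float(self.y_upper), 2),
            "y_lower": round(float(self.y_lower), 2),
            "side": int(self.side),
            "method": self.method,
        }


def tangent_angle(model: ml.MidlineModel, y: float) -> float:
    """Tangent deviation from the vertical image axis at height y, in
    degrees, range (-90, 90)."""
    return float(np.degrees(np.arctan(ml.evaluate(model, y, order=1))))


def cobb_angle(model: ml.MidlineModel, y_upper: float, y_lower: float) -> float:
    """|tangent_angle(y_upper) - tangent_angle(y_lower)| in degrees.

    ``y_upper`` must lie above ``y_lower`` (smaller y); a swapped pair is
    a contract violation, not a negated angle.
    """
    if y_upper >= y_lower:
        raise ValueError(f"y_upper ({y_upper}) must be < y_lower ({y_lower})")
    return abs(tangent_angle(model, y_upper) - tangent_angle(model, y_lower))


def select_end_vertebrae(
    segment, sequence: VertebraSequence
) -> Tuple[int, int]:
    """End vertebrae of a segment: nearest box centers to the segment
    boundaries, distance ties broken toward the segment interior."""
    ys = np.array([b.center[1] for b in sequence.boxes])
    y_start, y_end = (
        (segment.y_start, segment.y_end)
        if hasattr(segment, "y_start")
        else (segment[0], segment[1])
    )

    def nearest(y: float, prefer_larger: bool) -> int:
        d = np.abs(ys - y)
        best = np.flatnonzero(d == d.min())
        return int(best.max() if prefer_larger else best.min())

    upper = nearest(y_start, prefer_larger=True)
    lower = nearest(y_end, prefer_larger=False)
    if lower <= upper:  # degenerate sliver of a segment
        lower = min(upper + 1, len(ys) - 1)
        if lower == upper:
            upper = max(0, lower - 1)
    return upper, lower


def assign_regions(apex_fracs: Sequence[float]) -> List[str]:
    """Thoracic/lumbar labels from apex position fractions in [0, 1]
    (0 = most superior).  One segment: thoracic iff fraction < 0.5.  Two
    segments: the smaller fraction is thoracic, the larger lumbar.  More:
    each labeled by the 0.5 threshold."""
    n = len(apex_fracs)
    if n == 1:
        return ["thoracic" if apex_fracs[0] < 0.5 else "lumbar"]
    if n == 2:
        i = int(np.argmin(apex_fracs))
        out = ["lumbar", "lumbar"]
        out[i] = "thoracic"
        return out
    return ["thoracic" if f < 0.5 else "lumbar" for f in apex_fracs]


def measure_spine(
    model: ml.MidlineModel,
    sequence: VertebraSequence,
    tangent_at: str = "boundary",
) -> List[CobbMeasurement]:
    """One Cobb measurement per inflection-bounded midline segment,
    ordered superior -> inferior.

    ``tangent_at`` selects where boundary tangents are evaluated:
    ``boundary`` uses the segment boundaries themselves (domain endpoints
    and inflection points); ``vertebra`` uses the center heights of the
    selected end vertebrae.
    """
    if tangent_at not in ("boundary", "vertebra"):
        raise ValueError("tangent_at must be 'boundary' or 'vertebra'")
    segments = ml.segment_spine(model)
    ys = np.array([b.center[1] for b in sequence.boxes])
    n = len(ys)
    lo, hi = model.domain
    apex_fracs = []
    for seg in segments:
        rank = int(np.argmin(np.abs(ys - seg.apex_y)))
        apex_fracs.append(rank / (n - 1) if n > 1 else 0.5)
    regions = assign_regions(apex_fracs)
    out = []
    for seg, region in zip(segments, regions):
        upper, lower = select_end_vertebrae(seg, sequence)
        if tangent_at == "vertebra":
            yu = float(np.clip(ys[upper], lo, hi))
            yl = float(np.clip(ys[lower], lo, hi))
            if yu >= yl:
                yu, yl = seg.y_start, seg.y_end
        else:
            yu, yl = seg.y_start, seg.y_end
        out.append(
            CobbMeasurement(
                angle_deg=cobb_angle(model, yu, yl),
                region=region,
                upper_vertebra_index=upper,
                lower_vertebra_index=lower,
                y_upper=yu,
                y_lower=yl,
                side=seg.side,
            )
        )
    return out


def cobb_from_endplates(
    sequence: VertebraSequence, upper_index: int, lower_index: int
) -> float:
    """Classical endplate construction: |upper vertebra's upper-endplate
    tilt - lower vertebra's lower-endplate tilt| in degrees.  Requires
    Hough-refined endplate tilts on both vertebrae."""
    bu = sequence.boxes[upper_index]
    bl = sequence.boxes[lower_index]
    if (
        bu.endplate_tilts is None
        or bl.endplate_tilts is None
        or bu.endplate_tilts[0] is None
        or bl.endplate_tilts[1] is None
    ):
        raise ValueError(
            "endplates unavailable: run refine_endplates_hough on the sequence first"
        )
    return abs(bu.endplate_tilts[0] - bl.endplate_tilts[1])


def render_overlay(
    image,
    model: Optional[ml.MidlineModel],
    sequence: Optional[VertebraSequence],
    measurements: Sequence[CobbMeasurement],
    path,
    tangent_half_length: float = 150.0,
) -> None:
    """Write an annotated PNG: green vertebra boxes, red midline polyline
    (sampled every pixel of height), red tangent lines at each
    measurement boundary extended +/-150 px, and angle labels.  Output
    bytes are deterministic for fixed inputs."""
    px = as_standard_image(image).pixels
    rgb = Image.fromarray(
        (np.clip(px, 0, 1) * 255).round().astype(np.uint8)
    ).convert("RGB")
    draw = ImageDraw.Draw(rgb)
    green, red = (0, 200, 0), (230, 30, 30)
    if sequence is not None:
        for b in sequence.boxes:
            draw.rectangle([b.x_min, b.y_min, b.x_max, b.y_max], outline=green, width=2)
    if model is not None:
        lo, hi = model.domain
        ys = np.linspace(lo, hi, max(int(np.ceil(hi - lo)) + 1, 2))
        xs = ml.evaluate(model, ys, order=0)
        draw.line([(float(x), float(y)) for x, y in zip(xs, ys)], fill=red, width=2)
        for m in measurements:
            for y in (m.y_upper, m.y_lower):
                slope = ml.evaluate(model, y, order=1)  # dx/dy
                x0 = ml.evaluate(model, y, order=0)
                t = np.array([slope, 1.0])
                t /= np.linalg.norm(t)
                p0 = (x0 - tangent_half_length * t[0], y - tangent_half_length * t[1])
                p1 = (x0 + tangent_half_length * t[0], y + tangent_half_length * t[1])
                draw.line([p0, p1], fill=red, width=2)
            label_y = 0.5 * (m.y_upper + m.y_lower)
            label_x = ml.evaluate(model, float(np.clip(label_y, lo, hi)), order=0)
            draw.text(
                (float(label_x) + 12, float(label_y)),
                f"{m.region} {m.angle_deg:.2f} deg",
                fill=red,
            )
    rgb.save(path, format="PNG")
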