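"""Vertebra bounding boxes: annotation I/O and a classical detector.

Two routes produce the ordered superior->inferior box sequence the midline
fit consumes:

* :func:`read_boxes` ingests annotation files (JSON, CSV, or normalized
  YOLO-style label lines), the route used when boxes come from a human
  annotator or an external learned detector;
* :func:`detect_classical` finds bright quasi-rectangular vertebral bodies
  by global thresholding, morphological opening, connected-component
  filtering and a lateral-outlier guard.

:func:`refine_endplates_hough` optionally measures the tilt of the upper
and lower endplate of each box with a straight-line Hough transform on the
local edge map, enabling the classical endplate-based Cobb construction as
a cross-check on the midline-tangent method.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, transform

from .imageprep import as_standard_image

logger = logging.getLogger(__name__)

__all__ = [
    "VertebraBox",
    "VertebraSequence",
    "InsufficientVertebraeError",
    "AnnotationParseError",
    "read_boxes",
    "detect_classical",
    "refine_endplates_hough",
    "centers",
]

#: Minimum number of boxes required for downstream midline fitting.
MIN_VERTEBRAE = 3
#: IoU above which two boxes are considered duplicates and merged.
IOU_MERGE_THRESHOLD = 0.8
#: Default lateral outlier-guard distance (px) at the 900x1900 frame.
OUTLIER_GUARD_PX = 60.0
#: Aspect-ratio (width/height) gate for connected components.
ASPECT_RANGE = (0.8, 4.0)


class InsufficientVertebraeError(ValueError):
    """Fewer vertebrae than the midline fit needs."""


class AnnotationParseError(ValueError):
    """Malformed annotation file."""


@dataclass
class VertebraBox:
    """One vertebral body box in 0-based half-open pixel coordinates,
    y increasing downward (superior -> inferior)."""

    index: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    center: Tuple[float, float] = None
    endplate_tilts: Optional[Tuple[float, float]] = None
    confidence: float = 1.0

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box #{self.index}: "
                f"({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if self.center is None:
            self.center = (
                0.5 * (self.x_min + self.x_max),
                0.5 * (self.y_min + self.y_max),
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def iou(self, other: "VertebraBox") -> float:
        ix = max(0.0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0.0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def to_dict(self) -> dict:
        d = {
            "index": int(self.index),
            "x_min": float(self.x_min),
            "y_min": float(self.y_min),
            "x_max": float(self.x_max),
            "y_max": float(self.y_max),
            "center": [float(self.center[0]), float(self.center[1])],
            "confidence": float(self.confidence),
        }
        if self.endplate_tilts is not None:
            d["endplate_tilts"] = [float(t) for t in self.endplate_tilts]
        return d


@dataclass
class VertebraSequence:
    """Ordered vertebra boxes for one image."""

    boxes: List[VertebraBox]
    image_size: Tuple[int, int]
    source: str = "annotation"

    def __post_init__(self):
        ys = [b.center[1] for b in self.boxes]
        if any(b <= a for a, b in zip(ys, ys[1:])):
            raise ValueError("box centers must be strictly increasing in y")

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)


def _merge_duplicates(boxes: List[VertebraBox]) -> List[VertebraBox]:
    """Greedy IoU > 0.8 merge keeping the higher-confidence box; ties go
    to the larger area."""
    kept: List[VertebraBox] = []
    for b in sorted(boxes, key=lambda b: (-b.confidence, -b.area)):
        if all(b.iou(k) <= IOU_MERGE_THRESHOLD for k in kept):
            kept.append(b)
    return kept


def _finalize(boxes: List[VertebraBox], image_size, source: str) -> VertebraSequence:
    boxes = _merge_duplicates(boxes)
    boxes.sort(key=lambda b: b.center[1])
    for i, b in enumerate(boxes):
        b.index = i
    if len(boxes) < MIN_VERTEBRAE:
        raise InsufficientVertebraeError(
            f"insufficient vertebrae: found {len(boxes)}, need >= {MIN_VERTEBRAE}"
        )
    return VertebraSequence(boxes=boxes, image_size=tuple(image_size), source=source)


def read_boxes(path, format: str = "json", image_size=None) -> VertebraSequence:
    """Read vertebra boxes from an annotation file.

    Formats: ``json`` (records with x_min/y_min/x_max/y_max plus the image
    size), ``csv`` (columns index,x_min,y_min,x_max,y_max[,confidence]),
    ``yolo`` (lines ``cls cx cy w h`` normalized to [0, 1]; requires
    ``image_size`` to denormalize).  Boxes are sorted by center y and
    near-duplicates (IoU > 0.8) merged.
    """
    boxes: List[VertebraBox] = []
    if format == "json":
        with open(path) as fh:
            data = json.load(fh)
        image_size = tuple(data.get("image_size") or image_size or (0, 0))
        for rec in data["boxes"]:
            boxes.append(
                VertebraBox(
                    index=int(rec.get("index", len(boxes))),
                    x_min=float(rec["x_min"]),
                    y_min=float(rec["y_min"]),
                    x_max=float(rec["x_max"]),
                    y_max=float(rec["y_max"]),
                    confidence=float(rec.get("confidence", 1.0)),
                )
            )
    elif format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                try:
                    boxes.append(
                        VertebraBox(
                            index=int(row.get("index", len(boxes))),
                            x_min=float(row["x_min"]),
                            y_min=float(row["y_min"]),
                            x_max=float(row["x_max"]),
                            y_max=float(row["y_max"]),
                            confidence=float(row.get("confidence") or 1.0),
                        )
                    )
                except (KeyError, TypeError, ValueError) as exc:
                    raise AnnotationParseError(
                        f"{path}: malformed CSV row at line {lineno}: {exc}"
                    ) from exc
        if image_size is None:
            image_size = (0, 0)
    elif format == "yolo":
        if image_size is None:
            raise ValueError("YOLO labels are normalized; image_size is required")
        W, H = image_size
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) not in (5, 6):
                    raise AnnotationParseError(
                        f"{path}: malformed YOLO line {lineno}: {line!r}"
                    )
                try:
                    cx, cy, w, h = (float(v) for v in parts[1:5])
                    conf = float(parts[5]) if len(parts) == 6 else 1.0
                except ValueError as exc:
                    raise AnnotationParseError(
                        f"{path}: malformed YOLO line {lineno}: {line!r}"
                    ) from exc
                boxes.append(
                    VertebraBox(
                        index=len(boxes),
                        x_min=(cx - w / 2) * W,
                        y_min=(cy - h / 2) * H,
                        x_max=(cx + w / 2) * W,
                        y_max=(cy + h / 2) * H,
                        confidence=conf,
                    )
                )
    else:
        raise ValueError(f"unknown annotation format {format!r}; supported: json, csv, yolo")
    return _finalize(boxes, image_size, source="annotation")


def detect_classical(
    image,
    threshold: Optional[float] = None,
    min_area: Optional[float] = None,
    max_area: Optional[float] = None,
    outlier_guard: float = OUTLIER_GUARD_PX,
) -> VertebraSequence:
    """Detect bright vertebral bodies by threshold + connected components.

    Pipeline: global Otsu threshold (or user ``threshold``), 3x3
    morphological opening, connected-component labelling, an area gate
    (defaults: [0.25, 4] x the median component area) and an aspect-ratio
    gate (width/height in [0.8, 4.0]), a vertical sort, and a lateral
    outlier guard rejecting components whose centroid x deviates more than
    ``outlier_guard`` px from the running median of their neighbours.
    """
    img = as_standard_image(image)
    px = img.pixels
    if px.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        if np.ptp(px) < 1e-12:
            raise InsufficientVertebraeError("insufficient vertebrae: uniform image")
        threshold = float(filters.threshold_otsu(px))
    mask = px > threshold
    mask = morphology.opening(mask, footprint=np.ones((3, 3), dtype=bool))
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    if not props:
        raise InsufficientVertebraeError("insufficient vertebrae: no components found")
    # excess-intensity-weighted centroids: unbiased for blurred bodies,
    # unlike binary-mask centroids which quantize at the pixel grid
    excess = np.clip(px - threshold, 0.0, None)
    com = ndi.center_of_mass(excess, labels, [p.label for p in props])
    weighted = {p.label: c for p, c in zip(props, com)}
    areas = np.array([p.area for p in props], dtype=float)
    # area-weighted median (area of the component holding the median
    # foreground pixel): robust when small noise specks outnumber the
    # vertebral bodies
    order = np.argsort(areas)
    cum = np.cumsum(areas[order])
    med = float(areas[order][np.searchsorted(cum, cum[-1] / 2.0)])
    lo_area = min_area if min_area is not None else 0.25 * med
    hi_area = max_area if max_area is not None else 4.0 * med
    cands = []
    for p in props:
        if not (lo_area <= p.area <= hi_area):
            continue
        minr, minc, maxr, maxc = p.bbox
        w, h = maxc - minc, maxr - minr
        if h == 0 or not (ASPECT_RANGE[0] <= w / h <= ASPECT_RANGE[1]):
            continue
        cands.append(p)
    cands.sort(key=lambda p: weighted[p.label][0])
    xs = np.array([weighted[p.label][1] for p in cands])
    keep = []
    for i, p in enumerate(cands):
        nbr = [xs[j] for j in range(max(0, i - 2), min(len(cands), i + 3)) if j != i]
        if nbr and abs(xs[i] - np.median(nbr)) > outlier_guard:
            logger.warning("dropping lateral outlier component at y=%.1f", weighted[p.label][0])
            continue
        keep.append(p)
    boxes = []
    for p in keep:
        minr, minc, maxr, maxc = p.bbox
        boxes.append(
            VertebraBox(
                index=len(boxes),
                x_min=float(minc),
                y_min=float(minr),
                x_max=float(maxc),
                y_max=float(maxr),
                center=(float(weighted[p.label][1]), float(weighted[p.label][0])),
            )
        )
    h, w = px.shape
    return _finalize(boxes, (w, h), source="classical")


def _strongest_line(edges: np.ndarray, max_tilt_deg: float = 30.0):
    """Strongest near-horizontal Hough line in an edge map; returns
    (tilt_deg, rho, theta) or None.  Tilt is degrees from horizontal,
    positive when the right side sits lower on the image (larger y)."""
    if not edges.any():
        return None
    # theta is the line-normal angle; near-horizontal lines have normals
    # near +/-90 deg.  1 deg resolution over horizontal +/- max_tilt.
    theta = np.deg2rad(np.arange(-90.0 - max_tilt_deg, -90.0 + max_tilt_deg + 0.5, 1.0))
    h_space, angles, dists = transform.hough_line(edges, theta=theta)
    peaks = transform.hough_line_peaks(h_space, angles, dists, num_peaks=1)
    if len(peaks[0]) == 0:
        return None
    _, ang, rho = peaks[0][0], peaks[1][0], peaks[2][0]
    tilt = np.rad2deg(ang) + 90.0
    return float(tilt), float(rho), float(ang)


def refine_endplates_hough(
    image,
    sequence: VertebraSequence,
    gradient_percentile: float = 90.0,
    max_tilt_deg: float = 30.0,
) -> VertebraSequence:
    """Measure upper/lower endplate tilts of each box with a line Hough
    transform on the local gradient-magnitude edge map.

    The search window is the box padded vertically by half its height;
    the strongest near-horizontal line in the upper/lower half gives the
    endplate tilt in degrees (positive = right side lower).  When both
    endplates are found the box center is recomputed as the midpoint of
    the two line midpoints; when neither peak clears the accumulator
    threshold the box is left unchanged and a warning is logged.
    """
    img = as_standard_image(image)
    px = img.pixels
    H, W = px.shape
    grad = filters.sobel(px)
    for box in sequence.boxes:
        pad = box.height / 2
        r0 = int(np.clip(np.floor(box.y_min - pad), 0, H))
        r1 = int(np.clip(np.ceil(box.y_max + pad), 0, H))
        c0 = int(np.clip(np.floor(box.x_min), 0, W))
        c1 = int(np.clip(np.ceil(box.x_max), 0, W))
        window = grad[r0:r1, c0:c1]
        if window.size == 0 or window.max() < 1e-9:
            logger.warning("box %d: uniform window, endplates left unset", box.index)
            continue
        thr = np.percentile(window, gradient_percentile)
        edges = window >= max(thr, 1e-9)
        mid = window.shape[0] // 2
        found = {}
        for name, sl in (("upper", slice(0, mid)), ("lower", slice(mid, None))):
            half = np.zeros_like(edges)
            half[sl] = edges[sl]
            res = _strongest_line(half, max_tilt_deg)
            if res is not None:
                tilt, rho, ang = res
                xc_local = 0.5 * (box.x_min + box.x_max) - c0
                s = np.sin(ang)
                if abs(s) > 1e-9:
                    y_local = (rho - xc_local * np.cos(ang)) / s
                    found[name] = (tilt, y_local + r0)
        if not found:
            logger.warning("box %d: no endplate line found", box.index)
            continue
        upper = found.get("upper", (None, None))
        lower = found.get("lower", (None, None))
        box.endplate_tilts = (upper[0], lower[0])
        if upper[0] is not None and lower[0] is not None:
            xc = 0.5 * (box.x_min + box.x_max)
            box.center = (xc, 0.5 * (upper[1] + lower[1]))
    return sequence


def centers(sequence: VertebraSequence) -> List[Tuple[float, float]]:
    """Ordered (x, y) centers, one per box; Hough-refined centers are
    already stored on the boxes, so this is a plain projection."""
    return [tuple(b.center) for b in sequence.boxes]
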