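"""Polynomial spinal-midline model.

On an anteroposterior radiograph the spine is quasi-vertical, so the
midline is represented as a single-valued polynomial of the vertical pixel
coordinate:  x = f(y) = a_0 + a_1 y + ... + a_n y^n,  fitted to the
vertebral box centers by ordinary least squares.  For numerical
conditioning the fit runs on y rescaled affinely to [-1, 1]; the exposed
coefficients are converted back to raw pixel coordinates.

Inflection points — the real roots of f'' inside the fitted span — split
the spine into curve segments that bend in alternating directions.  Each
segment carries its apex (where the tangent is vertical, i.e. f' = 0, or
the boundary of smallest |f'| when the tangent never becomes vertical) and
a lateral side sign, defined as the sign of the apex's deviation from the
chord joining the midline's two span endpoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "MidlineModel",
    "CurveSegment",
    "fit_midline",
    "evaluate",
    "find_inflections",
    "segment_spine",
]

#: Maximum supported polynomial degree.
MAX_DEGREE = 6
#: Inflection roots closer than this (px) to a span endpoint are dropped.
ENDPOINT_GUARD_PX = 0.5


@dataclass
class MidlineModel:
    """Fitted polynomial midline x = f(y) with its domain and residuals.

    ``coefficients`` are in raw pixel coordinates (a_0 first); evaluation
    goes through the internally stored well-conditioned representation on
    y mapped to [-1, 1].
    """

    coefficients: np.ndarray
    degree: int
    domain: Tuple[float, float]
    rms_residual: float
    n_points: int
    _poly: Polynomial = field(repr=False, default=None)

    def __post_init__(self):
        if self._poly is None:
            self._poly = Polynomial(
                np.asarray(self.coefficients, dtype=float),
                domain=list(self.domain),
                window=list(self.domain),
            )

    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coefficients],
            "degree": int(self.degree),
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "rms_residual": float(self.rms_residual),
            "n_points": int(self.n_points),
        }


@dataclass
class CurveSegment:
    """One inflection-bounded span of the midline.

    ``side`` is +1/-1 for the lateral direction in which the apex deviates
    from the endpoint chord of the full fitted span (+1 toward larger x,
    i.e. image right).  When the apex sits on the chord (e.g. at a span
    endpoint) the sign of the segment's maximal chord deviation is used;
    an identically-zero deviation resolves to +1 by convention.  Tangent
    angles are degrees from the vertical image axis.
    """

    y_start: float
    y_end: float
    apex_y: float
    side: int
    tangent_start_deg: float
    tangent_end_deg: float


def _auto_degree(x: np.ndarray, y: np.ndarray, alpha: float = 0.01) -> int:
    """Data-driven fit degree by backward elimination of the leading term.

    Starting from min(6, n - 2), the leading coefficient of the LS fit
    (on y rescaled to ~[-1, 1]) is t-tested against zero at level
    ``alpha``; insignificant leading terms are dropped one degree at a
    time.  High degrees inflate the tangent-slope variance exactly where
    Cobb angles are read (the span ends), so capacity must be earned from
    the data.  Exact polynomial centers keep their true degree: spurious
    higher terms come out numerically zero and are dropped, while true
    leading terms have a vanishing standard error.
    """
    from scipy import stats as _stats

    n = len(y)
    t = (y - y.mean()) / (0.5 * np.ptp(y))  # conditioning rescale
    coef_floor = 1e-9 * max(1.0, float(np.abs(x).max()))
    d = min(MAX_DEGREE, n - 2)
    while d > 1:
        dof = n - (d + 1)
        if dof <= 0:
            d -= 1
            continue
        V = np.vander(t, d + 1, increasing=True)
        coef, _, _, _ = np.linalg.lstsq(V, x, rcond=None)
        rss = float(np.sum((x - V @ coef) ** 2))
        if abs(coef[d]) < coef_floor:
            d -= 1
            continue
        se = np.sqrt(max(rss / dof, 1e-18) * np.linalg.inv(V.T @ V)[d, d])
        if abs(coef[d]) / se > _stats.t.ppf(1 - alpha / 2, dof):
            return d
        d -= 1
    return max(d, 1)


def fit_midline(centers: Sequence[Tuple[float, float]], degree="auto") -> MidlineModel:
    """Least-squares fit of lateral position x as a polynomial in y.

    Parameters
    ----------
    centers
        Ordered (x, y) vertebral centers with strictly increasing y.
    degree
        Polynomial degree, 1..6, or ``"auto"`` (default) to select it by
        a leading-coefficient significance test.  An explicit degree is reduced (with a warning) on rank
        deficiency.

    Raises
    ------
    ValueError
        On fewer than ``degree + 1`` centers, non-increasing y, or a
        degree outside 1..6.
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centers must be a sequence of (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(y) <= 0):
        raise ValueError("center y coordinates must be strictly increasing")
    if degree == "auto":
        if len(pts) < 3:
            raise ValueError("insufficient vertebrae: need at least 3 centers")
        degree = _auto_degree(x, y)
    if not (isinstance(degree, (int, np.integer)) and 1 <= degree <= MAX_DEGREE):
        raise ValueError(f"degree must be in 1..{MAX_DEGREE} or 'auto', got {degree!r}")
    if len(pts) < degree + 1:
        raise ValueError(
            f"insufficient vertebrae for degree {degree}: "
            f"need at least {degree + 1} centers, got {len(pts)}"
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", np.exceptions.RankWarning)
        poly = Polynomial.fit(y, x, deg=degree)
        if any(issubclass(w.category, np.exceptions.RankWarning) for w in caught):
            degree = max(1, int(np.linalg.matrix_rank(np.vander(y, degree + 1))) - 1)
            logger.warning("rank-deficient fit; degree lowered to %d", degree)
            poly = Polynomial.fit(y, x, deg=degree)
    resid = x - poly(y)
    rms = float(np.sqrt(np.mean(resid**2)))
    pixel_coefs = poly.convert().coef
    pixel_coefs = np.pad(pixel_coefs, (0, degree + 1 - len(pixel_coefs)))
    model = MidlineModel(
        coefficients=pixel_coefs,
        degree=degree,
        domain=(float(y[0]), float(y[-1])),
        rms_residual=rms,
        n_points=len(pts),
        _poly=poly,
    )
    return model


def _check_domain(model: MidlineModel, y: float) -> None:
    lo, hi = model.domain
    eps = 1e-9 * max(1.0, abs(hi - lo))
    if not (lo - eps <= y <= hi + eps):
        raise ValueError(
            f"y={y} outside the fitted domain [{lo}, {hi}]; extrapolation is rejected"
        )


def evaluate(model: MidlineModel, y, order: int = 0):
    """Evaluate f, f' (dx/dy) or f'' (d2x/dy2) at y, in pixel units.

    The chain rule through the internal [-1, 1] rescale is handled by the
    polynomial's ``deriv``.  y outside the fitted domain raises.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    ys = np.atleast_1d(np.asarray(y, dtype=float))
    for yi in ys:
        _check_domain(model, yi)
    p = model._poly.deriv(order) if order else model._poly
    out = p(ys)
    return float(out[0]) if np.isscalar(y) or np.ndim(y) == 0 else out


def find_inflections(model: MidlineModel, scan_step: float = 1.0) -> List[float]:
    """Real roots of f'' strictly inside the domain, sorted ascending.

    Located by a sign-change scan at ``scan_step`` px resolution followed
    by bisection to 1e-6 px.  Roots within 0.5 px of a domain endpoint are
    dropped as boundary-degenerate.  Degree <= 1 returns an empty list.
    """
    if model.degree <= 1:
        return []
    d2 = model._poly.deriv(2)
    lo, hi = model.domain
    n = max(int(np.ceil((hi - lo) / scan_step)), 2)
    grid = np.linspace(lo, hi, n + 1)
    vals = d2(grid)
    roots: List[float] = []
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            roots.append(float(a))
        elif va * vb < 0:
            roots.append(float(brentq(d2, a, b, xtol=1e-6)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    roots = [r for r in roots if r - lo > ENDPOINT_GUARD_PX and hi - r > ENDPOINT_GUARD_PX]
    return sorted(roots)


def _apex_in_segment(model: MidlineModel, y_start: float, y_end: float) -> float:
    """Root of f' inside the segment if present, else the boundary with
    smaller |f'|."""
    d1 = model._poly.deriv(1)
    n = max(int(np.ceil(y_end - y_start)), 2)
    grid = np.linspace(y_start, y_end, n + 1)
    vals = d1(grid)
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            return float(a)
        if va * vb < 0:
            return float(brentq(d1, a, b, xtol=1e-6))
    if vals[-1] == 0.0:
        return float(grid[-1])
    return float(y_start if abs(vals[0]) <= abs(vals[-1]) else y_end)


def segment_spine(model: MidlineModel) -> List[CurveSegment]:
    """Partition the fitted span into inflection-bounded curve segments.

    Boundaries are the domain endpoints plus the inflection points.  Each
    segment gets its apex, side sign (apex deviation from the full-span
    endpoint chord; exact ties resolve to +1), and boundary tangent
    angles in degrees from vertical.
    """
    lo, hi = model.domain
    boundaries = [lo] + find_inflections(model) + [hi]
    f = model._poly
    x_lo, x_hi = f(lo), f(hi)

    def chord(y: float) -> float:
        if hi == lo:
            return float(x_lo)
        t = (y - lo) / (hi - lo)
        return float(x_lo + t * (x_hi - x_lo))

    d1 = f.deriv(1)
    span = abs(float(x_hi) - float(x_lo)) + abs(float(x_lo)) + 1.0
    segments = []
    for y0, y1 in zip(boundaries[:-1], boundaries[1:]):
        apex = _apex_in_segment(model, y0, y1)
        dev = float(f(apex)) - chord(apex)
        if abs(dev) < 1e-9 * span:
            # apex deviation degenerate (apex at a full-span endpoint):
            # fall back to the segment's maximal chord deviation
            grid = np.linspace(y0, y1, 65)
            devs = f(grid) - np.array([chord(g) for g in grid])
            dev = float(devs[np.argmax(np.abs(devs))])
        side = 1 if dev >= 0 else -1
        segments.append(
            CurveSegment(
                y_start=float(y0),
                y_end=float(y1),
                apex_y=apex,
                side=side,
                tangent_start_deg=float(np.degrees(np.arctan(d1(y0)))),
                tangent_end_deg=float(np.degrees(np.arctan(d1(y1)))),
            )
        )
    return segments
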