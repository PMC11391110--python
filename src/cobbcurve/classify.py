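"""Rule-based scoliosis classification and severity grading.

The classifier is a small decision tree over the two reported Cobb angles
(the superior "upper" curve, usually thoracic, and the inferior "lower"
curve, usually lumbar):

* no angle exceeds the 10° diagnostic threshold -> no scoliosis;
* exactly one angle exceeds 10° -> ``thoracic`` if the upper angle is the
  larger of the two, else ``lumbar``;
* both angles exceed 10° -> ``thoracolumbar`` when the two curves deviate
  toward different sides, ``combined`` when they deviate toward the same
  side.

Severity is graded on a single angle: ≤10° none, 10–25° mild, 25–45°
moderate, >45° severe.  The literature bands share their endpoints
("10°–25°", "25° to 45°"); this module resolves the overlap as
upper-inclusive half-open intervals, consistent with the strict ">10°"
diagnostic rule.  A ``band_convention="lower"`` switch makes the shared
endpoints belong to the higher band instead.

The ``thoracolumbar``/``combined`` assignment follows the source decision
tree verbatim; common clinical usage tends to reserve "thoracolumbar" for a
single long curve, so ``clinical_convention=True`` swaps the two labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "DIAGNOSTIC_THRESHOLD_DEG",
    "MILD_MODERATE_BOUNDARY_DEG",
    "MODERATE_SEVERE_BOUNDARY_DEG",
    "ClassificationResult",
    "classify",
    "severity",
    "classify_measurements",
]

#: Cobb angle (degrees) above which scoliosis is diagnosed (strict >).
DIAGNOSTIC_THRESHOLD_DEG = 10.0
#: Mild/moderate severity boundary in degrees.
MILD_MODERATE_BOUNDARY_DEG = 25.0
#: Moderate/severe severity boundary in degrees.
MODERATE_SEVERE_BOUNDARY_DEG = 45.0

LABELS = ("no_scoliosis", "thoracic", "lumbar", "thoracolumbar", "combined")
GRADES = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of the classification subroutine for one spine."""

    label: str
    severity: str
    upper_angle_deg: float
    lower_angle_deg: float
    same_side: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "severity": self.severity,
            "upper_angle_deg": round(self.upper_angle_deg, 2),
            "lower_angle_deg": round(self.lower_angle_deg, 2),
            "same_side": self.same_side,
        }


def classify(
    upper_angle: float,
    lower_angle: float,
    upper_side: Optional[int] = None,
    lower_side: Optional[int] = None,
    *,
    clinical_convention: bool = False,
) -> str:
    """Classify a spine from its upper and lower Cobb angles.

    Parameters
    ----------
    upper_angle, lower_angle
        Cobb angles in degrees (>= 0) of the superior and inferior curve.
    upper_side, lower_side
        Lateral deviation sign (-1 or +1) of each curve's apex.  Required
        only when both angles exceed the diagnostic threshold.
    clinical_convention
        Swap the ``thoracolumbar``/``combined`` labels to match common
        clinical usage (same-side double curve -> thoracolumbar).

    Returns
    -------
    str
        One of ``no_scoliosis``, ``thoracic``, ``lumbar``,
        ``thoracolumbar``, ``combined``.
    """
    if upper_angle < 0 or lower_angle < 0:
        raise ValueError("Cobb angles must be non-negative")
    thr = DIAGNOSTIC_THRESHOLD_DEG
    upper_pos = upper_angle > thr
    lower_pos = lower_angle > thr
    if not upper_pos and not lower_pos:
        return "no_scoliosis"
    if not (upper_pos and lower_pos):
        # exactly one curve above threshold: decide by which angle is greater
        return "thoracic" if upper_angle > lower_angle else "lumbar"
    if upper_side not in (-1, 1) or lower_side not in (-1, 1):
        raise ValueError(
            "side required: both angles exceed the diagnostic threshold, "
            "pass upper_side and lower_side in {-1, +1}"
        )
    same_side = upper_side == lower_side
    if clinical_convention:
        return "thoracolumbar" if same_side else "combined"
    return "combined" if same_side else "thoracolumbar"


def severity(angle: float, *, band_convention: str = "upper") -> str:
    """Grade scoliosis severity from a Cobb angle in degrees.

    Bands (``band_convention="upper"``, upper-inclusive): none (0, 10],
    mild (10, 25], moderate (25, 45], severe (45, inf).  With
    ``band_convention="lower"`` the shared endpoints 25 and 45 fall in the
    higher band (the 10° diagnostic threshold stays strict in both).
    """
    if angle < 0:
        raise ValueError("Cobb angle must be non-negative")
    if band_convention not in ("upper", "lower"):
        raise ValueError("band_convention must be 'upper' or 'lower'")
    if angle <= DIAGNOSTIC_THRESHOLD_DEG:
        return "none"
    if band_convention == "upper":
        if angle <= MILD_MODERATE_BOUNDARY_DEG:
            return "mild"
        if angle <= MODERATE_SEVERE_BOUNDARY_DEG:
            return "moderate"
        return "severe"
    if angle < MILD_MODERATE_BOUNDARY_DEG:
        return "mild"
    if angle < MODERATE_SEVERE_BOUNDARY_DEG:
        return "moderate"
    return "severe"


def classify_measurements(
    measurements,
    *,
    clinical_convention: bool = False,
    band_convention: str = "upper",
) -> ClassificationResult:
    """Classify a spine from a list of :class:`~cobbcurve.cobbmeas.CobbMeasurement`.

    The two largest-angle measurements feed the decision tree, ordered
    superior->inferior by their upper boundary; with a single measurement
    the absent curve contributes a 0° angle.  Severity is graded on the
    maximum angle across all measurements.
    """
    if not measurements:
        raise ValueError("no measurements to classify")
    ranked = sorted(measurements, key=lambda m: m.angle_deg, reverse=True)[:2]
    ranked.sort(key=lambda m: m.y_upper)
    if len(ranked) == 1:
        m = ranked[0]
        upper_a, lower_a = (m.angle_deg, 0.0)
        upper_s, lower_s = (m.side, m.side)
        if m.region == "lumbar":
            upper_a, lower_a = lower_a, upper_a
    else:
        upper_a, lower_a = ranked[0].angle_deg, ranked[1].angle_deg
        upper_s, lower_s = ranked[0].side, ranked[1].side
    label = classify(
        upper_a, lower_a, upper_s, lower_s, clinical_convention=clinical_convention
    )
    max_angle = max(m.angle_deg for m in measurements)
    grade = severity(max_angle, band_convention=band_convention)
    same = (
        bool(upper_s == lower_s)
        if upper_a > DIAGNOSTIC_THRESHOLD_DEG and lower_a > DIAGNOSTIC_THRESHOLD_DEG
        else None
    )
    return ClassificationResult(label, grade, upper_a, lower_a, same)
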