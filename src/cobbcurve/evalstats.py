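"""Manual-vs-automated measurement comparison statistics.

A measurement table has one row per (case, region) with up to three angle
columns — ``manual``, ``automated``, ``automated_enhanced`` — any cell
optionally missing.  The module reproduces the standard agreement report
for such paired designs: per-column average/min/max summaries, pairwise
difference tables, and a paired significance test (two-tailed paired t by
default, Wilcoxon signed-rank as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANGLE_COLUMNS",
    "Summary",
    "DifferenceReport",
    "PairedTestResult",
    "load_table",
    "validate_table",
    "summarize",
    "difference_report",
    "paired_test",
]

ANGLE_COLUMNS = ("manual", "automated", "automated_enhanced")


class Summary(NamedTuple):
    average: float
    minimum: float
    maximum: float
    n: int


@dataclass
class DifferenceReport:
    """Absolute differences of the summary statistics between two angle
    columns, plus the signed per-case differences (cmp - ref)."""

    delta_average: float
    delta_minimum: float
    delta_maximum: float
    per_case: List[float]

    def to_dict(self) -> dict:
        return {
            "delta_average": round(self.delta_average, 4),
            "delta_minimum": round(self.delta_minimum, 4),
            "delta_maximum": round(self.delta_maximum, 4),
            "per_case": [round(d, 4) for d in self.per_case],
        }


class PairedTestResult(NamedTuple):
    statistic: float
    p_value: float
    n: int
    test: str


def load_table(path) -> pd.DataFrame:
    """Read a comparison CSV with columns case, region, manual,
    automated, automated_enhanced (angle columns optional/missing cells
    allowed)."""
    table = pd.read_csv(path)
    validate_table(table)
    return table


def validate_table(table: pd.DataFrame) -> None:
    for col in ("case", "region"):
        if col not in table.columns:
            raise ValueError(f"comparison table is missing the {col!r} column")
    if table.duplicated(subset=["case", "region"]).any():
        dupes = table[table.duplicated(subset=["case", "region"], keep=False)]
        raise ValueError(f"duplicate (case, region) rows: {sorted(set(dupes['case']))}")
    for col in ANGLE_COLUMNS:
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise ValueError(f"negative angles in column {col!r}")


def _column(table: pd.DataFrame, column: str) -> pd.Series:
    if column not in table.columns:
        raise ValueError(
            f"unknown column {column!r}; available: {sorted(table.columns)}"
        )
    return pd.to_numeric(table[column], errors="coerce")


def summarize(table: pd.DataFrame, column: str) -> Summary:
    """Arithmetic mean, min and max of a column over non-missing cells."""
    vals = _column(table, column).dropna()
    if vals.empty:
        raise ValueError(f"column {column!r} has no non-missing values")
    return Summary(
        average=float(vals.mean()),
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        n=int(len(vals)),
    )


def difference_report(
    table: pd.DataFrame, ref_column: str, cmp_column: str
) -> DifferenceReport:
    """Summary-level absolute differences and signed per-case differences
    between two angle columns; cases must match one-to-one."""
    ref = _column(table, ref_column)
    cmp_ = _column(table, cmp_column)
    only_ref = table.loc[ref.notna() & cmp_.isna(), "case"].tolist()
    only_cmp = table.loc[cmp_.notna() & ref.isna(), "case"].tolist()
    if only_ref or only_cmp:
        raise ValueError(
            f"mismatched case sets: only in {ref_column!r}: {only_ref}; "
            f"only in {cmp_column!r}: {only_cmp}"
        )
    s_ref = summarize(table, ref_column)
    s_cmp = summarize(table, cmp_column)
    mask = ref.notna() & cmp_.notna()
    per_case = (cmp_[mask] - ref[mask]).tolist()
    return DifferenceReport(
        delta_average=abs(s_cmp.average - s_ref.average),
        delta_minimum=abs(s_cmp.minimum - s_ref.minimum),
        delta_maximum=abs(s_cmp.maximum - s_ref.maximum),
        per_case=[float(d) for d in per_case],
    )


def paired_test(
    table: pd.DataFrame, col_a: str, col_b: str, test: str = "t"
) -> PairedTestResult:
    """Paired two-tailed test on per-case differences.

    ``test='t'`` (default): paired t with the exact closed-form p from
    the t distribution.  All-zero differences report (t=0, p=1);
    zero-variance nonzero differences report an infinite statistic with
    p=0.  ``test='wilcoxon'``: signed-rank alternative.
    """
    a = _column(table, col_a)
    b = _column(table, col_b)
    mask = a.notna() & b.notna()
    d = (a[mask] - b[mask]).to_numpy(dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if test == "t":
        sd = d.std(ddof=1)
        mean = d.mean()
        if sd == 0.0:
            if mean == 0.0:
                return PairedTestResult(0.0, 1.0, n, "t")
            return PairedTestResult(float(np.sign(mean) * np.inf), 0.0, n, "t")
        t_stat = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
        return PairedTestResult(float(t_stat), float(p), n, "t")
    if test == "wilcoxon":
        if np.all(d == 0):
            return PairedTestResult(0.0, 1.0, n, "wilcoxon")
        stat, p = stats.wilcoxon(d)
        return PairedTestResult(float(stat), float(p), n, "wilcoxon")
    raise ValueError(f"unknown test {test!r}; supported: t, wilcoxon")
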