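"""Descriptive and inferential statistics for embolus counts and sizes.

Conventions deliberately match clinical reporting practice for small
bilateral cohorts:

* quartiles use the inverse-empirical-CDF convention (order statistics at
  ceil(n/4) and ceil(3n/4)), which is what the counts in a ten-patient
  bilateral table imply;
* medians of counts are reported rounded half-up to an integer, with the
  exact value kept internally;
* the rank-sum test uses midranks, a plain normal approximation and no
  continuity correction, signed so that a first group with the larger
  rank-sum yields a negative z (its rank-sum "deficit" relative to the
  second group drives the sign).  With a continuity correction the printed
  z for the reference cohort would be -1.04 rather than -1.15, so the
  correction is deliberately off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .events import PatientSummary

__all__ = [
    "CohortTable",
    "SizeDistributionSummary",
    "UndefinedStatisticError",
    "median_iqr",
    "round_half_up",
    "paired_t",
    "ranksum_z",
    "size_distribution",
    "cohort_report",
]

INTRA_CARDIAC_PROCEDURES = {"MVR", "AVR", "combined", "COMBINED", "valve", "VALVE"}


class UndefinedStatisticError(ValueError):
    """A test statistic is undefined for the given data (e.g. zero variance)."""


@dataclass
class CohortTable:
    """A cohort of patient summaries with an intra-cardiac vs CABG grouping."""

    patients: list[PatientSummary]

    def __post_init__(self) -> None:
        if not self.patients:
            raise ValueError("cohort must contain at least one patient")

    def group_totals(self) -> tuple[list[int], list[int]]:
        """(intra-cardiac totals, CABG-only totals), partitioning the cohort."""
        intra, cabg = [], []
        for p in self.patients:
            if p.procedure in INTRA_CARDIAC_PROCEDURES:
                intra.append(p.n_total)
            else:
                cabg.append(p.n_total)
        return intra, cabg


@dataclass
class SizeDistributionSummary:
    median: float                       # um
    q1: float
    q3: float
    frac_below_100um: float
    frac_above_500um: float
    frac_above_1mm: float
    per_stage_medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must be ordered")
        for f in (self.frac_below_100um, self.frac_above_500um, self.frac_above_1mm):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) with inverse-empirical-CDF quartiles.

    The median is the standard sample median (mean of the central pair for
    even n, returned exactly; round half-up when reporting counts).  The
    quartiles are the order statistics at positions ceil(0.25 n) and
    ceil(0.75 n).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("median_iqr needs at least one value")
    med = float(np.median(v))
    q1 = float(v[max(math.ceil(0.25 * n) - 1, 0)])
    q3 = float(v[max(math.ceil(0.75 * n) - 1, 0)])
    return med, q1, q3


def paired_t(a, b) -> tuple[float, int, float]:
    """Two-sided paired t-test of a vs b: (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t needs two equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired_t needs n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise UndefinedStatisticError("paired differences have zero variance")
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


def ranksum_z(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum z and two-sided p, normal approximation, no
    continuity correction, midranks for ties.

    The sign convention reports the first group's rank-sum deficit: if x
    holds systematically higher ranks than y, z is negative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)            # midranks
    w = float(ranks[:n1].sum())
    expect = n1 * (n1 + n2 + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0.0:
        return 0.0, 1.0
    z = (expect - w) / math.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def size_distribution(diameters_um, stages=None) -> SizeDistributionSummary:
    """Summary of a bubble-diameter sample, thresholds applied strictly.

    ``frac_below_100um`` counts diameters strictly below 100 um and the
    upper fractions strictly above their thresholds, matching the phrasing
    "less than" / "larger than" used in clinical reports.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        raise ValueError("size_distribution needs at least one diameter")
    med, q1, q3 = median_iqr(d)
    per_stage: dict[str, float] = {}
    if stages is not None:
        stages = np.asarray(stages)
        for s in np.unique(stages):
            per_stage[str(s)] = float(np.median(d[stages == s]))
    return SizeDistributionSummary(
        median=med,
        q1=q1,
        q3=q3,
        frac_below_100um=float(np.mean(d < 100.0)),
        frac_above_500um=float(np.mean(d > 500.0)),
        frac_above_1mm=float(np.mean(d > 1000.0)),
        per_stage_medians=per_stage,
    )


def cohort_report(table: CohortTable) -> dict:
    """Cohort-level roll-up: totals, medians/IQRs per side, group comparison.

    The intra-cardiac vs CABG comparison reports both the group medians and
    the group means of the per-patient totals: in small cohorts the two can
    differ a great deal (heavy showers concentrate in a few patients), so
    conflating them is flagged rather than silently resolved.
    """
    pts = table.patients
    totals = [p.n_total for p in pts]
    left = [p.n_emboli_left for p in pts]
    right = [p.n_emboli_right for p in pts]
    report: dict = {
        "n_patients": len(pts),
        "min_total": int(min(totals)),
        "max_total": int(max(totals)),
        "total_volume_range_ml": [
            float(min(p.total_volume for p in pts)),
            float(max(p.total_volume for p in pts)),
        ],
    }
    med_l, q1_l, q3_l = median_iqr(left)
    med_r, q1_r, q3_r = median_iqr(right)
    report["left"] = {
        "median": round_half_up(med_l), "median_exact": med_l, "q1": q1_l, "q3": q3_l
    }
    report["right"] = {
        "median": round_half_up(med_r), "median_exact": med_r, "q1": q1_r, "q3": q3_r
    }
    if len(pts) >= 2:
        try:
            t, df, p = paired_t(left, right)
            report["left_vs_right"] = {"t": t, "df": df, "p": p}
        except UndefinedStatisticError:
            report["left_vs_right"] = None
    intra, cabg = table.group_totals()
    if intra and cabg:
        z, p = ranksum_z(intra, cabg)
        report["intra_cardiac_vs_cabg"] = {
            "z": z,
            "p": p,
            "intra_median": float(np.median(intra)),
            "intra_mean": float(np.mean(intra)),
            "cabg_median": float(np.median(cabg)),
            "cabg_mean": float(np.mean(cabg)),
        }
    return report
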