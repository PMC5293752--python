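"""Validation statistics: qRT-PCR relative quantification, RNA-seq
concordance, gravitropism angle analysis and two-group comparisons.

qRT-PCR follows the ΔΔCt convention with ACTIN1 as the internal
reference: ΔCt = mean(Ct_target) − mean(Ct_actin) per gene × condition,
relative level 2^(−ΔCt), and the log2 ratio of a treatment vs the
control condition is −(ΔCt_cond − ΔCt_ctrl). Concordance with RNA-seq is
an ordinary least-squares regression of RNA-seq log2 ratios (y) on qPCR
log2 ratios (x); a slope near 1 with high Pearson r validates the
sequencing calls.

Root gravitropism after a 90° reorientation is summarized by binning tip
angles into [0,30], (30,60], (60,90] and (90,∞) degrees and by per-group
means; treatment-vs-control differences use Student's pooled two-sample
t-test (Welch behind a flag), with the usual star convention
(* p ≤ 0.05, ** p ≤ 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import fraction_report

__all__ = [
    "relative_expression",
    "concordance_regression",
    "RegressionResult",
    "bin_angles",
    "DEFAULT_ANGLE_BINS",
    "group_compare",
    "GroupComparison",
]

QPCR_COLUMNS = ["gene_id", "condition", "replicate", "ct_target", "ct_actin"]


def relative_expression(qpcr: pd.DataFrame, control: str = "M0") -> pd.DataFrame:
    """ΔΔCt relative quantification of a replicated Ct table.

    ``qpcr`` needs columns gene_id, condition, replicate, ct_target,
    ct_actin. Returns one row per gene × condition with delta_ct, its SD
    over replicates, the level relative to the reference gene
    (2^(−ΔCt)) and the log2 ratio vs the ``control`` condition.
    """
    missing = set(QPCR_COLUMNS) - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns: {sorted(missing)}")
    if control not in set(qpcr["condition"]):
        raise ValueError(f"control condition {control!r} absent from qPCR table")
    if not np.isfinite(qpcr[["ct_target", "ct_actin"]].to_numpy(float)).all():
        raise ValueError("non-finite Ct values")

    per_rep = qpcr.assign(dct=qpcr["ct_target"] - qpcr["ct_actin"])
    grouped = per_rep.groupby(["gene_id", "condition"])["dct"]
    if (grouped.count() < 2).any():
        raise ValueError("need >= 2 replicates per gene x condition")
    summary = grouped.agg(delta_ct="mean", delta_ct_sd="std").reset_index()
    summary["relative"] = 2.0 ** (-summary["delta_ct"])
    ctrl = summary[summary["condition"] == control].set_index("gene_id")["delta_ct"]
    no_ctrl = set(summary["gene_id"]) - set(ctrl.index)
    if no_ctrl:
        raise ValueError(f"genes without control measurements: {sorted(no_ctrl)[:5]}")
    summary["log2_ratio"] = -(summary["delta_ct"] - summary["gene_id"].map(ctrl))
    return summary


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    n: int


def concordance_regression(
    qpcr_log2: Sequence[float], rnaseq_log2: Sequence[float]
) -> RegressionResult:
    """OLS of RNA-seq log2 ratios on qPCR log2 ratios (qPCR on x)."""
    x = np.asarray(qpcr_log2, float)
    y = np.asarray(rnaseq_log2, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in qPCR ratios; slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept), float(fit.rvalue), len(x))


DEFAULT_ANGLE_BINS: tuple[tuple[float, float], ...] = (
    (0, 30), (30, 60), (60, 90), (90, math.inf),
)


def bin_angles(
    records: pd.DataFrame,
    bins: Sequence[tuple[float, float]] = DEFAULT_ANGLE_BINS,
) -> pd.DataFrame:
    """Percentage of seedlings per tip-angle bin per treatment.

    ``records`` needs columns treatment and angle. Bins are (lo, hi]
    except the first, which also includes its lower edge. Percentages
    use half-up rounding to one decimal, so rows sum to 100 ± rounding.
    """
    for col in ("treatment", "angle"):
        if col not in records.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    if records.empty:
        raise ValueError("empty phenotype table")
    bins = sorted((float(lo), float(hi)) for lo, hi in bins)
    for (lo1, hi1), (lo2, _) in zip(bins, bins[1:]):
        if lo2 < hi1:
            raise ValueError(f"overlapping bins: ({lo1},{hi1}] and ({lo2},...]")
    edges = [bins[0][0]] + [hi for _, hi in bins]
    if (records["angle"] < edges[0]).any() or (records["angle"] > edges[-1]).any():
        raise ValueError("angles outside the binning range")
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    cut = pd.cut(records["angle"], bins=edges, labels=labels, include_lowest=True)
    rows = []
    for treatment, sub in records.groupby("treatment", sort=True):
        n = len(sub)
        counts = cut[sub.index].value_counts()
        for label in labels:
            k = int(counts.get(label, 0))
            rows.append((treatment, label, k, n, fraction_report(k, n)))
    return pd.DataFrame(rows, columns=["treatment", "bin", "k", "n", "pct"])


def _bin_label(lo: float, hi: float) -> str:
    if math.isinf(hi):
        return f">{lo:g}"
    return f"{lo:g}-{hi:g}"


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    stars: str


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> GroupComparison:
    """Two-sided two-sample t-test with mean ± SD summaries and stars.

    Student's pooled test by default; ``welch=True`` drops the
    equal-variance assumption. Degenerate zero-variance groups are
    resolved exactly: equal constants give t = 0, p = 1, distinct
    constants p = 0.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = a.mean() == b.mean()
        t, p = (0.0, 1.0) if equal else (math.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    stars = "**" if p <= 0.01 else "*" if p <= 0.05 else ""
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t=t, p=p, stars=stars,
    )
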