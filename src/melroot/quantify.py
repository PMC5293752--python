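"""FPKM quantification and fold-change DEG calling for replicate-free designs.

The study design is three single RNA-seq libraries (water control M0 and
two melatonin doses M10, M20), so differential expression is a plain FPKM
fold-change rule rather than a replicate-aware test:

    FPKM[g, s] = 1e9 * C[g, s] / (N[s] * L[g])

with C the mapped fragments of gene g in sample s, N the total mapped
reads of sample s, and L the exon length of g in bp. A gene is called up
in treatment vs control when (FPKM_t + eps) / (FPKM_c + eps) >= fold
(default 2, boundary included) and down when the ratio is <= 1/fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "compute_fpkm",
    "call_degs",
    "deg_sets",
    "intersect_degs",
    "DEGOverlap",
    "fraction_report",
]


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped reads.

    Parameters
    ----------
    counts
        Integer matrix of mapped fragments, genes × samples.
    lengths
        Exon length in bp per gene (index aligned with ``counts``).
    totals
        Total mapped reads N per sample. Defaults to the column sums of
        ``counts``; an explicit value is allowed because N in the FPKM
        definition is reads mapped to the whole genome, which can exceed
        the gene-assigned total.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"no exon length for genes: {missing}")
    bad = lengths <= 0
    if bad.any():
        raise ValueError(f"non-positive exon length for genes: {list(lengths.index[bad])[:5]}")
    if totals is None:
        totals = counts.sum(axis=0)
    else:
        totals = totals.reindex(counts.columns)
        if totals.isna().any():
            raise ValueError(f"no library total for samples: {list(counts.columns[totals.isna()])}")
    if (totals <= 0).any():
        raise ValueError(f"non-positive library total for samples: {list(totals.index[totals <= 0])}")
    fpkm = 1e9 * counts.div(totals, axis=1).div(lengths, axis=0)
    return fpkm


def call_degs(
    fpkm: pd.DataFrame,
    treatment: str,
    control: str,
    fold: float = 2.0,
    pseudocount: float = 1.0,
    min_fpkm: float | None = 1.0,
) -> pd.DataFrame:
    """Call up/down regulated genes by FPKM fold change.

    Returns a DataFrame indexed by gene with columns ``log2fc``,
    ``direction`` (up/down/none) and ``unstable`` (True where a zero
    denominator with ``pseudocount=0`` made the ratio infinite). The
    comparison label is stored in ``.attrs['comparison']``.

    ``min_fpkm`` is an expressed-gene prefilter: genes below it in both
    samples are left uncalled (direction ``none``) because ratios of
    near-zero abundances are unstable. Pass ``None`` to disable.
    """
    for sample in (treatment, control):
        if sample not in fpkm.columns:
            raise KeyError(f"sample {sample!r} not in expression matrix")
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    t = fpkm[treatment].to_numpy(float)
    c = fpkm[control].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (t + pseudocount) / (c + pseudocount)
        log2fc = np.log2(fc)
    # 0/0 with pseudocount 0: no evidence either way
    log2fc = np.where(np.isnan(log2fc), 0.0, log2fc)
    unstable = np.isinf(log2fc)

    direction = np.full(len(fpkm), "none", dtype=object)
    direction[log2fc >= np.log2(fold) - 1e-12] = "up"
    direction[log2fc <= -np.log2(fold) + 1e-12] = "down"
    if min_fpkm is not None:
        silent = (t < min_fpkm) & (c < min_fpkm)
        direction[silent] = "none"
    out = pd.DataFrame(
        {"log2fc": log2fc, "direction": direction, "unstable": unstable},
        index=fpkm.index,
    )
    out.attrs["comparison"] = f"{control}-vs-{treatment}"
    out.attrs["fold"] = fold
    out.attrs["pseudocount"] = pseudocount
    return out


def deg_sets(degs: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(up, down) gene-id sets of a DEG call table."""
    up = set(degs.index[degs["direction"] == "up"])
    down = set(degs.index[degs["direction"] == "down"])
    return up, down


@dataclass(frozen=True)
class DEGOverlap:
    """Intersection of two DEG calls over the same gene universe."""

    co_up: frozenset = field(default_factory=frozenset)
    co_down: frozenset = field(default_factory=frozenset)
    a_only_up: frozenset = field(default_factory=frozenset)
    b_only_up: frozenset = field(default_factory=frozenset)
    a_only_down: frozenset = field(default_factory=frozenset)
    b_only_down: frozenset = field(default_factory=frozenset)

    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in (
            "co_up", "co_down", "a_only_up", "b_only_up", "a_only_down", "b_only_down")}


def intersect_degs(a: pd.DataFrame, b: pd.DataFrame) -> DEGOverlap:
    """Co-up / co-down and exclusive sets of two comparisons."""
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("DEG tables cover different gene universes")
        b = b.reindex(a.index)
    up_a, down_a = deg_sets(a)
    up_b, down_b = deg_sets(b)
    return DEGOverlap(
        co_up=frozenset(up_a & up_b),
        co_down=frozenset(down_a & down_b),
        a_only_up=frozenset(up_a - up_b),
        b_only_up=frozenset(up_b - up_a),
        a_only_down=frozenset(down_a - down_b),
        b_only_down=frozenset(down_b - down_a),
    )


def fraction_report(k: int, n: int) -> float:
    """Percentage 100·k/n rounded half-up to one decimal, e.g. 46/51 → 90.2."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"numerator {k} outside [0, {n}]")
    pct = Fraction(100 * k, n)
    with localcontext() as ctx:
        ctx.prec = 50
        value = Decimal(pct.numerator) / Decimal(pct.denominator)
        return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
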