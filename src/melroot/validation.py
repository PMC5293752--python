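"""Recovery benchmarks of the pipeline on synthetic ground truth.

Each function runs one arm of the pipeline on a
:class:`~melroot.synthetic.SyntheticDataset` and scores it against the
recorded truth: DEG recall and false-call rate on high-expression null
genes, silhouette-based K selection, motif-carrier enrichment flags and
planted-GO detection. These are the quantities a scientist would check
before trusting the pipeline on real libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cluster as mcluster
from . import enrich as menrich
from . import motifscan as mscan
from . import quantify as mquant
from .synthetic import SyntheticDataset

__all__ = [
    "DERecovery",
    "de_recovery",
    "selected_k",
    "motif_enrichment_flags",
    "planted_go_detected",
    "fpkm_of",
]


def fpkm_of(ds: SyntheticDataset) -> pd.DataFrame:
    lengths = ds.annotation.set_index("gene_id")["length"]
    return mquant.compute_fpkm(ds.counts, lengths)


@dataclass(frozen=True)
class DERecovery:
    """Planted-DE recall and null false-call rate, pooled over the
    treatment-vs-control comparisons."""

    recovered: int
    planted: int
    false_calls: int
    null_genes: int

    @property
    def recall(self) -> float:
        return self.recovered / self.planted if self.planted else float("nan")

    @property
    def false_call_rate(self) -> float:
        return self.false_calls / self.null_genes if self.null_genes else float("nan")


def de_recovery(ds: SyntheticDataset, min_null_mean: float = 500.0) -> DERecovery:
    """Call DEGs for every treatment and score against the planted truth.

    False calls are counted over genes with no planted effect of any kind
    (neither DE nor cluster prototype) and baseline mean ≥
    ``min_null_mean``, where the fold-change rule is expected to be
    reliable; planted cluster genes are genuinely co-regulated, so they
    are neither hits nor false calls here.
    """
    fpkm = fpkm_of(ds)
    truth = ds.truth
    control = ds.spec.conditions[0]
    rec = plant = fp = nn = 0
    for cond in ds.spec.conditions[1:]:
        calls = mquant.call_degs(fpkm, cond, control)
        up, down = mquant.deg_sets(calls)
        comp = f"{control}-vs-{cond}"
        true_up, true_down = truth.de_up[comp], truth.de_down[comp]
        planted_any = true_up | true_down | set(truth.cluster_labels)
        nulls = [
            g for g in fpkm.index
            if g not in planted_any and truth.baseline_means[g] >= min_null_mean
        ]
        rec += len(up & true_up) + len(down & true_down)
        plant += len(true_up) + len(true_down)
        fp += sum(1 for g in nulls if g in up or g in down)
        nn += len(nulls)
    return DERecovery(rec, plant, fp, nn)


def selected_k(ds: SyntheticDataset, k_range: range = range(2, 13), seed: int = 0) -> int:
    """Silhouette-selected K on the planted cluster genes' profiles."""
    genes = sorted(ds.truth.cluster_labels)
    if not genes:
        raise ValueError("dataset has no planted cluster structure")
    normed = mcluster.normalize_profiles(fpkm_of(ds).loc[genes])
    k, _ = mcluster.select_k(normed, k_range, seed=seed)
    return k


def motif_enrichment_flags(ds: SyntheticDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Scan the planted genome and test each catalog motif for
    over-representation in the true co-up gene set."""
    promoters = mscan.extract_promoters(
        ds.genome, ds.annotation, length=ds.spec.promoter_length
    )
    carriers = mscan.carrier_table(promoters, ds.motif_catalog)
    control = ds.spec.conditions[0]
    co_up = set.intersection(
        *(set(ds.truth.de_up[f"{control}-vs-{c}"]) for c in ds.spec.conditions[1:])
    )
    return menrich.motif_enrichment(carriers, {"co_up": co_up}, alpha=alpha)


def planted_go_detected(ds: SyntheticDataset, alpha: float = 0.05) -> bool:
    """Is every planted-enriched GO term flagged in the true co-up set?"""
    control = ds.spec.conditions[0]
    co_up = set.intersection(
        *(set(ds.truth.de_up[f"{control}-vs-{c}"]) for c in ds.spec.conditions[1:])
    )
    records = menrich.enrich_features(
        co_up, list(ds.annotation["gene_id"]), ds.go_map, alpha=alpha
    )
    flagged = set(records.loc[records["significant"], "feature"])
    return ds.truth.enriched_go <= flagged
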