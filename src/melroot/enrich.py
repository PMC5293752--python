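"""Hypergeometric over-representation testing.

One machinery serves two questions: are GO terms over-represented in a
gene set (a DEG list or a cluster), and are promoter motifs
over-represented among co-regulated DEGs relative to the genome-wide
background? Both reduce to the upper-tail hypergeometric probability

    p = P(X >= k),  X ~ Hypergeometric(M, K, n)

of seeing k feature-positive genes in a query of n drawn from a universe
of M genes containing K positives — identical to a one-sided (greater)
Fisher's exact test on the 2×2 table. The tail is inclusive, so k = 0
gives p = 1.

No multiplicity adjustment is applied by default (raw p < 0.05 is the
reporting convention mirrored here); Benjamini–Hochberg is available and
recommended when many features are tested.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .quantify import fraction_report

__all__ = [
    "hypergeom_upper",
    "enrich_features",
    "motif_enrichment",
    "tf_family_breakdown",
]


def hypergeom_upper(k: int, n: int, K: int, M: int) -> float:
    """Upper-tail inclusive hypergeometric p-value P(X >= k).

    ``M``: universe size, ``K``: feature-positives in the universe,
    ``n``: query-set size, ``k``: feature-positives in the query.
    Computed via the survival function (log-space internally) for
    numerical stability.
    """
    _validate_counts(k, n, K, M)
    return float(hypergeom.sf(k - 1, M, K, n))


def _validate_counts(k: int, n: int, K: int, M: int) -> None:
    if min(k, n, K, M) < 0:
        raise ValueError("counts must be nonnegative")
    if n > M or K > M:
        raise ValueError(f"query n={n} and positives K={K} must not exceed universe M={M}")
    if k > n or k > K:
        raise ValueError(f"k={k} exceeds query size n={n} or universe positives K={K}")
    if n - k > M - K:
        raise ValueError(
            f"query has {n - k} feature-negatives but the universe only {M - K}"
        )


def enrich_features(
    query: Iterable[str],
    universe: Iterable[str],
    feature_map: pd.DataFrame | Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Test every feature present in the query for over-representation.

    ``feature_map`` maps features to genes, either a two-column DataFrame
    (gene_id, feature) or a mapping feature → gene ids. Annotations are
    taken as given — no ontology-ancestor propagation. Returns one row
    per feature with k ≥ 1 in the query, sorted by p, with fold
    enrichment (k/n)/(K/M) and a significance flag at ``alpha`` on the
    (adjusted, when ``adjust='bh'``) p-value.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    if adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    if isinstance(feature_map, pd.DataFrame):
        gene_col, feat_col = feature_map.columns[:2]
        feat2genes: dict[str, set] = {
            feat: set(sub[gene_col]) & universe
            for feat, sub in feature_map.groupby(feat_col, sort=False)
        }
    else:
        feat2genes = {feat: set(genes) & universe for feat, genes in feature_map.items()}

    M, n = len(universe), len(query)
    rows = []
    for feat, genes in feat2genes.items():
        K = len(genes)
        k = len(genes & query)
        if k == 0:
            continue
        p = hypergeom_upper(k, n, K, M)
        fold = (k / n) / (K / M)
        rows.append((feat, k, n, K, M, fold, p))
    out = pd.DataFrame(rows, columns=["feature", "k", "n", "K", "M", "fold", "p"])
    out = out.sort_values(["p", "feature"], ignore_index=True)
    if adjust == "bh" and len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = out["p"]
    out["significant"] = out["p_adj"] < alpha
    return out


def motif_enrichment(
    carriers: pd.DataFrame,
    deg_sets: Mapping[str, Iterable[str]],
    background: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Motif-carrier over-representation per (DEG set × motif).

    ``carriers`` is the boolean gene × motif table from the promoter
    scan; ``background`` defaults to every gene in it (the genome-wide
    background). For each motif, M = background genes, K = background
    carriers, n = DEG-set size, k = DEG-set carriers, and the carrier
    percentage 100·k/n is reported alongside p.
    """
    if background is None:
        background = carriers.index
    background = set(background)
    missing = background - set(carriers.index)
    if missing:
        raise ValueError(f"background genes missing from carrier table: {sorted(missing)[:5]}")
    table = carriers.loc[sorted(background)]
    rows = []
    for set_name, genes in deg_sets.items():
        genes = set(genes)
        absent = genes - background
        if absent:
            raise ValueError(
                f"DEG set {set_name!r} has genes outside the scanned background: "
                f"{sorted(absent)[:5]}"
            )
        sub = table.loc[sorted(genes)]
        for motif_id in table.columns:
            M = len(background)
            K = int(table[motif_id].sum())
            n = len(genes)
            k = int(sub[motif_id].sum())
            p = hypergeom_upper(k, n, K, M) if n else 1.0
            pct = fraction_report(k, n) if n else 0.0
            fold = (k / n) / (K / M) if n and K else np.nan
            rows.append((set_name, motif_id, k, n, K, M, pct, fold, p, p < alpha))
    return pd.DataFrame(
        rows,
        columns=["set", "motif", "k", "n", "K", "M", "carrier_pct", "fold", "p", "significant"],
    )


def tf_family_breakdown(
    deg_sets: Mapping[str, Iterable[str]],
    family_map: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-tabulate DEG sets against transcription-factor families.

    ``family_map`` is a two-column table (gene_id, family). Returns per
    (set × family) counts plus each family's share of the set's TFs as a
    rounded percentage.
    """
    gene_col, fam_col = family_map.columns[:2]
    fam = dict(zip(family_map[gene_col], family_map[fam_col]))
    rows = []
    for set_name, genes in deg_sets.items():
        tfs = [g for g in genes if g in fam]
        total = len(tfs)
        counts: dict[str, int] = {}
        for g in tfs:
            counts[fam[g]] = counts.get(fam[g], 0) + 1
        for family, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append((set_name, family, c, total, fraction_report(c, total)))
    return pd.DataFrame(rows, columns=["set", "family", "count", "set_tf_total", "pct"])
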