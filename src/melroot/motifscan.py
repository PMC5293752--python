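"""Strand-aware promoter extraction and IUPAC-degenerate motif scanning.

A promoter here is the 1000 bp immediately upstream of a gene's
transcription start site on its coding strand: for a + strand gene with
1-based TSS t it is bases [t-1000, t-1], and for a − strand gene the
reverse complement of [t+1, t+1000]. Promoters overhanging a contig edge
are clipped and flagged. Motifs are IUPAC consensus strings (W=A/T,
S=G/C, N=any, ...); matching is exact degenerate matching, overlapping
occurrences counted, by default on both strands since plant cis-element
catalogs are conventionally strand-agnostic.

Internal coordinates are 0-based half-open; GFF3 input is 1-based closed
and BED output 0-based half-open.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "IUPAC_CODES",
    "validate_iupac",
    "iupac_to_regex",
    "expand_iupac",
    "match_iupac",
    "extract_promoters",
    "carrier_table",
    "write_promoter_bed",
]

IUPAC_CODES: dict[str, str] = {k: v for k, v in ambiguous_dna_values.items() if k != "X"}


def validate_iupac(motif: str) -> str:
    motif = motif.upper()
    if not motif:
        raise ValueError("empty motif")
    bad = set(motif) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC letters in {motif!r}: {sorted(bad)}")
    return motif


def iupac_to_regex(motif: str) -> str:
    """Translate an IUPAC consensus into a character-class regex."""
    parts = []
    for letter in validate_iupac(motif):
        opts = IUPAC_CODES[letter]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def expand_iupac(motif: str, rng) -> str:
    """One concrete A/C/G/T realization of an IUPAC consensus."""
    return "".join(IUPAC_CODES[letter][rng.integers(len(IUPAC_CODES[letter]))]
                   for letter in validate_iupac(motif))


def match_iupac(sequence: str, motif: str, both_strands: bool = True) -> int:
    """Count overlapping degenerate matches of ``motif`` in ``sequence``.

    With ``both_strands`` the reverse complement of the sequence is also
    scanned and the counts summed (a palindromic site therefore counts
    twice, once per strand).
    """
    pattern = re.compile(f"(?=({iupac_to_regex(motif)}))")
    seq = sequence.upper()
    count = len(pattern.findall(seq))
    if both_strands:
        count += len(pattern.findall(str(Seq(seq).reverse_complement())))
    return count


def promoter_intervals(annotation: pd.DataFrame, length: int = 1000) -> pd.DataFrame:
    """0-based half-open genomic intervals of the upstream regions,
    unclipped (may be negative at contig starts)."""
    plus = annotation["strand"] == "+"
    # + strand, TSS = start (1-based): bases [start-length, start-1] 1-based
    start0 = (annotation["start"] - 1 - length).where(plus, annotation["end"])
    end0 = (annotation["start"] - 1).where(plus, annotation["end"] + length)
    return pd.DataFrame(
        {
            "gene_id": annotation["gene_id"],
            "chrom": annotation["chrom"],
            "start": start0.astype(int),
            "end": end0.astype(int),
            "strand": annotation["strand"],
        }
    )


def extract_promoters(
    genome: Mapping[str, str],
    annotation: pd.DataFrame,
    length: int = 1000,
) -> pd.DataFrame:
    """Extract strand-aware promoter sequences for every gene.

    Returns a DataFrame with columns gene_id, chrom, start, end (0-based
    half-open genomic coordinates of the extracted window), strand,
    clipped (True when the window hit a contig edge) and seq (promoter in
    coding-strand orientation). No masking against neighboring gene
    bodies is applied.
    """
    if length < 1:
        raise ValueError("promoter length must be >= 1")
    missing = set(annotation["chrom"]) - set(genome)
    if missing:
        raise KeyError(f"genes on contigs absent from the genome: {sorted(missing)}")
    intervals = promoter_intervals(annotation, length)
    rows = []
    for row in intervals.itertuples(index=False):
        contig = genome[row.chrom]
        start = max(row.start, 0)
        end = min(row.end, len(contig))
        if end < start:
            start = end = min(max(row.start, 0), len(contig))
        seq = contig[start:end]
        if row.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        rows.append(
            (row.gene_id, row.chrom, start, end, row.strand,
             end - start != length, seq)
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "clipped", "seq"]
    )


def carrier_table(
    promoters: pd.DataFrame,
    catalog: pd.DataFrame | Mapping[str, str],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Boolean gene × motif matrix: does the promoter carry ≥1 match?

    ``catalog`` is either a DataFrame with columns motif_id/iupac or a
    mapping motif_id → IUPAC string. Presence/absence (not occurrence
    count) is what feeds enrichment downstream.
    """
    if isinstance(catalog, pd.DataFrame):
        motifs = dict(zip(catalog["motif_id"], catalog["iupac"]))
    else:
        motifs = dict(catalog)
    data = {}
    for motif_id, iupac in motifs.items():
        pattern = re.compile(f"(?=({iupac_to_regex(iupac)}))")
        flags = []
        for seq in promoters["seq"]:
            seq = seq.upper()
            hit = pattern.search(seq) is not None
            if not hit and both_strands:
                hit = pattern.search(str(Seq(seq).reverse_complement())) is not None
            flags.append(hit)
        data[motif_id] = flags
    return pd.DataFrame(data, index=pd.Index(promoters["gene_id"], name="gene_id"))


def write_promoter_bed(promoters: pd.DataFrame, path) -> None:
    """BED6 (0-based half-open) audit trail of the extracted windows."""
    bed = promoters[["chrom", "start", "end", "gene_id", "strand"]].copy()
    bed.insert(4, "score", 0)
    bed.to_csv(path, sep="\t", header=False, index=False)


def iter_carrier_sets(carriers: pd.DataFrame) -> Iterable[tuple[str, set[str]]]:
    for motif_id in carriers.columns:
        yield motif_id, set(carriers.index[carriers[motif_id]])
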