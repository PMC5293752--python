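"""Readers and writers for the plain-text formats the pipeline consumes.

Gene annotations travel as GFF3 (1-based, closed intervals), genomes as
FASTA, and everything tabular (counts, motif catalogs, GO maps, carrier
matrices) as TSV. Internally the annotation is a flat DataFrame with one
row per gene; coordinates stay 1-based closed until promoter extraction,
which converts to 0-based half-open.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "length"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case contig sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: Mapping[str, str] | Iterable[SeqRecord], path: str | os.PathLike) -> None:
    if isinstance(contigs, Mapping):
        records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    else:
        records = list(contigs)
    SeqIO.write(records, path if hasattr(path, "write") else str(path), "fasta")


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Load gene models from GFF3 into the flat annotation table.

    Only ``gene`` features are kept; ``length`` is the summed length of the
    gene's exons when exon children are present, otherwise the gene span.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        exons = list(db.children(gene, featuretype="exon"))
        if exons:
            length = sum(e.end - e.start + 1 for e in exons)
        else:
            length = gene.end - gene.start + 1
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        rows.append((gene_id, gene.seqid, gene.start, gene.end, gene.strand, length))
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_gff3(annotation: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the annotation table as GFF3 (gene + single exon per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            fh.write(
                f"{row.chrom}\tmelroot\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{row.chrom}\tmelroot\texon\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={row.gene_id}.exon1;Parent={row.gene_id}\n"
            )


def tss(annotation: pd.DataFrame) -> pd.Series:
    """1-based transcription start per gene: ``start`` on +, ``end`` on −."""
    plus = annotation["strand"] == "+"
    return annotation["start"].where(plus, annotation["end"]).rename("tss")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_motif_catalog(path: str | os.PathLike) -> pd.DataFrame:
    """Motif catalog TSV with columns ``motif_id`` and ``iupac``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"motif_id", "iupac"} - set(df.columns)
    if missing:
        raise ValueError(f"motif catalog lacks columns: {sorted(missing)}")
    df["iupac"] = df["iupac"].str.upper()
    return df


def read_gene_map(path: str | os.PathLike, value_col: str) -> pd.DataFrame:
    """Two-column gene→feature TSV (GO terms, TF families, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", value_col} - set(df.columns)
    if missing:
        raise ValueError(f"gene map lacks columns: {sorted(missing)}")
    return df[["gene_id", value_col]]


def atomic_write_text(text: str, path: str | os.PathLike) -> None:
    """Write text to ``path`` via a temp file in the same directory."""
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
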