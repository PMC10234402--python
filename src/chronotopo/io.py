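"""Readers for the plain-text genomics formats the pipeline consumes."""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

_ID_RE = re.compile(r"ID=([^;]+)")


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene records of a GFF3 file as a frame with 0-based starts.

    Columns: gene_id, chrom, start (0-based), end (exclusive), strand.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )
    df = df[df.type == "gene"].copy()
    df["gene_id"] = df.attributes.str.extract(_ID_RE)
    out = pd.DataFrame(
        {
            "gene_id": df.gene_id,
            "chrom": df.seqid,
            "start": df.start.astype(int) - 1,  # GFF3 is 1-based inclusive
            "end": df.end.astype(int),
            "strand": df.strand,
        }
    )
    return out.reset_index(drop=True)


def read_bed(path, value_col: str = "rpkm") -> pd.DataFrame:
    """BED (0-based half-open) with optional name and score columns."""
    df = pd.read_csv(path, sep="\t", header=None)
    cols = ["chrom", "start", "end", "name", value_col][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="t")  # skips 'track' lines
    df.columns = ["chrom", "start", "end", "value"]
    return df


def read_methylation(path) -> pd.DataFrame:
    """Methylation TSV with header chrom, pos, meth_pct."""
    return pd.read_csv(path, sep="\t")


def read_true_ages(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def chrom_sizes_from_fasta(path) -> dict[str, int]:
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
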