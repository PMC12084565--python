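"""Plain-text format helpers: bedGraph, gene tables.

BED/bedGraph conventions throughout: 0-based half-open, tab-separated,
no header. The gene table is a headered TSV with at least gene_id,
chrom, tss, strand, expression.
"""

from __future__ import annotations

import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "expression"]


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_table(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    return genes
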