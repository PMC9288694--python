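"""Readers and writers for the plain-text genomics formats the pipeline touches.

All interval formats are BED-style: 0-based half-open, tab-separated, no
header.  Genomic outputs are sorted (chrom, start) so reruns diff cleanly.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping

import pandas as pd

BED3 = ["chrom", "start", "end"]
BED4 = BED3 + ["name"]
BEDGRAPH = BED3 + ["value"]
READS_COLUMNS = ["sample", "chrom", "fragment_index", "count"]


def _read_tab(path, columns):
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    if df.shape[1] < len(columns):
        raise ValueError(
            f"{path}: expected at least {len(columns)} columns, found {df.shape[1]}"
        )
    df = df.iloc[:, : len(columns)]
    df.columns = columns
    return df


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file; extra columns beyond (chrom, start, end, name) are dropped."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = min(df.shape[1], 4)
    df = df.iloc[:, :ncol]
    df.columns = (BED4)[:ncol]
    _validate_intervals(df, str(path))
    return df


def _validate_intervals(df: pd.DataFrame, origin: str) -> None:
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        line = int(bad[0]) + 1
        raise ValueError(f"{origin}, line {line}: invalid interval (need 0 <= start < end)")


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns]
    out = df.sort_values(["chrom", "start"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bedgraph(path) -> pd.DataFrame:
    df = _read_tab(path, BEDGRAPH)
    _validate_intervals(df, str(path))
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    out = df.sort_values(["chrom", "start"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False, columns=BEDGRAPH)


def read_reads(path) -> pd.DataFrame:
    """Read a fragment-level read table (sample, chrom, fragment_index, count)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(READS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: reads table missing columns {sorted(missing)}")
    return df[READS_COLUMNS]


def write_reads(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=READS_COLUMNS)


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
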