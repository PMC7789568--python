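"""Readers and writers for the plain-text formats used across the pipeline.

FASTA via Biopython; reads as BED6 (name column = sample id); counts as TSV
with ``chrom:start-stop`` row labels; sample sheets as two-column TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .windows import CountMatrix, WindowGrid

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed_reads",
    "write_bed_reads",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_count_matrix",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed_reads(path: str | Path, sample: str | None = None) -> dict[str, pd.DataFrame]:
    """Read a BED file of read intervals, split by the name column.

    With 3-column BED (or ``sample`` given) all intervals belong to one
    sample; with BED6 the name field multiplexes samples.
    """
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "stop", 3: "name"})
    if sample is not None or df.shape[1] < 4:
        name = sample if sample is not None else Path(path).stem
        return {name: df[["chrom", "start", "stop"]]}
    return {
        str(name): g[["chrom", "start", "stop"]].reset_index(drop=True)
        for name, g in df.groupby("name", sort=False)
    }


def write_bed_reads(reads: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    frames = []
    for sample, df in reads.items():
        out = df[["chrom", "start", "stop"]].copy()
        out["name"] = sample
        out["score"] = 0
        out["strand"] = "+"
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(
        str(path), sep="\t", header=False, index=False
    )


def write_counts_tsv(counts: CountMatrix, path: str | Path) -> None:
    counts.counts.rename_axis("window").to_csv(str(path), sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", index_col=0)


def write_sample_sheet(groups: Mapping[str, str] | pd.Series, path: str | Path) -> None:
    pd.Series(dict(groups), name="group").rename_axis("sample_id").to_csv(
        str(path), sep="\t"
    )


def read_sample_sheet(path: str | Path) -> pd.Series:
    df = pd.read_csv(str(path), sep="\t")
    return df.set_index("sample_id")["group"]


def load_count_matrix(counts_path: str | Path, sheet_path: str | Path) -> CountMatrix:
    """Counts TSV + sample sheet TSV -> CountMatrix (the TSV entry point)."""
    counts = read_counts_tsv(counts_path)
    groups = read_sample_sheet(sheet_path)
    return CountMatrix.from_counts(counts, groups)


def write_window_bed(grid: WindowGrid, path: str | Path) -> None:
    """Window BED with per-window CpG counts in the score column."""
    out = grid.windows.copy()
    out["name"] = grid.labels()
    out["score"] = grid.cpg if grid.cpg is not None else 0
    out["strand"] = "."
    out.to_csv(str(path), sep="\t", header=False, index=False)
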