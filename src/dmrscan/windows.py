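"""Fixed-width genome window grids, read counting, RPKM and CpG metrics.

Coordinates are 0-based half-open (BED convention) throughout.  Windows are
labelled ``chrom:start-stop``.  A read is assigned to exactly one window: the
one containing its midpoint ``floor((start + stop) / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WindowGrid",
    "CountMatrix",
    "tile_genome",
    "count_reads",
    "rpkm",
    "cpg_count",
    "cpg_density",
    "parse_window_label",
]

GROUPS = ("case", "control", "blinded")


def parse_window_label(label: str) -> tuple[str, int, int]:
    """Split a ``chrom:start-stop`` label into its parts."""
    chrom, _, span = label.rpartition(":")
    start, _, stop = span.partition("-")
    return chrom, int(start), int(stop)


@dataclass
class WindowGrid:
    """The genome tiled into contiguous, non-overlapping, sorted windows.

    All windows are ``window_size`` long except for at most one trailing
    partial window per chromosome, whose true (shorter) length is kept.
    """

    window_size: int
    chrom_lengths: dict[str, int]
    windows: pd.DataFrame  # columns: chrom, start, stop
    cpg: np.ndarray | None = None  # per-window CpG count, once sequence attached

    def __post_init__(self) -> None:
        offsets: dict[str, tuple[int, int]] = {}
        pos = 0
        for chrom, length in self.chrom_lengths.items():
            n = -(-length // self.window_size)
            offsets[chrom] = (pos, n)
            pos += n
        self._offsets = offsets

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def labels(self) -> pd.Index:
        w = self.windows
        return pd.Index(
            w["chrom"].astype(str)
            + ":"
            + w["start"].astype(str)
            + "-"
            + w["stop"].astype(str)
        )

    def lengths(self) -> np.ndarray:
        return (self.windows["stop"] - self.windows["start"]).to_numpy()

    def chrom_slice(self, chrom: str) -> slice:
        off, n = self._offsets[chrom]
        return slice(off, off + n)

    def window_index(self, chrom: str, pos: int) -> int:
        """Global index of the window containing position ``pos``."""
        off, n = self._offsets[chrom]
        i = pos // self.window_size
        if not 0 <= i < n:
            raise IndexError(f"position {pos} outside {chrom}")
        return off + i

    def attach_cpg(self, genome: Mapping[str, str]) -> None:
        """Compute per-window CpG counts from chromosome sequences."""
        counts = np.zeros(self.n_windows, dtype=int)
        for chrom in self.chrom_lengths:
            seq = genome[chrom]
            sl = self.chrom_slice(chrom)
            for i, (start, stop) in enumerate(
                zip(self.windows["start"].iloc[sl], self.windows["stop"].iloc[sl])
            ):
                counts[sl.start + i] = cpg_count(seq, (start, stop))
        self.cpg = counts


@dataclass
class CountMatrix:
    """Integer read counts per (window, sample) with sample metadata.

    ``counts`` is indexed by window label with one column per sample.
    ``library_size`` always equals the per-sample column sum.
    """

    counts: pd.DataFrame
    groups: pd.Series
    library_size: pd.Series
    skipped: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        groups: Mapping[str, str] | pd.Series,
        skipped: dict[str, int] | None = None,
    ) -> "CountMatrix":
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        groups = groups.reindex(counts.columns)
        if groups.isna().any():
            missing = list(groups.index[groups.isna()])
            raise ValueError(f"samples missing a group label: {missing}")
        bad = set(groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        return cls(
            counts=counts,
            groups=groups,
            library_size=counts.sum(axis=0),
            skipped=skipped or {},
        )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix.from_counts(self.counts[samples], self.groups[samples])

    def with_groups(self, groups: Mapping[str, str] | pd.Series) -> "CountMatrix":
        return CountMatrix.from_counts(self.counts, groups, dict(self.skipped))


def tile_genome(
    chrom_lengths: Mapping[str, int], window_size: int = 1000
) -> WindowGrid:
    """Tile each chromosome into ``ceil(L / window_size)`` windows.

    The trailing window is retained even when shorter than ``window_size``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    chroms, starts, stops = [], [], []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        edges = np.arange(0, length, window_size)
        chroms.extend([chrom] * len(edges))
        starts.append(edges)
        stops.append(np.minimum(edges + window_size, length))
    windows = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts) if starts else [],
            "stop": np.concatenate(stops) if stops else [],
        }
    )
    return WindowGrid(
        window_size=window_size,
        chrom_lengths=dict(chrom_lengths),
        windows=windows,
    )


def _as_interval_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    return pd.DataFrame(list(reads), columns=["chrom", "start", "stop"])


def count_reads(
    reads: Mapping[str, object],
    grid: WindowGrid,
    groups: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Count per-sample read intervals into the window grid.

    ``reads`` maps sample id to an interval table (DataFrame with chrom /
    start / stop columns, or an iterable of such tuples).  Reads whose
    midpoint falls on an unknown chromosome (or beyond its end) are counted
    per sample in ``CountMatrix.skipped``.  Malformed intervals
    (``stop <= start``) raise with the offending record number.
    """
    labels = grid.labels()
    mat = {}
    skipped: dict[str, int] = {}
    for sample, table in reads.items():
        df = _as_interval_frame(table)
        start = df["start"].to_numpy(dtype=np.int64)
        stop = df["stop"].to_numpy(dtype=np.int64)
        bad = np.nonzero(stop <= start)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"sample {sample}: malformed interval at record {i + 1}: "
                f"stop ({stop[i]}) <= start ({start[i]})"
            )
        counts = np.zeros(grid.n_windows, dtype=np.int64)
        n_skip = 0
        mid = (start + stop) // 2
        chrom_arr = df["chrom"].to_numpy()
        for chrom in pd.unique(chrom_arr):
            sel = chrom_arr == chrom
            if chrom not in grid.chrom_lengths:
                n_skip += int(sel.sum())
                continue
            m = mid[sel]
            inside = (m >= 0) & (m < grid.chrom_lengths[chrom])
            n_skip += int((~inside).sum())
            off, _ = grid._offsets[chrom]
            idx = off + m[inside] // grid.window_size
            np.add.at(counts, idx, 1)
        mat[sample] = counts
        skipped[sample] = n_skip
    counts_df = pd.DataFrame(mat, index=labels)
    if groups is None:
        groups = {s: "blinded" for s in counts_df.columns}
    return CountMatrix.from_counts(counts_df, groups, skipped)


def rpkm(counts: CountMatrix, grid: WindowGrid | None = None) -> pd.DataFrame:
    """Reads per kilobase of window per million library reads.

    ``rpkm(w, j) = count(w, j) / ((len(w)/1000) * (N(j)/1e6))``.  Window
    lengths come from the grid when given, otherwise from the
    ``chrom:start-stop`` row labels.
    """
    zero = counts.library_size[counts.library_size <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    if grid is not None:
        lengths = grid.lengths()
    else:
        lengths = np.array(
            [stop - start for _, start, stop in map(parse_window_label, counts.counts.index)]
        )
    kb = lengths / 1000.0
    per_million = counts.library_size.to_numpy() / 1e6
    return counts.counts.div(kb, axis=0).div(per_million, axis=1)


def cpg_count(sequence: str, interval: tuple[int, int]) -> int:
    """Number of CG dinucleotides fully inside ``[start, stop)``.

    Counted on the given strand only; CG is its own reverse complement, so
    the choice of strand does not matter.  Case-insensitive.
    """
    start, stop = interval
    if start < 0 or stop > len(sequence) or start > stop:
        raise ValueError(
            f"interval [{start}, {stop}) outside sequence of length {len(sequence)}"
        )
    return sequence[start:stop].upper().count("CG")


def cpg_density(sequence: str, interval: tuple[int, int]) -> float:
    """CpG dinucleotides per 100 bp of the interval."""
    start, stop = interval
    if stop == start:
        return 0.0
    return 100.0 * cpg_count(sequence, interval) / (stop - start)
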