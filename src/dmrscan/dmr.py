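"""DMR calling and characterization.

Significant windows (raw p below threshold) are merged into DMRs when
adjacent on the same chromosome; each DMR carries its member-window count,
minimum p, a post-hoc q < 0.05 check, the log fold change of its most
significant window (sign gives the direction), length, CpG content, and
gene associations within 10 kb of a strand-aware TSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .windows import WindowGrid, cpg_count

__all__ = [
    "DMR",
    "ThresholdTable",
    "GeneAnnotation",
    "call_dmrs",
    "threshold_table",
    "dmr_features",
    "associate_genes",
    "gene_set_overlap",
    "dmrs_to_frame",
]

DEFAULT_THRESHOLDS = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7)


@dataclass
class DMR:
    chrom: str
    start: int
    stop: int
    n_windows: int
    min_p: float
    all_q_below_05: bool
    max_lfc: float
    direction: str  # "increase" | "decrease"
    length_kb: float
    window_indices: tuple[int, ...] = ()
    window_labels: tuple[str, ...] = ()
    cpg_count: int | None = None
    cpg_density_bin: int | None = None
    gene_associations: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.stop}"


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    stop: int
    strand: str
    functional_category: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError(f"gene {self.gene_id}: start must be < stop")

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.stop
        raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")


@dataclass
class ThresholdTable:
    counts: pd.DataFrame  # columns: threshold, n_dmrs, n_multi_window
    working_threshold: float
    histogram: dict[int, int]  # n_windows -> DMR count at the working threshold


def _check_alignment(results: pd.DataFrame, grid: WindowGrid) -> None:
    if len(results) != grid.n_windows:
        raise ValueError(
            f"results ({len(results)} rows) not aligned to grid ({grid.n_windows} windows)"
        )
    if not (
        np.array_equal(results["start"].to_numpy(), grid.windows["start"].to_numpy())
        and (results["chrom"].to_numpy() == grid.windows["chrom"].to_numpy()).all()
    ):
        raise ValueError("results rows are not aligned to the window grid")


def call_dmrs(
    results: pd.DataFrame,
    grid: WindowGrid,
    p_threshold: float = 1e-5,
) -> list[DMR]:
    """Merge maximal runs of adjacent significant windows into DMRs."""
    _check_alignment(results, grid)
    p = results["p_value"].to_numpy()
    q = results["q_value"].to_numpy()
    lfc = results["lfc"].to_numpy()
    starts = results["start"].to_numpy()
    stops = results["stop"].to_numpy()
    labels = results.index.to_numpy()

    dmrs: list[DMR] = []
    for chrom in grid.chrom_lengths:
        sl = grid.chrom_slice(chrom)
        sig = np.nonzero(p[sl] < p_threshold)[0] + sl.start
        if sig.size == 0:
            continue
        breaks = np.nonzero(np.diff(sig) > 1)[0] + 1
        for run in np.split(sig, breaks):
            member_p = p[run]
            best_local = _best_window(member_p, lfc[run])
            best = run[best_local]
            dmrs.append(
                DMR(
                    chrom=chrom,
                    start=int(starts[run[0]]),
                    stop=int(stops[run[-1]]),
                    n_windows=len(run),
                    min_p=float(member_p.min()),
                    all_q_below_05=bool((q[run] < 0.05).all()),
                    max_lfc=float(lfc[best]),
                    direction="increase" if lfc[best] > 0 else "decrease",
                    length_kb=float(stops[run[-1]] - starts[run[0]]) / 1000.0,
                    window_indices=tuple(int(i) for i in run),
                    window_labels=tuple(labels[run]),
                )
            )
    return dmrs


def _best_window(p: np.ndarray, lfc: np.ndarray) -> int:
    """Index of the minimum-p member; ties broken by larger |lfc|."""
    tied = np.nonzero(p == p.min())[0]
    return int(tied[np.argmax(np.abs(lfc[tied]))])


def threshold_table(
    results: pd.DataFrame,
    grid: WindowGrid,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    working_threshold: float = 1e-5,
) -> ThresholdTable:
    """DMR counts per p-value cutoff plus a size histogram at the working cutoff."""
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    rows = []
    for t in thresholds:
        dmrs = call_dmrs(results, grid, p_threshold=t)
        rows.append(
            {
                "threshold": t,
                "n_dmrs": len(dmrs),
                "n_multi_window": sum(1 for d in dmrs if d.n_windows >= 2),
            }
        )
    working = call_dmrs(results, grid, p_threshold=working_threshold)
    hist: dict[int, int] = {}
    for d in working:
        hist[d.n_windows] = hist.get(d.n_windows, 0) + 1
    return ThresholdTable(
        counts=pd.DataFrame(rows),
        working_threshold=working_threshold,
        histogram=dict(sorted(hist.items())),
    )


def dmr_features(dmr: DMR, genome: dict[str, str]) -> DMR:
    """Populate CpG count and the 1..10+ density bin from sequence."""
    if dmr.chrom not in genome:
        raise ValueError(f"no sequence for chromosome {dmr.chrom}")
    n = cpg_count(genome[dmr.chrom], (dmr.start, dmr.stop))
    density = 100.0 * n / (dmr.stop - dmr.start)
    # the density axis has no zero bin: < 0.5 rounds up into bin 1, > 10 clamps
    dmr.cpg_count = n
    dmr.cpg_density_bin = int(min(max(math.floor(density + 0.5), 1), 10))
    return dmr


def _categorize(dmr: DMR, gene: GeneAnnotation, max_dist: int) -> tuple[str, int] | None:
    """(category, distance) for one DMR/gene pair, or None if too far."""
    if dmr.start < gene.stop and gene.start < dmr.stop:
        return "overlap", 0
    upstream = (gene.strand == "+" and dmr.stop <= gene.start) or (
        gene.strand == "-" and dmr.start >= gene.stop
    )
    if gene.strand == "+":
        gap = gene.start - dmr.stop if upstream else dmr.start - gene.stop
    else:
        gap = dmr.start - gene.stop if upstream else gene.start - dmr.stop
    if gap > max_dist:
        return None
    if upstream:
        if gap <= 1000:
            return "proximal_1k", gap
        if gap <= 5000:
            return "proximal_5k", gap
        return "distal_10k", gap
    return "downstream_10k", gap


def associate_genes(
    dmrs: list[DMR],
    annotation: list[GeneAnnotation],
    max_dist: int = 10_000,
) -> list[DMR]:
    """Attach (gene_id, category, distance) tuples; unmatched DMRs stay intergenic.

    Categories: ``overlap`` for intersecting intervals; strand-aware upstream
    bands ``proximal_1k`` (gap <= 1 kb of the TSS), ``proximal_5k`` (1-5 kb),
    ``distal_10k`` (5-10 kb); other genes within ``max_dist`` are recorded as
    ``downstream_10k``.
    """
    for gene in annotation:
        gene.tss  # validates strand eagerly
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for gene in annotation:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for dmr in dmrs:
        dmr.gene_associations = []
        for gene in by_chrom.get(dmr.chrom, []):
            hit = _categorize(dmr, gene, max_dist)
            if hit is not None:
                dmr.gene_associations.append((gene.gene_id, hit[0], hit[1]))
    return dmrs


def gene_set_overlap(
    dmr_genes: set[str], gene_set: set[str], universe: int, name: str = ""
) -> dict:
    """Hypergeometric overlap test of DMR-associated genes against a gene set.

    p = P[X >= overlap] with X ~ Hypergeom(universe, |gene_set|, |dmr_genes|).
    Percent overlap is relative to the smaller of the two sets.
    """
    if len(dmr_genes) > universe or len(gene_set) > universe:
        raise ValueError("set larger than the declared universe")
    k = len(dmr_genes & gene_set)
    if universe < len(dmr_genes) + len(gene_set) - k:
        raise ValueError("universe too small for the observed sets (universe mismatch)")
    smaller = min(len(dmr_genes), len(gene_set))
    pct = 100.0 * k / smaller if smaller else 0.0
    p = float(hypergeom.sf(k - 1, universe, len(gene_set), len(dmr_genes)))
    return {
        "name": name,
        "overlap": k,
        "percent_overlap": pct,
        "p_value": min(p, 1.0),
        "overlapping_genes": sorted(dmr_genes & gene_set),
    }


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Flatten DMRs into a feature table (one row per DMR)."""
    rows = []
    for d in dmrs:
        rows.append(
            {
                "name": d.label,
                "chrom": d.chrom,
                "start": d.start,
                "stop": d.stop,
                "length_bp": d.stop - d.start,
                "n_windows": d.n_windows,
                "min_p": d.min_p,
                "all_q_below_05": d.all_q_below_05,
                "max_lfc": d.max_lfc,
                "direction": d.direction,
                "cpg_count": d.cpg_count,
                "cpg_density_bin": d.cpg_density_bin,
                "genes": ";".join(
                    f"{g}:{cat}:{dist}" for g, cat, dist in d.gene_associations
                ),
            }
        )
    return pd.DataFrame(rows)
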