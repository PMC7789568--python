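"""Synthetic MeDIP-seq-like data: genomes, planted DMRs and NB window counts.

The generative model matches the assumptions of the differential test so that
recovery experiments are well-posed: counts are negative binomial (Gamma-
Poisson) with a common dispersion, per-sample library-size factors are
log-normal with a configurable CV, and a minority of truly differential
window runs ("planted DMRs") get a multiplicative fold applied to the case
group only, up or down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .windows import CountMatrix, WindowGrid, tile_genome

__all__ = [
    "SimConfig",
    "PlantedDMR",
    "SimResult",
    "simulate_genome",
    "plant_dmrs",
    "simulate_counts",
    "simulate_reads",
    "simulate_dataset",
]

_NON_G = np.frombuffer(b"ACT", dtype="S1")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Parameters of the synthetic 13-vs-13 two-group design."""

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    window_size: int = 1000
    n_case: int = 13
    n_control: int = 13
    base_mean_depth: float = 30.0
    baseline_cv: float = 0.0  # window-to-window variation of the baseline mean
    libsize_cv: float = 0.1
    dispersion: float = 0.1  # NB phi; var = mu + phi * mu^2
    n_planted_dmrs: int = 0
    planted_width_windows: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.90, 2: 0.07, 3: 0.03}
    )
    effect_fold: float = 2.5
    frac_decrease: float = 0.62
    background_cpg_rate: float = 2.0  # CG dinucleotides per 100 bp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise ValueError("n_chromosomes and chrom_length must be positive")
        if self.chrom_length < self.window_size:
            raise ValueError("chrom_length must be >= window_size")
        if min(self.n_case, self.n_control) < 0 or self.n_planted_dmrs < 0:
            raise ValueError("counts must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.frac_decrease <= 1:
            raise ValueError("frac_decrease must be in [0, 1]")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if self.background_cpg_rate < 0 or self.background_cpg_rate > 50:
            raise ValueError("background_cpg_rate must be in [0, 50] per 100 bp")
        widths = self.planted_width_windows
        if any(w < 1 for w in widths) or abs(sum(widths.values()) - 1.0) > 1e-9:
            raise ValueError("planted_width_windows must be a distribution over widths >= 1")

    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)}

    def sample_ids(self) -> tuple[list[str], list[str]]:
        case = [f"case_{i + 1:02d}" for i in range(self.n_case)]
        control = [f"control_{i + 1:02d}" for i in range(self.n_control)]
        return case, control


@dataclass
class PlantedDMR:
    """Ground-truth differential run: contiguous window indices on one chromosome."""

    chrom: str
    window_indices: tuple[int, ...]  # global grid indices, contiguous
    direction: str  # "increase" | "decrease"
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        idx = self.window_indices
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("window_indices must be contiguous")


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    grid: WindowGrid
    planted: list[PlantedDMR]
    counts: CountMatrix


def _cg_free_background(length: int, rng: np.random.Generator) -> np.ndarray:
    """IID A/C/G/T bytes with every accidental CG broken (G -> A)."""
    seq = rng.choice(_BASES, size=length)
    if length >= 2:
        cg = (seq[:-1] == b"C") & (seq[1:] == b"G")
        seq[1:][cg] = b"A"
    return seq


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Generate uppercase A/C/G/T chromosomes at the requested CpG rate.

    CG dinucleotides are planted at non-overlapping positions on a CG-free
    background, so the realized count is Binomial(L - 1, rate / 100) and a
    rate of zero yields a sequence with no CG at all.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.background_cpg_rate / 100.0
    genome: dict[str, str] = {}
    for chrom, length in config.chrom_lengths().items():
        seq = _cg_free_background(length, rng)
        if p > 0 and length >= 2:
            k = rng.binomial(length - 1, p)
            k = min(k, length // 2)
            if k > 0:
                # sorted choice + offset -> non-overlapping positions >= 2 apart
                q = np.sort(rng.choice(length - 1 - (k - 1), size=k, replace=False))
                pos = q + np.arange(k)
                seq[pos] = b"C"
                seq[pos + 1] = b"G"
        genome[chrom] = seq.tobytes().decode("ascii")
    return genome


def plant_dmrs(
    grid: WindowGrid, config: SimConfig, rng: np.random.Generator | None = None
) -> list[PlantedDMR]:
    """Place mutually non-adjacent differential window runs on the grid.

    Non-adjacency (>= 1 clean window between runs) guarantees that merging
    significant windows downstream yields exactly one DMR per planted run.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.n_planted_dmrs == 0:
        return []
    widths = sorted(config.planted_width_windows)
    probs = [config.planted_width_windows[w] for w in widths]
    if config.n_planted_dmrs * max(widths) * 3 > grid.n_windows:
        raise ValueError(
            f"cannot pack {config.n_planted_dmrs} runs of width <= {max(widths)} "
            f"(plus separation) into {grid.n_windows} windows"
        )
    occupied = np.zeros(grid.n_windows, dtype=bool)
    chrom_bounds = {c: (s.start, s.stop) for c, s in
                    ((c, grid.chrom_slice(c)) for c in grid.chrom_lengths)}
    chroms = list(chrom_bounds)
    planted: list[PlantedDMR] = []
    max_attempts = 1000 * config.n_planted_dmrs
    attempts = 0
    while len(planted) < config.n_planted_dmrs:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "failed to place non-adjacent planted DMRs; "
                "reduce n_planted_dmrs or enlarge the genome"
            )
        width = int(rng.choice(widths, p=probs))
        chrom = chroms[int(rng.integers(len(chroms)))]
        lo, hi = chrom_bounds[chrom]
        if hi - lo < width:
            continue
        start = int(rng.integers(lo, hi - width + 1))
        # block the run plus one flanking window on each side
        block = slice(max(lo, start - 1), min(hi, start + width + 1))
        if occupied[block].any():
            continue
        occupied[block] = True
        direction = "decrease" if rng.random() < config.frac_decrease else "increase"
        planted.append(
            PlantedDMR(
                chrom=chrom,
                window_indices=tuple(range(start, start + width)),
                direction=direction,
                fold=config.effect_fold,
            )
        )
    return planted


def simulate_counts(
    grid: WindowGrid,
    config: SimConfig,
    planted: list[PlantedDMR] | None = None,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Draw the (window x sample) NB count matrix.

    mu(w, j) = b(w) * f(j) * e(w, j) with baseline b(w), library factor f(j)
    (log-normal, mean 1, CV = libsize_cv) and e = fold (increase) or 1/fold
    (decrease) for case samples in planted windows, 1 otherwise.  Recorded
    library sizes are the realized column sums.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    planted = planted or []
    case_ids, control_ids = config.sample_ids()
    samples = case_ids + control_ids
    W, S = grid.n_windows, len(samples)

    if config.baseline_cv > 0:
        sigma = math.sqrt(math.log(1 + config.baseline_cv**2))
        b = config.base_mean_depth * rng.lognormal(-sigma**2 / 2, sigma, size=W)
    else:
        b = np.full(W, config.base_mean_depth)
    if config.libsize_cv > 0:
        sigma = math.sqrt(math.log(1 + config.libsize_cv**2))
        f = rng.lognormal(-sigma**2 / 2, sigma, size=S)
    else:
        f = np.ones(S)

    effect = np.ones((W, S))
    n_case = len(case_ids)
    for run in planted:
        idx = list(run.window_indices)
        fold = run.fold if run.direction == "increase" else 1.0 / run.fold
        effect[idx, :n_case] = fold

    mu = b[:, None] * f[None, :] * effect
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        y = rng.negative_binomial(r, r / (r + mu))
    else:
        y = rng.poisson(mu)

    counts = pd.DataFrame(y, index=grid.labels(), columns=samples)
    groups = {s: "case" for s in case_ids} | {s: "control" for s in control_ids}
    return CountMatrix.from_counts(counts, groups)


def simulate_reads(
    counts: CountMatrix,
    grid: WindowGrid,
    read_length: int = 100,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Expand a count matrix into per-sample read intervals.

    Each read's midpoint is uniform within its window, so re-counting with
    :func:`dmrscan.windows.count_reads` reproduces the matrix exactly.
    """
    if read_length > grid.window_size:
        raise ValueError("read_length must be <= window_size")
    if rng is None:
        rng = np.random.default_rng(0)
    half = read_length // 2
    w = grid.windows
    starts = w["start"].to_numpy()
    stops = w["stop"].to_numpy()
    chroms = w["chrom"].to_numpy()
    out: dict[str, pd.DataFrame] = {}
    for sample in counts.samples:
        col = counts.counts[sample].to_numpy()
        nz = np.nonzero(col)[0]
        rows_chrom, rows_start = [], []
        for i in nz:
            n = int(col[i])
            lo = max(starts[i], half)
            hi = stops[i]
            if lo >= hi:  # degenerate partial window at a chromosome start
                lo = starts[i]
            mids = rng.integers(lo, hi, size=n)
            rows_chrom.extend([chroms[i]] * n)
            rows_start.append(mids - half)
        rs = np.concatenate(rows_start) if rows_start else np.array([], dtype=int)
        out[sample] = pd.DataFrame(
            {"chrom": rows_chrom, "start": rs, "stop": rs + read_length}
        )
    return out


def simulate_dataset(config: SimConfig) -> SimResult:
    """One-stop deterministic generator: genome, grid, planted truth, counts."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    grid = tile_genome(config.chrom_lengths(), config.window_size)
    grid.attach_cpg(genome)
    planted = plant_dmrs(grid, config, rng)
    counts = simulate_counts(grid, config, planted, rng)
    return SimResult(config=config, genome=genome, grid=grid, planted=planted, counts=counts)
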