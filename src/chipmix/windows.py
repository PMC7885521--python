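"""Genome windowing, per-window read counting, and depth normalization.

The background-weight regression operates on read counts in sliding
windows (default 200 bp windows every 50 bp, so each base is covered by
up to four windows). A read is assigned to every window containing its
5' end, and counts are put on a common scale by reads-per-billion
normalization: ``n = r * 1e9 / total_read_count``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeTable
from .reads import MappedReadSet

RPB = 1_000_000_000  # reads-per-billion normalization constant


@dataclass(frozen=True)
class WindowGrid:
    """Sliding windows tiling each chromosome from 0.

    Per chromosome the window starts are 0, step, 2*step, ...; every
    window has the nominal size except the final one, which is truncated
    at the chromosome end. A chromosome shorter than one window gets a
    single truncated window.
    """

    genome: GenomeTable
    window_size: int = 200
    step: int = 50

    def __post_init__(self):
        if not 0 < self.step <= self.window_size:
            raise ValueError(
                "require 0 < step <= window_size; larger steps would leave "
                "gaps and silently drop reads")

    def chrom_windows(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome."""
        length = self.genome.length(chrom)
        n = self.n_windows(chrom)
        starts = np.arange(n, dtype=np.int64) * self.step
        ends = np.minimum(starts + self.window_size, length)
        return starts, ends

    def n_windows(self, chrom: str) -> int:
        length = self.genome.length(chrom)
        if length <= self.window_size:
            return 1
        return int(-(-(length - self.window_size) // self.step)) + 1

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.genome.names)


def make_grid(genome: GenomeTable, window_size: int = 200, step: int = 50) -> WindowGrid:
    return WindowGrid(genome, window_size, step)


def count_reads_in_windows(rs: MappedReadSet, grid: WindowGrid) -> np.ndarray:
    """Raw count row: reads whose 5' end falls in each window.

    The assignment point is the 5' base of the read (start for +, end-1
    for -), so each read contributes to every window covering that single
    base — at most window_size/step windows.
    """
    rows = []
    df = rs.reads
    fwd = df["strand"].to_numpy() == "+"
    point = np.where(fwd, df["start"].to_numpy(), df["end"].to_numpy() - 1)
    chrom_arr = df["chrom"].to_numpy()
    for chrom in grid.genome.names:
        pts = np.sort(point[chrom_arr == chrom])
        starts, ends = grid.chrom_windows(chrom)
        counts = np.searchsorted(pts, ends, side="left") - \
            np.searchsorted(pts, starts, side="left")
        rows.append(counts.astype(np.int64))
    return np.concatenate(rows)


def normalize_rpb(raw: np.ndarray, total_read_count: int) -> np.ndarray:
    """Reads-per-billion: n = r * 1e9 / total. Exact and invertible."""
    if total_read_count <= 0:
        raise ValueError("cannot normalize empty sample")
    return np.asarray(raw, dtype=float) * (RPB / total_read_count)


@dataclass
class WindowCountMatrix:
    """Raw and normalized window counts for k controls plus one treatment.

    Rows are samples (controls first, treatment last), columns are the
    windows of ``grid`` in genome order.
    """

    grid: WindowGrid
    raw_counts: np.ndarray          # (k+1, n_windows) int
    totals: np.ndarray              # (k+1,) total reads per sample
    sample_ids: list[str]

    @property
    def n_controls(self) -> int:
        return self.raw_counts.shape[0] - 1

    @property
    def treatment_index(self) -> int:
        return self.raw_counts.shape[0] - 1

    @property
    def normalized(self) -> np.ndarray:
        return np.vstack([
            normalize_rpb(self.raw_counts[m], self.totals[m])
            for m in range(self.raw_counts.shape[0])
        ])

    @property
    def control_ids(self) -> list[str]:
        return self.sample_ids[:-1]


def build_count_matrix(controls: list[MappedReadSet], treatment: MappedReadSet,
                       grid: WindowGrid) -> WindowCountMatrix:
    samples = list(controls) + [treatment]
    raw = np.vstack([count_reads_in_windows(rs, grid) for rs in samples])
    totals = np.array([rs.total_read_count for rs in samples], dtype=np.int64)
    return WindowCountMatrix(grid, raw, totals, [rs.sample_id for rs in samples])
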