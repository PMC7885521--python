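"""Piecewise-constant genome tracks and weighted control construction.

The treatment track is fragment coverage: each read extended from its 5'
end in the 3' direction to the fragment length ``d``. The combined
control track is built by streaming over controls one at a time: each
control's read starts are smoothed by symmetric ("bidirectional")
extension at three length scales (d, 1 kb, 10 kb), depth-scaled to the
treatment, scaled by its mixture weight, and accumulated. The final
background is the pointwise maximum of the genome-wide expected density
``lambda_BG`` and the three accumulated scale tracks, all expressed in
expected fragments per d-sized window (the local-lambda convention — the
1 kb and 10 kb tracks carry an extra factor d/s so every candidate in
the max is on treatment-fragment units).

Tracks are stored per chromosome as (interval end positions, heights):
``heights[i]`` holds on ``[ends[i-1], ends[i])`` with an implicit start
at 0 and the last end at the chromosome length. Dense per-base arrays
appear only in test oracles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .genome import GenomeTable
from .reads import MappedReadSet

log = logging.getLogger(__name__)

DEFAULT_SCALES = (1_000, 10_000)  # smoothing scales beyond d, in bp


@dataclass
class PileupTrack:
    genome: GenomeTable
    chrom_data: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (ends, heights)
    scale: str = ""

    @classmethod
    def constant(cls, genome: GenomeTable, value: float, scale: str = "") -> "PileupTrack":
        data = {c: (np.array([l], dtype=np.int64), np.array([float(value)]))
                for c, l in genome.chroms}
        return cls(genome, data, scale)

    @classmethod
    def from_intervals(cls, genome: GenomeTable, chrom: str | np.ndarray,
                       starts, ends, weights=None, scale: str = "") -> "PileupTrack":
        """Sum of weighted indicator functions of intervals, clipped to the
        chromosome. Accepts one chrom name for all intervals or an array."""
        starts = np.asarray(starts, dtype=np.int64)
        ends_arr = np.asarray(ends, dtype=np.int64)
        if weights is None:
            weights = np.ones(len(starts))
        else:
            weights = np.broadcast_to(np.asarray(weights, dtype=float), starts.shape)
        if isinstance(chrom, str):
            chrom = np.full(len(starts), chrom, dtype=object)
        else:
            chrom = np.asarray(chrom, dtype=object)
        data = {}
        for name, length in genome.chroms:
            sel = chrom == name
            data[name] = _events_to_track(
                starts[sel], ends_arr[sel], weights[sel], length)
        return cls(genome, data, scale)

    def heights_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Track value at each (0-based) position."""
        ends, vals = self.chrom_data[chrom]
        idx = np.searchsorted(ends, np.asarray(pos), side="right")
        return vals[np.minimum(idx, len(vals) - 1)]

    def integral(self) -> float:
        total = 0.0
        for ends, vals in self.chrom_data.values():
            widths = np.diff(ends, prepend=0)
            total += float(vals @ widths)
        return total

    def max_value(self) -> float:
        return max(float(v.max()) for _, v in self.chrom_data.values())

    def min_value(self) -> float:
        return min(float(v.min()) for _, v in self.chrom_data.values())

    def dense(self, chrom: str) -> np.ndarray:
        """Per-base array for one chromosome (small genomes / debugging)."""
        ends, vals = self.chrom_data[chrom]
        return np.repeat(vals, np.diff(ends, prepend=0))

    def scaled(self, factor: float) -> "PileupTrack":
        return PileupTrack(self.genome,
                           {c: (e, v * factor) for c, (e, v) in self.chrom_data.items()},
                           self.scale)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.genome.names:
                ends, vals = self.chrom_data[chrom]
                start = 0
                for end, val in zip(ends.tolist(), vals.tolist()):
                    fh.write(f"{chrom}\t{start}\t{end}\t{val:.5f}\n")
                    start = end


def _events_to_track(starts, ends, weights, length: int):
    """Event sweep: +w at each clipped start, -w at each clipped end."""
    starts = np.clip(starts, 0, length)
    ends = np.clip(ends, 0, length)
    keep = starts < ends
    starts, ends, weights = starts[keep], ends[keep], weights[keep]
    if len(starts) == 0:
        return np.array([length], dtype=np.int64), np.zeros(1)
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([weights, -weights])
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    uniq, idx = np.unique(pos, return_index=True)
    sums = np.add.reduceat(delta, idx)
    heights = np.cumsum(sums)
    # heights[i] holds on [uniq[i], uniq[i+1]); re-express as end-anchored
    track_ends = np.append(uniq[1:], length)
    track_vals = heights
    if uniq[0] > 0:
        track_ends = np.insert(track_ends, 0, uniq[0])
        track_vals = np.insert(track_vals, 0, 0.0)
    if track_ends[-1] != length:  # all events end before chrom end
        track_ends = np.append(track_ends, length)
        track_vals = np.append(track_vals, 0.0)
    # drop zero-width segments and tidy float noise at interval ends
    keep = np.diff(track_ends, prepend=0) > 0
    track_vals = np.where(np.abs(track_vals) < 1e-12, 0.0, track_vals)
    return track_ends[keep], track_vals[keep]


def _merge_chrom(a_ends, a_vals, b_ends, b_vals, op):
    ends = np.union1d(a_ends, b_ends)
    ai = np.searchsorted(a_ends, ends, side="left")
    bi = np.searchsorted(b_ends, ends, side="left")
    vals = op(a_vals[np.minimum(ai, len(a_vals) - 1)],
              b_vals[np.minimum(bi, len(b_vals) - 1)])
    # compact runs of equal value
    keep = np.ones(len(ends), dtype=bool)
    keep[:-1] = vals[:-1] != vals[1:]
    return ends[keep], vals[keep]


def track_combine(a: PileupTrack, b: PileupTrack, op, scale: str = "") -> PileupTrack:
    data = {c: _merge_chrom(*a.chrom_data[c], *b.chrom_data[c], op)
            for c in a.genome.names}
    return PileupTrack(a.genome, data, scale)


def track_add(a: PileupTrack, b: PileupTrack) -> PileupTrack:
    return track_combine(a, b, np.add)


def track_max(tracks: list[PileupTrack], scale: str = "combined") -> PileupTrack:
    out = reduce(lambda x, y: track_combine(x, y, np.maximum), tracks)
    out.scale = scale
    return out


@dataclass(frozen=True)
class FragmentLength:
    d: int
    source: str  # "user-fixed" | "estimated"

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("fragment length must be positive")


@dataclass(frozen=True)
class BackgroundLambda:
    """Genome-wide expected fragment coverage per base."""

    lambda_bg: float

    @classmethod
    def from_treatment(cls, treatment_total: int, d: int,
                       effective_genome_size: int) -> "BackgroundLambda":
        if treatment_total <= 0:
            raise ValueError("lambda_BG undefined for empty treatment")
        return cls(treatment_total * d / effective_genome_size)


def estimate_fragment_length(rs: MappedReadSet, mfold=(5, 50), tag_size: int = 50,
                             bandwidth: int = 300, fallback_d: int | None = None,
                             min_regions: int = 100) -> FragmentLength:
    """Paired-peak fragment-length model.

    Scans windows of width 2*bandwidth for regions whose 5'-end count is
    within ``mfold`` of the genome-wide expectation, then measures, per
    candidate region, the separation between the median + strand and
    median - strand 5' positions; ``d`` is the mean separation. With
    fewer than ``min_regions`` usable regions the estimate is considered
    unreliable and the user-supplied fallback is used instead (error if
    none was given). Deterministic given the input reads.
    """
    genome = rs.genome
    width = 2 * bandwidth
    lam = rs.total_read_count * width / genome.effective_genome_size
    lo, hi = mfold[0] * lam, mfold[1] * lam

    df = rs.reads
    fwd = df["strand"].to_numpy() == "+"
    five = np.where(fwd, df["start"].to_numpy(), df["end"].to_numpy())
    chrom_arr = df["chrom"].to_numpy()

    seps = []
    for chrom, length in genome.chroms:
        sel = chrom_arr == chrom
        p5, is_fwd = five[sel], fwd[sel]
        if len(p5) == 0:
            continue
        order = np.argsort(p5, kind="stable")
        p5, is_fwd = p5[order], is_fwd[order]
        starts = np.arange(0, max(length - width, 0) + 1, bandwidth, dtype=np.int64)
        counts = np.searchsorted(p5, starts + width) - np.searchsorted(p5, starts)
        cand = (counts >= lo) & (counts <= hi)
        if not np.any(cand):
            continue
        # merge overlapping candidate windows into regions
        idx = np.flatnonzero(cand)
        breaks = np.flatnonzero(np.diff(idx) > 2)  # windows > 1 step apart
        groups = np.split(idx, breaks + 1)
        for g in groups:
            rs_, re_ = starts[g[0]], starts[g[-1]] + width
            lo_i, hi_i = np.searchsorted(p5, (rs_, re_))
            pf = p5[lo_i:hi_i][is_fwd[lo_i:hi_i]]
            pr = p5[lo_i:hi_i][~is_fwd[lo_i:hi_i]]
            if len(pf) < 5 or len(pr) < 5:
                continue
            sep = float(np.median(pr)) - float(np.median(pf))
            if 0 < sep <= 2 * width:
                seps.append(sep)

    if len(seps) >= min_regions:
        d = int(round(float(np.mean(seps))))
        if d >= 2 * tag_size:
            return FragmentLength(d, "estimated")
        log.warning("estimated d=%d < 2*tag_size; falling back", d)
    else:
        log.warning("only %d paired-peak regions (< %d); falling back",
                    len(seps), min_regions)
    if fallback_d is None:
        raise ValueError(
            "fragment-length model failed and no fallback --extsize given")
    warnings.warn("fragment-length model unreliable; using fallback d="
                  f"{fallback_d}", stacklevel=2)
    return FragmentLength(fallback_d, "user-fixed")


def pileup_treatment(rs: MappedReadSet, d: FragmentLength) -> PileupTrack:
    """Fragment coverage: each read extended to length d from its 5' end
    in the 3' direction (+: [start, start+d); -: [end-d, end))."""
    df = rs.reads
    fwd = df["strand"].to_numpy() == "+"
    start = np.where(fwd, df["start"].to_numpy(), df["end"].to_numpy() - d.d)
    end = start + d.d
    return PileupTrack.from_intervals(
        rs.genome, df["chrom"].to_numpy(), start, end, scale="treatment-d")


def bidirection_extend(rs: MappedReadSet, scale_bp: int, weight: float = 1.0) -> PileupTrack:
    """Parzen box smoothing: each read's 5' end extended symmetrically to
    an interval of total width (diameter) ``scale_bp``; odd widths place
    the extra base 3'-ward."""
    if scale_bp <= 0:
        raise ValueError("scale must be positive")
    df = rs.reads
    fwd = df["strand"].to_numpy() == "+"
    five = np.where(fwd, df["start"].to_numpy(), df["end"].to_numpy())
    half = scale_bp // 2
    start = np.where(fwd, five - half, five - (scale_bp - half))
    end = start + scale_bp
    return PileupTrack.from_intervals(
        rs.genome, df["chrom"].to_numpy(), start, end,
        weights=weight, scale=f"control-{scale_bp}")


def build_weighted_control(controls: list[MappedReadSet], weights, d: FragmentLength,
                           treatment_total: int, lambda_bg: BackgroundLambda,
                           scales: tuple[int, ...] = DEFAULT_SCALES,
                           return_parts: bool = False):
    """Weighted, multi-scale control background, streamed one control at
    a time.

    For each smoothing scale s in {d} + scales, the accumulator is

        accum_s = sum_j theta_j * (treatment_total / total_j) * (d / s)
                         * bidirection_extend(control_j, s)

    and the combined track is the pointwise max of lambda_BG and the
    per-scale accumulators. Only one control's reads are needed in memory
    at a time beyond the accumulator tracks.
    """
    theta = np.asarray(getattr(weights, "theta", weights), dtype=float)
    if len(controls) != len(theta):
        raise ValueError(
            f"{len(controls)} controls but {len(theta)} weights")
    genome = controls[0].genome
    all_scales = (d.d,) + tuple(scales)
    accums = [PileupTrack.constant(genome, 0.0, scale=f"control-{s}")
              for s in all_scales]
    if np.all(theta == 0):
        warnings.warn("all control weights are zero; background is the "
                      "genome-wide lambda_BG only", stacklevel=2)
    for ctrl, w in zip(controls, theta):
        if w == 0:
            continue
        depth_scale = treatment_total / ctrl.total_read_count
        for si, s in enumerate(all_scales):
            factor = w * depth_scale * (d.d / s)
            accums[si] = track_add(accums[si],
                                   bidirection_extend(ctrl, s, weight=factor))
        log.info("control %s: total=%d weight=%.6g depth_scale=%.4g",
                 ctrl.sample_id, ctrl.total_read_count, w, depth_scale)
    floor = PileupTrack.constant(genome, lambda_bg.lambda_bg)
    combined = track_max([floor] + accums)
    if return_parts:
        return combined, accums
    return combined
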