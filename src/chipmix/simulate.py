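"""Synthetic ChIP-seq fixture generation.

The generator emulates the structure the weighted-control model assumes:
each control sample has its own smooth background bias profile (a mixture
of wide Gaussian bumps over a positive baseline, standing in for
chromatin-accessibility / GC / mappability biases), the treatment's
background reads are drawn from a known nonnegative mixture of those
profiles, and true binding is spiked in as fragments centered inside
known peak intervals at a chosen fold enrichment over the genome-wide
background density.

Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeTable
from .reads import MappedReadSet, from_arrays

_GRID = 100  # bp resolution at which profiles are discretized for sampling


@dataclass(frozen=True)
class GaussianBump:
    chrom: str
    center: float
    sd: float
    amplitude: float


@dataclass(frozen=True)
class ControlProfile:
    """Smooth positive read-density profile: baseline plus Gaussian bumps."""

    bumps: tuple[GaussianBump, ...]
    baseline: float = 1.0

    def bin_masses(self, genome: GenomeTable) -> dict[str, np.ndarray]:
        """Unnormalized probability mass per _GRID-bp bin, per chromosome."""
        out = {}
        for chrom, length in genome.chroms:
            n_bins = -(-length // _GRID)
            centers = (np.arange(n_bins) + 0.5) * _GRID
            dens = np.full(n_bins, self.baseline, dtype=float)
            for b in self.bumps:
                if b.chrom != chrom:
                    continue
                dens += b.amplitude * np.exp(-0.5 * ((centers - b.center) / b.sd) ** 2)
            out[chrom] = dens
        return out


def random_profiles(genome: GenomeTable, k: int, seed: int,
                    n_bumps: int = 15, sd_range=(5_000, 50_000),
                    amplitude_range=(2.0, 10.0),
                    baseline: float = 0.5) -> list[ControlProfile]:
    """Draw k distinct smooth bias profiles over the genome."""
    rng = np.random.default_rng(seed)
    lengths = np.array([l for _, l in genome.chroms], dtype=float)
    p_chrom = lengths / lengths.sum()
    profiles = []
    for _ in range(k):
        bumps = []
        for _ in range(n_bumps):
            ci = rng.choice(len(lengths), p=p_chrom)
            chrom, length = genome.chroms[ci]
            bumps.append(GaussianBump(
                chrom=chrom,
                center=float(rng.uniform(0, length)),
                sd=float(rng.uniform(*sd_range)),
                amplitude=float(rng.uniform(*amplitude_range)),
            ))
        profiles.append(ControlProfile(tuple(bumps), baseline=baseline))
    return profiles


@dataclass(frozen=True)
class SpikedPeak:
    chrom: str
    start: int
    end: int
    fold: float  # enrichment of fragment density over lambda_BG


def spike_grid(genome: GenomeTable, n: int, width: int, fold: float,
               seed: int, margin: int = 20_000) -> list[SpikedPeak]:
    """n well-separated peak intervals of the given width, jittered on a grid."""
    rng = np.random.default_rng(seed)
    usable = [(c, l - 2 * margin) for c, l in genome.chroms if l > 2 * margin + width]
    total = sum(u for _, u in usable)
    per_chrom = [max(1, round(n * u / total)) for _, u in usable]
    # adjust rounding so the total is exactly n
    while sum(per_chrom) > n:
        per_chrom[int(np.argmax(per_chrom))] -= 1
    while sum(per_chrom) < n:
        per_chrom[int(np.argmax([u for _, u in usable]))] += 1
    peaks = []
    for (chrom, usable_len), m in zip(usable, per_chrom):
        slot = usable_len / m
        for i in range(m):
            jitter = rng.uniform(0.15, 0.85)
            start = int(margin + i * slot + jitter * (slot - width))
            peaks.append(SpikedPeak(chrom, start, start + width, fold))
    return peaks


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic treatment-plus-controls dataset."""

    genome: GenomeTable
    profiles: tuple[ControlProfile, ...]
    weights: tuple[float, ...]          # true mixture over control profiles
    control_depths: tuple[int, ...]
    treatment_depth: int                # background reads in the treatment
    peaks: tuple[SpikedPeak, ...] = ()
    fragment_length: int = 200
    tag_size: int = 50


@dataclass(frozen=True)
class FixtureTruth:
    weights: tuple[float, ...]
    peaks: tuple[SpikedPeak, ...]
    fragment_length: int


@dataclass(frozen=True)
class Fixture:
    controls: list[MappedReadSet]
    treatment: MappedReadSet
    truth: FixtureTruth


def _sample_positions(masses: dict[str, np.ndarray], n: int, rng,
                      genome: GenomeTable):
    """Sample n genomic positions from a binned density. Returns (chroms, pos)."""
    names = genome.names
    flat = np.concatenate([masses[c] for c in names])
    p = flat / flat.sum()
    bins = rng.choice(len(flat), size=n, p=p)
    offsets = rng.uniform(0, _GRID, size=n)
    # map flat bin index back to (chrom, bin-within-chrom)
    sizes = np.array([len(masses[c]) for c in names])
    edges = np.concatenate([[0], np.cumsum(sizes)])
    ci = np.searchsorted(edges, bins, side="right") - 1
    pos = (bins - edges[ci]) * _GRID + offsets
    chroms = np.asarray(names, dtype=object)[ci]
    # clip inside each chromosome
    lens = np.array([genome.length(c) for c in names], dtype=float)[ci]
    pos = np.minimum(pos, lens - 1e-9)
    return chroms, pos


def _reads_from_five_prime(chroms, five, strands, tag: int, genome: GenomeTable):
    """Build read intervals from 5' coordinates (+: start; -: exclusive end)."""
    lens = np.array([genome.length(c) for c in chroms], dtype=np.int64)
    five = np.asarray(np.round(five), dtype=np.int64)
    fwd = strands == "+"
    # keep the 5' anchor inside the chromosome with room for the tag
    five = np.where(fwd, np.clip(five, 0, lens - tag), np.clip(five, tag, lens))
    start = np.where(fwd, five, five - tag)
    end = start + tag
    return chroms, start, end, strands


def generate_fixture(spec: FixtureSpec, seed: int) -> Fixture:
    """Generate control and treatment read sets plus ground truth.

    Treatment background reads are drawn from the density
    ``sum_j w_j * profile_j`` (normalized), so the expected fitted mixture
    weights equal ``w / sum(w)``. Spiked peaks add fragments whose centers
    are uniform inside each truth interval, at a rate giving the requested
    fold enrichment of fragment coverage over the genome-wide background
    density lambda_BG = treatment_depth * d / effective_genome_size.
    """
    k = len(spec.profiles)
    if len(spec.weights) != k or len(spec.control_depths) != k:
        raise ValueError("profiles, weights and control_depths must align")
    if any(w < 0 for w in spec.weights):
        raise ValueError("mixture weights must be nonnegative")
    if spec.treatment_depth <= 0 or any(d <= 0 for d in spec.control_depths):
        raise ValueError("read depths must be positive")

    rng = np.random.default_rng(seed)
    genome = spec.genome
    tag = spec.tag_size
    d = spec.fragment_length
    masses = [p.bin_masses(genome) for p in spec.profiles]
    # normalize each profile to a probability mass before mixing
    norm_masses = []
    for m in masses:
        total = sum(v.sum() for v in m.values())
        norm_masses.append({c: v / total for c, v in m.items()})

    controls = []
    for j, (nm, depth) in enumerate(zip(norm_masses, spec.control_depths)):
        chroms, pos = _sample_positions(nm, depth, rng, genome)
        strands = np.where(rng.random(depth) < 0.5, "+", "-").astype(object)
        controls.append(from_arrays(
            f"control{j + 1}", *_reads_from_five_prime(chroms, pos, strands, tag, genome),
            genome=genome))

    w = np.asarray(spec.weights, dtype=float)
    mix = {c: sum(w[j] * norm_masses[j][c] for j in range(k))
           for c in genome.names}
    chroms, pos = _sample_positions(mix, spec.treatment_depth, rng, genome)
    strands = np.where(rng.random(spec.treatment_depth) < 0.5, "+", "-").astype(object)
    t_parts = [_reads_from_five_prime(chroms, pos, strands, tag, genome)]

    if spec.peaks:
        lam_bg = spec.treatment_depth * d / genome.effective_genome_size
        for pk in spec.peaks:
            width = pk.end - pk.start
            n_pk = int(round(pk.fold * lam_bg * width / d))
            centers = rng.uniform(pk.start, pk.end, size=n_pk)
            s = np.where(rng.random(n_pk) < 0.5, "+", "-").astype(object)
            five = np.where(s == "+", centers - d // 2, centers + (d - d // 2))
            t_parts.append(_reads_from_five_prime(
                np.full(n_pk, pk.chrom, dtype=object), five, s, tag, genome))

    chroms = np.concatenate([p[0] for p in t_parts])
    starts = np.concatenate([p[1] for p in t_parts])
    ends = np.concatenate([p[2] for p in t_parts])
    strands = np.concatenate([p[3] for p in t_parts])
    treatment = from_arrays("treatment", chroms, starts, ends, strands, genome=genome)

    truth = FixtureTruth(tuple(spec.weights), tuple(spec.peaks), d)
    return Fixture(controls, treatment, truth)
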