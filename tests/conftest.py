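import numpy as np
import pytest

import chipmix as cm


def make_reads(genome, rows, sample_id="sample"):
    """Read set from (chrom, start, end, strand) tuples."""
    chrom, start, end, strand = zip(*rows)
    return cm.from_arrays(sample_id, chrom, start, end, strand, genome=genome)


@pytest.fixture(scope="session")
def tiny_genome():
    return cm.GenomeTable.from_dict({"chr1": 400, "chr2": 150})


@pytest.fixture(scope="session")
def toy_genome():
    """100 kb single-chromosome genome for dense-array oracles."""
    return cm.GenomeTable.from_dict({"chr1": 100_000})


@pytest.fixture(scope="session")
def mb_genome():
    return cm.GenomeTable.from_dict({"chr1": 1_000_000})


def random_reads(genome, n, rng, tag=50):
    """Uniform random reads across the genome (edges included)."""
    names = genome.names
    lens = np.array([genome.length(c) for c in names])
    ci = rng.integers(0, len(names), size=n)
    five = rng.integers(0, lens[ci], size=n)
    strand = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    fwd = strand == "+"
    start = np.where(fwd, np.minimum(five, lens[ci] - tag),
                     np.maximum(five, tag) - tag)
    end = start + tag
    return cm.from_arrays("rand", np.asarray(names, dtype=object)[ci],
                          start, end, strand, genome=genome)


@pytest.fixture(scope="session")
def peakfree_fixture(mb_genome):
    """Three controls with distinct bias profiles and a treatment whose
    background is the known mixture (0.6, 0.3, 0.1); no spiked peaks."""
    profiles = tuple(cm.random_profiles(mb_genome, 3, seed=101))
    spec = cm.FixtureSpec(mb_genome, profiles, (0.6, 0.3, 0.1),
                          (2_000_000,) * 3, 2_000_000, (), fragment_length=200)
    return cm.generate_fixture(spec, seed=11), spec


@pytest.fixture(scope="session")
def spiked_fixture(mb_genome):
    """One control, treatment with 30 spiked peaks at 10-fold enrichment."""
    profiles = tuple(cm.random_profiles(mb_genome, 1, seed=202))
    peaks = tuple(cm.spike_grid(mb_genome, 30, 400, 10.0, seed=203))
    spec = cm.FixtureSpec(mb_genome, profiles, (1.0,), (150_000,),
                          150_000, peaks, fragment_length=200)
    return cm.generate_fixture(spec, seed=12), spec
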