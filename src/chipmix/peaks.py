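"""Candidate-region scoring and peak calling.

Enrichment is tested per position with an upper-tail Poisson test: the
treatment fragment coverage at a position is compared against the local
background mean given by the combined control track. Because both tracks
are piecewise constant, the test is evaluated once per interval of their
merged breakpoint set (float-identical to per-base evaluation). q-values
are Benjamini-Hochberg adjusted with each distinct p weighted by the
number of bases carrying it — every base is one test, genome-wide.
Positions passing the q cutoff are merged across gaps up to ``max_gap``
and regions shorter than ``min_length`` are dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .genome import GenomeTable
from .pileup import PileupTrack, track_combine

_LN10 = np.log(10.0)


def _poisson_p(treat: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """P(X >= treat) for X ~ Poisson(mean); treat rounded to integer."""
    t = np.round(np.asarray(treat)).astype(np.int64)
    return scipy.stats.poisson.sf(t - 1, np.asarray(mean))


def _poisson_neglog10p(treat: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """-log10 P(X >= treat), computed in log space to survive underflow."""
    t = np.round(np.asarray(treat)).astype(np.int64)
    return -scipy.stats.poisson.logsf(t - 1, np.asarray(mean)) / _LN10


def score_positions(treatment: PileupTrack, control: PileupTrack) -> PileupTrack:
    """Piecewise-constant track of upper-tail Poisson p-values."""
    return track_combine(treatment, control, _poisson_p, scale="pvalue")


def _bh_neglog10(nlp: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """bp-weighted Benjamini-Hochberg on the -log10 scale.

    Each interval contributes ``lengths`` tests at significance
    ``10**-nlp``; returns -log10 q per interval.
    """
    total = float(lengths.sum())
    # unique significance levels, most significant first
    uniq, inv = np.unique(-nlp, return_inverse=True)
    uniq = -uniq  # descending nlp == ascending p
    bp = np.zeros(len(uniq))
    np.add.at(bp, inv, lengths)
    # reorder to ascending p
    order = np.arange(len(uniq))
    cum = np.cumsum(bp)
    raw = uniq - np.log10(total / cum)      # -log10 (p * total / rank)
    # enforce monotonicity: q non-decreasing with p
    nlq_u = np.maximum.accumulate(raw[::-1])[::-1]
    nlq_u = np.maximum(nlq_u, 0.0)          # q <= 1
    del order
    return nlq_u[inv]


def compute_qvalues(p_track: PileupTrack) -> PileupTrack:
    """BH-adjusted q-value track over all chromosomes, bp-weighted."""
    chroms = p_track.genome.names
    nlp_parts, len_parts, split = [], [], []
    for c in chroms:
        ends, pv = p_track.chrom_data[c]
        with np.errstate(divide="ignore"):
            nlp_parts.append(-np.log10(np.maximum(pv, 1e-323)))
        len_parts.append(np.diff(ends, prepend=0).astype(float))
        split.append(len(ends))
    nlq = _bh_neglog10(np.concatenate(nlp_parts), np.concatenate(len_parts))
    out, at = {}, 0
    for c, n in zip(chroms, split):
        ends, _ = p_track.chrom_data[c]
        out[c] = (ends, 10.0 ** -nlq[at:at + n])
        at += n
    return PileupTrack(p_track.genome, out, scale="qvalue")


@dataclass
class PeakSet:
    """Scored, sorted, non-overlapping enriched intervals.

    ``peaks`` columns: chrom, start, end, summit (bp offset within the
    peak of the maximal treatment pileup), pileup_height,
    fold_enrichment, neglog10_p, neglog10_q.
    """

    sample_id: str
    peaks: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def param_digest(self) -> str:
        blob = json.dumps(self.params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_PEAK_COLS = ["chrom", "start", "end", "summit", "pileup_height",
              "fold_enrichment", "neglog10_p", "neglog10_q"]


def call_peaks(treatment: PileupTrack, control: PileupTrack, q_cutoff: float = 0.05,
               min_length: int = 200, max_gap: int = 50,
               sample_id: str = "sample", params: dict | None = None) -> PeakSet:
    """Call peaks where the BH q-value is at or below ``q_cutoff``.

    Significant intervals separated by gaps of at most ``max_gap`` bp are
    merged; merged regions shorter than ``min_length`` are dropped. The
    summit is the leftmost position of maximal treatment pileup inside
    the peak, and the reported p/q are the values at the summit.
    """
    genome = treatment.genome
    # aligned (ends, treatment, control) per chromosome
    aligned = {}
    for c in genome.names:
        te, tv = treatment.chrom_data[c]
        ce, cv = control.chrom_data[c]
        ends = np.union1d(te, ce)
        ti = np.minimum(np.searchsorted(te, ends, side="left"), len(tv) - 1)
        ci = np.minimum(np.searchsorted(ce, ends, side="left"), len(cv) - 1)
        aligned[c] = (ends, tv[ti], cv[ci])

    nlp_all = [ _poisson_neglog10p(tv, cv) for (_, tv, cv) in aligned.values() ]
    len_all = [np.diff(ends, prepend=0).astype(float)
               for (ends, _, _) in aligned.values()]
    nlq_all = _bh_neglog10(np.concatenate(nlp_all), np.concatenate(len_all))
    nlq_cut = -np.log10(q_cutoff)

    rows = []
    at = 0
    for c, (ends, tv, cv) in aligned.items():
        n = len(ends)
        nlq = nlq_all[at:at + n]
        nlp = nlp_all[list(aligned).index(c)]
        at += n
        starts = np.concatenate([[0], ends[:-1]])
        sig = nlq >= nlq_cut
        if not np.any(sig):
            continue
        idx = np.flatnonzero(sig)
        # merge significant intervals across gaps <= max_gap
        region_start = starts[idx[0]]
        region_end = ends[idx[0]]
        regions = []
        for i in idx[1:]:
            if starts[i] - region_end <= max_gap:
                region_end = ends[i]
            else:
                regions.append((region_start, region_end))
                region_start, region_end = starts[i], ends[i]
        regions.append((region_start, region_end))
        for rs_, re_ in regions:
            if re_ - rs_ < min_length:
                continue
            lo = np.searchsorted(ends, rs_, side="right")
            hi = np.searchsorted(ends, re_, side="left") + 1
            seg_t = tv[lo:hi]
            best = int(np.argmax(seg_t))           # leftmost maximal interval
            summit_pos = max(int(starts[lo + best]), int(rs_))
            rows.append((c, int(rs_), int(re_), summit_pos - int(rs_),
                         float(seg_t[best]), float(seg_t[best] / cv[lo + best]),
                         float(nlp[lo + best]), float(nlq[lo + best])))

    df = pd.DataFrame(rows, columns=_PEAK_COLS)
    return PeakSet(sample_id, df, params or {"q_cutoff": q_cutoff,
                                             "min_length": min_length,
                                             "max_gap": max_gap})


# ---------------------------------------------------------------- output

def write_narrowpeak(ps: PeakSet, path) -> None:
    """ENCODE narrowPeak: 10 columns, 0-based half-open, -log10 p/q in
    columns 8-9, summit offset in column 10."""
    with open(path, "w") as fh:
        for i, r in enumerate(ps.peaks.itertuples(index=False), 1):
            score = int(min(1000, round(10 * r.neglog10_q)))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{ps.sample_id}_peak_{i}\t"
                     f"{score}\t.\t{r.fold_enrichment:.5f}\t{r.neglog10_p:.5f}\t"
                     f"{r.neglog10_q:.5f}\t{r.summit}\n")


def write_xls(ps: PeakSet, path) -> None:
    """MACS-style tab-separated table with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("# peak calling results\n")
        for key in sorted(ps.params):
            fh.write(f"# {key} = {ps.params[key]}\n")
        fh.write("chr\tstart\tend\tlength\tabs_summit\tpileup\t"
                 "-log10(pvalue)\tfold_enrichment\t-log10(qvalue)\tname\n")
        for i, r in enumerate(ps.peaks.itertuples(index=False), 1):
            fh.write(f"{r.chrom}\t{r.start + 1}\t{r.end}\t{r.end - r.start}\t"
                     f"{r.start + r.summit + 1}\t{r.pileup_height:.2f}\t"
                     f"{r.neglog10_p:.5f}\t{r.fold_enrichment:.5f}\t"
                     f"{r.neglog10_q:.5f}\t{ps.sample_id}_peak_{i}\n")


def read_narrowpeak(path, sample_id: str | None = None) -> PeakSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: expected 10 narrowPeak columns")
            rows.append((f[0], int(f[1]), int(f[2]), int(f[9]), np.nan,
                         float(f[6]), float(f[7]), float(f[8])))
            if sample_id is None:
                sample_id = f[3].rsplit("_peak_", 1)[0]
    df = pd.DataFrame(rows, columns=_PEAK_COLS)
    return PeakSet(sample_id or "peaks", df)
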