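"""Peak-quality evaluation: standardization, motif precision, AUPRC,
and replicate reproducibility.

Comparing peak callers is confounded by the number and width of the
peaks each one emits. Standardization removes both effects: peaks are
re-expressed as the 1 kb genome bins they overlap (a peak spanning a bin
boundary counts once in each bin, each bin inheriting the best
overlapping peak's -log10 p), and every condition is truncated to the
top n bins where n is the smallest bin count among the conditions being
compared. Motif precision is the fraction of peaks (or bins) that
overlap at least one significant motif hit by >= 1 bp; motif-hit
intervals are consumed as precomputed BED, never scanned here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaks import PeakSet


@dataclass
class MotifHitSet:
    """Precomputed significant motif-match intervals (sorted, may overlap)."""

    intervals: pd.DataFrame  # chrom, start, end
    significance_cutoff: float | None = None

    @classmethod
    def from_bed(cls, path, significance_cutoff: float | None = None) -> "MotifHitSet":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
                rows.append((f[0], int(f[1]), int(f[2])))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        return cls(df, significance_cutoff)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class StandardizedPeakSet:
    """Width-standardized peaks: unique (chrom, bin_start) bins with the
    best overlapping source-peak score (-log10 p)."""

    source_id: str
    bin_width: int
    bins: pd.DataFrame  # chrom, bin_start, score

    @property
    def n_retained(self) -> int:
        return len(self.bins)

    def as_intervals(self) -> pd.DataFrame:
        df = self.bins.copy()
        df["start"] = df["bin_start"]
        df["end"] = df["bin_start"] + self.bin_width
        return df[["chrom", "start", "end"]]


def standardize_bins(ps: PeakSet, bin_width: int = 1000) -> StandardizedPeakSet:
    """Map each peak to every bin it overlaps.

    The end coordinate is exclusive: a peak ending exactly on a bin
    boundary does not enter the next bin. A peak [s, e) therefore covers
    bins floor(s/b)..floor((e-1)/b). Bins are deduplicated keeping the
    best -log10 p among overlapping peaks.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    records = []
    for r in ps.peaks.itertuples(index=False):
        first = (r.start // bin_width) * bin_width
        last = ((r.end - 1) // bin_width) * bin_width
        for b in range(first, last + bin_width, bin_width):
            records.append((r.chrom, b, float(r.neglog10_p)))
    df = pd.DataFrame(records, columns=["chrom", "bin_start", "score"])
    if len(df):
        df = (df.groupby(["chrom", "bin_start"], as_index=False)["score"].max()
                .sort_values(["chrom", "bin_start"], kind="stable")
                .reset_index(drop=True))
    return StandardizedPeakSet(ps.sample_id, bin_width, df)


def standardize_topn(binned: list[StandardizedPeakSet]) -> list[StandardizedPeakSet]:
    """Truncate every condition to its top n bins by score, where n is the
    smallest bin count among the conditions. Ties at the boundary break
    deterministically by (chrom, bin_start)."""
    if not binned:
        return []
    n = min(b.n_retained for b in binned)
    if n == 0:
        warnings.warn("a condition has no bins; all standardized sets are empty",
                      stacklevel=2)
    out = []
    for b in binned:
        df = (b.bins.sort_values(["score", "chrom", "bin_start"],
                                 ascending=[False, True, True], kind="stable")
                .head(n)
                .sort_values(["chrom", "bin_start"], kind="stable")
                .reset_index(drop=True))
        out.append(StandardizedPeakSet(b.source_id, b.bin_width, df))
    return out


def _overlap_flags(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """For each query interval, whether it shares >= 1 bp with any subject
    interval. Sorted sweep: per chromosome the subjects are sorted by
    start and a running maximum of ends answers each query in O(log n)."""
    flags = np.zeros(len(query), dtype=bool)
    q_chrom = query["chrom"].to_numpy()
    q_start = query["start"].to_numpy()
    q_end = query["end"].to_numpy()
    for chrom, sub in subject.groupby("chrom", sort=False):
        sel = np.flatnonzero(q_chrom == chrom)
        if len(sel) == 0:
            continue
        s_start = np.sort(sub["start"].to_numpy())
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        run_max_end = np.maximum.accumulate(sub["end"].to_numpy()[order])
        i = np.searchsorted(s_start, q_end[sel], side="left")
        has = i > 0
        has[has] = run_max_end[i[has] - 1] > q_start[sel[has]]
        flags[sel] = has
    return flags


def _peak_intervals(peaks) -> pd.DataFrame:
    if isinstance(peaks, StandardizedPeakSet):
        return peaks.as_intervals()
    return peaks.peaks[["chrom", "start", "end"]]


def motif_precision(peaks, hits: MotifHitSet) -> float:
    """Fraction of peaks (or standardized bins) overlapping >= 1 motif hit."""
    iv = _peak_intervals(peaks)
    if len(iv) == 0:
        raise ValueError("precision undefined for an empty peak set")
    return float(_overlap_flags(iv, hits.intervals).mean())


def precision_recall_curve(peaks, hits: MotifHitSet):
    """Precision-recall over a rank sweep of the peaks.

    Peaks are ranked by -log10 p (descending; ties by chrom, start). At
    each rank prefix, precision is the motif-hit fraction of the prefix
    and recall is the fraction of motif-hit intervals overlapped by at
    least one prefix peak. Returns (precision, recall, auprc); the area
    is trapezoidal over recall, anchored at recall 0.
    """
    if len(hits) == 0:
        raise ValueError("AUPRC undefined with zero motif hits")
    if isinstance(peaks, StandardizedPeakSet):
        iv = peaks.as_intervals().copy()
        iv["rank_score"] = peaks.bins["score"].to_numpy()
    else:
        iv = peaks.peaks[["chrom", "start", "end"]].copy()
        iv["rank_score"] = peaks.peaks["neglog10_p"].to_numpy()
    if len(iv) == 0:
        raise ValueError("AUPRC undefined for an empty peak set")
    iv = iv.sort_values(["rank_score", "chrom", "start"],
                        ascending=[False, True, True], kind="stable"
                        ).reset_index(drop=True)
    is_tp = _overlap_flags(iv, hits.intervals)

    # best (lowest) rank of a peak overlapping each hit interval
    n_hits = len(hits.intervals)
    best_rank = np.full(n_hits, len(iv), dtype=np.int64)
    h = hits.intervals.reset_index(drop=True)
    for chrom, sub in iv.groupby("chrom", sort=False):
        hsel = np.flatnonzero(h["chrom"].to_numpy() == chrom)
        if len(hsel) == 0:
            continue
        p_start = sub["start"].to_numpy()
        p_end = sub["end"].to_numpy()
        ranks = sub.index.to_numpy()
        order = np.argsort(p_start, kind="stable")
        p_start, p_end, ranks = p_start[order], p_end[order], ranks[order]
        for hi in hsel:
            s, e = h.at[hi, "start"], h.at[hi, "end"]
            lo = np.searchsorted(p_start, e, side="left")
            cand = (p_end[:lo] > s)
            if np.any(cand):
                best_rank[hi] = ranks[:lo][cand].min()

    r = np.arange(1, len(iv) + 1)
    precision = np.cumsum(is_tp) / r
    recovered = np.array([(best_rank < k).sum() for k in r])
    recall = recovered / n_hits
    auprc = float(np.trapezoid(np.concatenate([[precision[0]], precision]),
                               np.concatenate([[0.0], recall])))
    return precision, recall, auprc


def replicate_overlap(a: PeakSet, b: PeakSet) -> float:
    """Percentage of a's peaks overlapping >= 1 of b's peaks.

    Asymmetric by construction; report both directions (and their mean)
    when summarizing replicate reproducibility.
    """
    if len(a) == 0:
        raise ValueError("replicate overlap undefined for an empty peak set")
    flags = _overlap_flags(a.peaks[["chrom", "start", "end"]],
                           b.peaks[["chrom", "start", "end"]])
    return float(100.0 * flags.mean())


def quality_report(conditions: dict[str, PeakSet], hits: MotifHitSet | None = None,
                   replicates: dict[str, PeakSet] | None = None,
                   bin_width: int = 1000, standardize: bool = True) -> pd.DataFrame:
    """Per-condition summary table: peak/bin counts, motif precision and
    AUPRC (when hits are given), replicate overlap (when replicates are
    given), for all peaks and, optionally, standardized peaks."""
    names = list(conditions)
    binned = {n: standardize_bins(conditions[n], bin_width) for n in names}
    std = dict(zip(names, standardize_topn([binned[n] for n in names]))) \
        if standardize else {}
    rows = []
    for n in names:
        row = {"condition": n, "n_peaks": len(conditions[n]),
               "n_bins": binned[n].n_retained,
               "n_standardized": std[n].n_retained if standardize else np.nan}
        if hits is not None and len(conditions[n]):
            row["precision_all"] = motif_precision(conditions[n], hits)
            _, _, row["auprc_all"] = precision_recall_curve(conditions[n], hits)
            if standardize and std[n].n_retained:
                row["precision_std"] = motif_precision(std[n], hits)
        if replicates and n in replicates and len(conditions[n]):
            fwd = replicate_overlap(conditions[n], replicates[n])
            rev = replicate_overlap(replicates[n], conditions[n])
            row["overlap_pct"] = fwd
            row["overlap_pct_rev"] = rev
            row["overlap_pct_mean"] = 0.5 * (fwd + rev)
        rows.append(row)
    return pd.DataFrame(rows)
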