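"""Standardization, motif precision, AUPRC, and replicate overlap."""

import numpy as np
import pandas as pd
import pytest

import chipmix as cm
from chipmix.peaks import _PEAK_COLS, PeakSet


def _peakset(rows, sample_id="x"):
    """PeakSet from (chrom, start, end, neglog10_p) tuples."""
    df = pd.DataFrame([
        (c, s, e, 0, 10.0, 2.0, nlp, nlp) for c, s, e, nlp in rows
    ], columns=_PEAK_COLS)
    return PeakSet(sample_id, df)


def _hits(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return cm.MotifHitSet(df.sort_values(["chrom", "start"]).reset_index(drop=True))


# ------------------------------------------------------------ binning

def test_worked_example_peak_spans_two_bins():
    """A peak at chr1:14520-15420 with 1 kb bins covers exactly the bins
    starting at 14000 and 15000."""
    ps = _peakset([("chr1", 14520, 15420, 7.0)])
    std = cm.standardize_bins(ps, 1000)
    assert std.bins["bin_start"].tolist() == [14000, 15000]
    assert std.n_retained == 2
    assert (std.bins["score"] == 7.0).all()


def test_bin_aligned_peak_covers_one_bin():
    ps = _peakset([("chr1", 14000, 15000, 3.0)])
    std = cm.standardize_bins(ps, 1000)
    assert std.bins["bin_start"].tolist() == [14000]


def test_bin_count_matches_closed_form():
    rng = np.random.default_rng(19)
    bin_width = 1000
    for _ in range(100):
        s = int(rng.integers(0, 500_000))
        e = s + int(rng.integers(1, 10_000))
        std = cm.standardize_bins(_peakset([("chr1", s, e, 1.0)]), bin_width)
        expected = (e - 1) // bin_width - s // bin_width + 1
        assert std.n_retained == expected


def test_overlapping_peaks_share_bins_with_best_score():
    ps = _peakset([("chr1", 100, 1100, 3.0), ("chr1", 900, 1500, 9.0)])
    std = cm.standardize_bins(ps, 1000)
    assert std.bins["bin_start"].tolist() == [0, 1000]
    assert std.bins["score"].tolist() == [9.0, 9.0]


# ------------------------------------------------------------ top-n

def _binned(n, sample_id, score_fn=lambda i: float(i)):
    ps = _peakset([("chr1", i * 2000, i * 2000 + 500, score_fn(i))
                   for i in range(n)], sample_id)
    return cm.standardize_bins(ps, 1000)


def test_topn_truncates_to_smallest_condition():
    sets = [_binned(100, "a"), _binned(250, "b"), _binned(80, "c")]
    out = cm.standardize_topn(sets)
    assert [o.n_retained for o in out] == [80, 80, 80]


def test_topn_single_condition_unchanged():
    one = _binned(40, "a")
    out = cm.standardize_topn([one])
    pd.testing.assert_frame_equal(out[0].bins, one.bins)


def test_topn_keeps_most_significant_bins():
    sets = [_binned(50, "a"), _binned(10, "b")]
    out = cm.standardize_topn(sets)
    # condition a truncated to its 10 best-scoring bins (scores 40..49)
    assert sorted(out[0].bins["score"]) == [float(i) for i in range(40, 50)]


def test_topn_boundary_ties_resolve_identically_across_reruns():
    sets = [_binned(60, "a", score_fn=lambda i: 1.0), _binned(30, "b")]
    a1 = cm.standardize_topn(sets)[0].bins
    a2 = cm.standardize_topn([_binned(60, "a", score_fn=lambda i: 1.0),
                              _binned(30, "b")])[0].bins
    pd.testing.assert_frame_equal(a1, a2)
    assert len(a1) == 30


def test_topn_empty_condition_empties_all_with_warning():
    sets = [_binned(10, "a"), cm.standardize_bins(_peakset([]), 1000)]
    with pytest.warns(UserWarning, match="no bins"):
        out = cm.standardize_topn(sets)
    assert all(o.n_retained == 0 for o in out)


# ------------------------------------------------------------ precision

def test_precision_all_and_none():
    ps = _peakset([("chr1", 0, 100, 1.0), ("chr1", 500, 700, 2.0)])
    assert cm.motif_precision(ps, _hits([("chr1", 50, 60), ("chr1", 600, 610)])) == 1.0
    assert cm.motif_precision(ps, _hits([("chr2", 50, 60)])) == 0.0


def test_precision_is_order_invariant_and_matches_brute_force():
    rng = np.random.default_rng(23)
    peaks = [("chr1", int(s), int(s) + int(w), float(rng.uniform(1, 10)))
             for s, w in zip(rng.integers(0, 50_000, 80),
                             rng.integers(50, 900, 80))]
    hits = [("chr1", int(s), int(s) + 11) for s in rng.integers(0, 50_000, 40)]
    ps = _peakset(peaks)
    h = _hits(hits)
    got = cm.motif_precision(ps, h)
    brute = np.mean([
        any(s < he and e > hs for _, hs, he in hits)
        for _, s, e, _ in peaks])
    assert got == pytest.approx(float(brute))
    shuffled = _peakset([peaks[i] for i in rng.permutation(len(peaks))])
    assert cm.motif_precision(shuffled, h) == got


def test_precision_of_empty_peakset_is_an_error():
    with pytest.raises(ValueError, match="undefined"):
        cm.motif_precision(_peakset([]), _hits([("chr1", 0, 10)]))


# ------------------------------------------------------------ AUPRC

def test_auprc_perfect_ranking_is_one():
    # all motif-bearing peaks outrank all motif-free peaks
    peaks = [("chr1", i * 1000, i * 1000 + 100, 10.0 - i) for i in range(6)]
    hits = [("chr1", i * 1000 + 10, i * 1000 + 20) for i in range(3)]
    _, recall, auprc = cm.precision_recall_curve(_peakset(peaks), _hits(hits))
    assert recall[-1] == 1.0
    assert auprc == pytest.approx(1.0)


def test_auprc_no_hits_recovered_is_zero():
    peaks = [("chr1", i * 1000, i * 1000 + 100, float(i)) for i in range(5)]
    hits = [("chr2", 0, 50)]
    _, _, auprc = cm.precision_recall_curve(_peakset(peaks), _hits(hits))
    assert auprc == 0.0


def test_auprc_matches_enumeration_oracle():
    """20-peak toy case against an independent dumb-loop computation."""
    rng = np.random.default_rng(31)
    peaks = [("chr1", int(s), int(s) + 200, float(rng.uniform(1, 20)))
             for s in rng.integers(0, 40_000, 20)]
    hits = [("chr1", int(s), int(s) + 15) for s in rng.integers(0, 40_000, 10)]
    ps, h = _peakset(peaks), _hits(hits)
    _, _, auprc = cm.precision_recall_curve(ps, h)

    ranked = sorted(peaks, key=lambda r: (-r[3], r[0], r[1]))
    pts = [(0.0, None)]
    prec_at, rec_at = [], []
    for k in range(1, len(ranked) + 1):
        prefix = ranked[:k]
        tp = sum(1 for _, s, e, _ in prefix
                 if any(s < he and e > hs for _, hs, he in hits))
        rec = sum(1 for _, hs, he in hits
                  if any(s < he and e > hs for _, s, e, _ in prefix))
        prec_at.append(tp / k)
        rec_at.append(rec / len(hits))
    expected = np.trapezoid([prec_at[0]] + prec_at, [0.0] + rec_at)
    assert auprc == pytest.approx(float(expected), rel=1e-9)


def test_auprc_zero_hits_is_an_error():
    with pytest.raises(ValueError, match="zero motif hits"):
        cm.precision_recall_curve(_peakset([("chr1", 0, 10, 1.0)]),
                                  cm.MotifHitSet(pd.DataFrame(
                                      columns=["chrom", "start", "end"])))


# ------------------------------------------------------------ replicates

def test_replicate_overlap_extremes():
    a = _peakset([("chr1", 0, 100, 1.0), ("chr1", 500, 600, 1.0)])
    assert cm.replicate_overlap(a, a) == 100.0
    b = _peakset([("chr1", 200, 300, 1.0)])
    assert cm.replicate_overlap(a, b) == 0.0
    with pytest.raises(ValueError):
        cm.replicate_overlap(_peakset([]), a)


def test_replicate_overlap_matches_brute_force_and_is_asymmetric():
    rng = np.random.default_rng(41)
    mk = lambda n, seed_off: _peakset(
        [("chr1", int(s), int(s) + int(w), 1.0)
         for s, w in zip(rng.integers(0, 30_000, n), rng.integers(50, 500, n))])
    a, b = mk(40, 0), mk(15, 1)
    got = cm.replicate_overlap(a, b)
    brute = 100.0 * np.mean([
        any(ra.start < rb.end and ra.end > rb.start
            for rb in b.peaks.itertuples())
        for ra in a.peaks.itertuples()])
    assert got == pytest.approx(float(brute))
    # asymmetry is expected: denominators differ
    assert cm.replicate_overlap(b, a) != got


def test_quality_report_columns(tmp_path):
    a = _peakset([("chr1", 0, 1500, 5.0), ("chr1", 4000, 4400, 3.0)], "a")
    b = _peakset([("chr1", 0, 900, 4.0)], "b")
    hits = _hits([("chr1", 10, 30)])
    rep = cm.quality_report({"a": a, "b": b}, hits, replicates={"a": b, "b": a})
    assert set(rep["condition"]) == {"a", "b"}
    assert (rep["n_standardized"] == rep["n_standardized"].min()).all()
    assert {"precision_all", "auprc_all", "overlap_pct"} <= set(rep.columns)
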