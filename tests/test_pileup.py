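"""Pileup tracks: fragment extension, Parzen smoothing, and the weighted
multi-scale control construction, all checked against dense-array oracles."""

import numpy as np
import pytest

import chipmix as cm
from chipmix.pileup import BackgroundLambda, FragmentLength, track_add

from conftest import make_reads, random_reads


def _dense_from_intervals(length, intervals):
    """Oracle: per-base accumulation of weighted intervals."""
    arr = np.zeros(length)
    for s, e, w in intervals:
        arr[max(s, 0):min(e, length)] += w
    return arr


# ------------------------------------------------------------ treatment

def test_plus_read_extends_downstream(toy_genome):
    rs = make_reads(toy_genome, [("chr1", 100, 136, "+")])
    track = cm.pileup_treatment(rs, FragmentLength(200, "user-fixed"))
    dense = track.dense("chr1")
    assert (dense[100:300] == 1).all()
    assert dense.sum() == 200


def test_minus_read_extends_upstream_from_its_five_prime(toy_genome):
    # - read with exclusive 5' end at 300 covers [100, 300)
    rs = make_reads(toy_genome, [("chr1", 264, 300, "-")])
    track = cm.pileup_treatment(rs, FragmentLength(200, "user-fixed"))
    dense = track.dense("chr1")
    assert (dense[100:300] == 1).all()
    assert dense.sum() == 200


def test_treatment_integral_matches_per_read_clipped_oracle(toy_genome):
    rng = np.random.default_rng(23)
    rs = random_reads(toy_genome, 10_000, rng)
    d = 200
    track = cm.pileup_treatment(rs, FragmentLength(d, "user-fixed"))
    fwd = rs.reads["strand"].to_numpy() == "+"
    start = np.where(fwd, rs.reads["start"], rs.reads["end"] - d)
    clipped = (np.minimum(start + d, 100_000) - np.maximum(start, 0)).clip(min=0)
    assert track.integral() == pytest.approx(float(clipped.sum()), rel=1e-12)


# ------------------------------------------------- bidirectional extension

def test_bidirection_extend_is_a_centered_box(toy_genome):
    rs = make_reads(toy_genome, [("chr1", 1000, 1036, "+")])
    dense = cm.bidirection_extend(rs, 1000).dense("chr1")
    assert (dense[500:1500] == 1).all() and dense.sum() == 1000


def test_bidirection_extend_even_scale_symmetric(toy_genome):
    rs = make_reads(toy_genome, [("chr1", 100, 136, "+")])
    d = 200
    dense = cm.bidirection_extend(rs, d).dense("chr1")
    assert (dense[100 - d // 2:100 + d // 2] == 1).all()


def test_bidirection_extend_odd_scale_extra_base_three_prime(toy_genome):
    plus = make_reads(toy_genome, [("chr1", 100, 136, "+")])
    minus = make_reads(toy_genome, [("chr1", 64, 100, "-")])  # 5' end at 100
    dp = cm.bidirection_extend(plus, 5).dense("chr1")
    dm = cm.bidirection_extend(minus, 5).dense("chr1")
    assert np.flatnonzero(dp).tolist() == [98, 99, 100, 101, 102]
    assert np.flatnonzero(dm).tolist() == [97, 98, 99, 100, 101]


def test_bidirection_extend_matches_dense_oracle_at_10kb(toy_genome):
    rng = np.random.default_rng(31)
    rs = random_reads(toy_genome, 2_000, rng)
    track = cm.bidirection_extend(rs, 10_000)
    fwd = rs.reads["strand"].to_numpy() == "+"
    five = np.where(fwd, rs.reads["start"], rs.reads["end"])
    start = five - 5_000
    oracle = _dense_from_intervals(
        100_000, [(s, s + 10_000, 1.0) for s in start])
    np.testing.assert_allclose(track.dense("chr1"), oracle, atol=1e-9)
    # no mass outside the chromosome
    ends, _ = track.chrom_data["chr1"]
    assert ends[-1] == 100_000


# ------------------------------------------------- weighted control

@pytest.fixture()
def two_controls(toy_genome):
    rng = np.random.default_rng(47)
    return [random_reads(toy_genome, 1_500, rng) for _ in range(2)]


def _expected_dense(controls, theta, d, treatment_total, lam, length):
    """Oracle: dense weighted multi-scale accumulation and max-flooring."""
    scales = (d, 1_000, 10_000)
    accums = []
    for s in scales:
        acc = np.zeros(length)
        for ctrl, w in zip(controls, theta):
            if w == 0:
                continue
            factor = w * (treatment_total / ctrl.total_read_count) * (d / s)
            fwd = ctrl.reads["strand"].to_numpy() == "+"
            five = np.where(fwd, ctrl.reads["start"], ctrl.reads["end"])
            half = s // 2
            start = np.where(fwd, five - half, five - (s - half))
            acc += _dense_from_intervals(length, [(int(a), int(a) + s, factor)
                                                  for a in start])
        accums.append(acc)
    return np.maximum.reduce([np.full(length, lam)] + accums)


def test_weighted_control_matches_dense_linearity_oracle(toy_genome, two_controls):
    d = FragmentLength(200, "user-fixed")
    lam = BackgroundLambda.from_treatment(3_000, 200, toy_genome.effective_genome_size)
    theta = np.array([2.0, 3.0])
    combined = cm.build_weighted_control(two_controls, theta, d, 3_000, lam)
    oracle = _expected_dense(two_controls, theta, 200, 3_000,
                             lam.lambda_bg, 100_000)
    np.testing.assert_allclose(combined.dense("chr1"), oracle, rtol=1e-9)


def test_unit_weight_equals_unweighted_single_control(toy_genome, two_controls):
    """A single control with weight exactly 1 reproduces the unweighted
    construction bit for bit."""
    d = FragmentLength(200, "user-fixed")
    lam = BackgroundLambda.from_treatment(3_000, 200, toy_genome.effective_genome_size)
    weighted = cm.build_weighted_control(
        two_controls[:1], cm.ControlWeightResults.default_single_control(),
        d, 3_000, lam)
    unweighted = cm.build_weighted_control(two_controls[:1], [1.0], d, 3_000, lam)
    for c in toy_genome.names:
        ew, vw = weighted.chrom_data[c]
        eu, vu = unweighted.chrom_data[c]
        assert (ew == eu).all()
        assert (vw == vu).all()  # bit-identical, not just close


def test_all_zero_weights_floor_at_lambda_bg(toy_genome, two_controls):
    d = FragmentLength(200, "user-fixed")
    lam = BackgroundLambda.from_treatment(3_000, 200, toy_genome.effective_genome_size)
    with pytest.warns(UserWarning, match="zero"):
        combined = cm.build_weighted_control(two_controls, [0.0, 0.0], d, 3_000, lam)
    assert combined.max_value() == combined.min_value() == lam.lambda_bg


def test_combined_never_below_lambda_bg(toy_genome, two_controls):
    d = FragmentLength(200, "user-fixed")
    lam = BackgroundLambda.from_treatment(3_000, 200, toy_genome.effective_genome_size)
    combined = cm.build_weighted_control(two_controls, [0.3, 0.1], d, 3_000, lam)
    assert combined.min_value() >= lam.lambda_bg


def test_homogeneity_in_weights_before_flooring(toy_genome, two_controls):
    d = FragmentLength(200, "user-fixed")
    lam = BackgroundLambda.from_treatment(3_000, 200, toy_genome.effective_genome_size)
    _, parts1 = cm.build_weighted_control(two_controls, [1.0, 0.5], d, 3_000,
                                          lam, return_parts=True)
    _, parts3 = cm.build_weighted_control(two_controls, [3.0, 1.5], d, 3_000,
                                          lam, return_parts=True)
    for p1, p3 in zip(parts1, parts3):
        np.testing.assert_allclose(p3.dense("chr1"), 3 * p1.dense("chr1"),
                                   rtol=1e-9)


def test_streaming_accumulation_equals_batch_sum(toy_genome, two_controls):
    d = FragmentLength(200, "user-fixed")
    lam = BackgroundLambda.from_treatment(3_000, 200, toy_genome.effective_genome_size)
    _, parts = cm.build_weighted_control(two_controls, [1.2, 0.7], d, 3_000,
                                         lam, return_parts=True)
    for si, s in enumerate((200, 1_000, 10_000)):
        batch = None
        for ctrl, w in zip(two_controls, [1.2, 0.7]):
            factor = w * (3_000 / ctrl.total_read_count) * (200 / s)
            t = cm.bidirection_extend(ctrl, s, weight=factor)
            batch = t if batch is None else track_add(batch, t)
        np.testing.assert_allclose(parts[si].dense("chr1"),
                                   batch.dense("chr1"), rtol=1e-9)


def test_weight_count_mismatch_is_an_error(toy_genome, two_controls):
    d = FragmentLength(200, "user-fixed")
    lam = BackgroundLambda.from_treatment(3_000, 200, toy_genome.effective_genome_size)
    with pytest.raises(ValueError, match="weights"):
        cm.build_weighted_control(two_controls, [1.0], d, 3_000, lam)


# ------------------------------------------------- fragment length

def test_fragment_length_estimated_from_paired_strand_peaks():
    genome = cm.GenomeTable.from_dict({"chr1": 2_000_000})
    flat = (cm.ControlProfile(bumps=(), baseline=1.0),)
    sites = tuple(cm.spike_grid(genome, 300, 100, 50.0, seed=62))
    spec = cm.FixtureSpec(genome, flat, (1.0,), (50_000,), 100_000,
                          sites, fragment_length=200)
    fx = cm.generate_fixture(spec, seed=63)
    est = cm.estimate_fragment_length(fx.treatment, tag_size=50)
    assert est.source == "estimated"
    assert 180 <= est.d <= 220


def test_user_extsize_bypasses_estimation():
    fl = FragmentLength(147, "user-fixed")
    assert fl.d == 147 and fl.source == "user-fixed"


def test_peak_free_reads_trigger_fallback(toy_genome):
    rng = np.random.default_rng(71)
    rs = random_reads(toy_genome, 5_000, rng)
    with pytest.warns(UserWarning, match="fallback"):
        est = cm.estimate_fragment_length(rs, fallback_d=180)
    assert est.d == 180 and est.source == "user-fixed"
    with pytest.raises(ValueError, match="fallback"):
        cm.estimate_fragment_length(rs)


def test_lambda_bg_requires_nonempty_treatment(toy_genome):
    with pytest.raises(ValueError):
        BackgroundLambda.from_treatment(0, 200, toy_genome.effective_genome_size)
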