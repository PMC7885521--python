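"""End-to-end orchestration: reads -> weights -> background -> peaks.

Thin glue used by both the command-line interface and tests; all the
science lives in the modules it calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .background import ControlWeightModel, ControlWeightResults
from .peaks import PeakSet, call_peaks
from .pileup import (BackgroundLambda, FragmentLength, PileupTrack,
                     build_weighted_control, estimate_fragment_length,
                     pileup_treatment)
from .reads import MappedReadSet, deduplicate

log = logging.getLogger(__name__)


@dataclass
class PeakCallRun:
    peaks: PeakSet
    weights: ControlWeightResults
    d: FragmentLength
    lambda_bg: BackgroundLambda
    treatment_track: PileupTrack
    control_track: PileupTrack
    scale_factors: list[float]


def resolve_weights(controls: list[MappedReadSet], treatment: MappedReadSet,
                    weights: ControlWeightResults | None = None,
                    fit: bool = False, window_size: int = 200, step: int = 50
                    ) -> ControlWeightResults:
    """User weights > fitted weights > the single-control default of 1."""
    if weights is not None:
        if weights.k != len(controls):
            raise ValueError(f"{weights.k} weights for {len(controls)} controls")
        return weights
    if not fit and len(controls) == 1:
        return ControlWeightResults.default_single_control(controls[0].sample_id)
    model = ControlWeightModel.from_samples(controls, treatment,
                                            window_size=window_size, step=step)
    return model.fit()


def run_peak_calling(treatment: MappedReadSet, controls: list[MappedReadSet],
                     weights: ControlWeightResults | None = None,
                     fit: bool = False, extsize: int | None = None,
                     model: bool = False, q_cutoff: float = 0.05,
                     min_length: int | None = None, max_gap: int | None = None,
                     keep_dup: int | None = 1, tag_size: int | None = None,
                     window_size: int = 200, step: int = 50) -> PeakCallRun:
    """Full pipeline on in-memory read sets.

    ``keep_dup`` deduplicates every sample per-locus before anything else
    (None disables). ``extsize`` fixes the fragment length; ``model``
    requests the paired-peak estimate with extsize as fallback. Defaults:
    min_length = d, max_gap = tag size.
    """
    if not controls:
        raise ValueError("at least one control is required")
    if keep_dup is not None:
        treatment = deduplicate(treatment, keep_dup)
        controls = [deduplicate(c, keep_dup) for c in controls]

    if tag_size is None:
        tag_size = int(np.median(treatment.reads["end"] - treatment.reads["start"]))
    if model or extsize is None:
        d = estimate_fragment_length(treatment, tag_size=tag_size,
                                     fallback_d=extsize)
    else:
        d = FragmentLength(extsize, "user-fixed")

    w = resolve_weights(controls, treatment, weights, fit, window_size, step)
    for cid, wt in zip(w.control_ids, w.theta):
        log.info("control %s: weight %.6g (%s)", cid, wt,
                 "nonzero" if wt > 0 else "zero")

    lam = BackgroundLambda.from_treatment(
        treatment.total_read_count, d.d, treatment.genome.effective_genome_size)
    t_track = pileup_treatment(treatment, d)
    c_track = build_weighted_control(controls, w, d,
                                     treatment.total_read_count, lam)
    scale_factors = [treatment.total_read_count / c.total_read_count
                     for c in controls]

    peaks = call_peaks(
        t_track, c_track, q_cutoff=q_cutoff,
        min_length=min_length if min_length is not None else d.d,
        max_gap=max_gap if max_gap is not None else tag_size,
        sample_id=treatment.sample_id,
        params={
            "q_cutoff": q_cutoff, "d": d.d, "d_source": d.source,
            "min_length": min_length if min_length is not None else d.d,
            "max_gap": max_gap if max_gap is not None else tag_size,
            "keep_dup": keep_dup, "lambda_bg": lam.lambda_bg,
            "weights": dict(zip(w.control_ids, w.theta.tolist())),
            "weight_source": w.source,
        })
    return PeakCallRun(peaks, w, d, lam, t_track, c_track, scale_factors)
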