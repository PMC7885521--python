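# Methods

## Background model

The treatment's genome-wide read density is modelled as a nonnegative
linear combination of control densities. Counts are taken in 200 bp
windows sliding by 50 bp (so each base is covered by up to four
windows), and every sample is normalized to reads per billion,
`n = r * 1e9 / total_reads`, which removes sequencing depth from the
regression entirely: scaling a control's raw counts and total by any
c > 0 leaves its normalized row, hence its fitted weight, unchanged.

The weights solve

    min_{theta, theta0} (1/2n) * sum_i (y_i - theta . x_i - theta0)^2,
    theta >= 0, theta0 >= 0,

via `scipy.optimize.nnls` on the design augmented with a constant-1
column, which is the only way to put the offset under the same
nonnegativity constraint as the weights. Zeros in the solution are
active constraints of the NNLS optimizer, not thresholded small values.
The problem is convex, so the returned solution is the global minimizer;
a test certifies this against random feasible perturbations.

Modelling assumptions worth stating plainly:

- Each window is treated as an independent regression instance although
  overlapping windows share reads; the induced residual autocorrelation
  biases no point estimate but makes naive standard errors optimistic.
  The `summary()` standard errors are computed on the nonzero support of
  the unconstrained subproblem and are labelled approximate for exactly
  this reason.
- All windows genome-wide are used by default, including all-zero ones
  (dropping them only affects the offset's shrinkage; a flag exposes the
  alternative). A seeded uniform window subsample is available as a
  performance escape hatch, off by default.
- Weights are identified up to the regression itself: when the treatment
  background is an exact mixture with coefficients summing to 1 (as the
  synthetic generator constructs), the expected fitted weights equal the
  mixture proportions. Poisson counting noise in the control windows is
  an errors-in-variables effect that attenuates the weights slightly
  toward zero; at 2e6 reads/sample on a 1 Mb genome the attenuation is
  well under 0.01 per weight, at 2e5 reads it approaches 0.05.

With a single control and no fit requested the weight is exactly 1.0
(not fitted), so the whole pipeline — background track, p/q-values,
peak coordinates, output bytes — is identical to the unweighted
single-control caller. This equivalence is asserted bit-for-bit in the
tests.

## Background track construction

The treatment pileup extends each read from its 5' end in the 3'
direction to the fragment length d; its integral equals
(reads x d) minus edge clipping, which a per-read oracle test checks
exactly. The 5' end of a minus-strand read is its exclusive end
coordinate, so a minus read with 5' end 300 and d = 200 covers
[100, 300).

Controls are smoothed by symmetric ("bidirectional") extension of read
starts into boxes of total width s for s in {d, 1 kb, 10 kb} — a Parzen
box-kernel density estimate at three bandwidths. Odd widths put the
extra base 3'-ward. Each control's track is scaled by
(treatment_total / control_total), then by its weight theta_j, and
accumulated into the three per-scale tracks one control at a time, so
only one control's reads are ever resident beyond the accumulators.
The 1 kb and 10 kb tracks carry an extra factor d/s so that every
candidate is an expected fragment count per d-window; without that
rescaling the widest track would dominate the maximum spuriously. The
final background is the pointwise max of lambda_BG =
treatment_total * d / effective_genome_size and the three scale tracks,
hence never below lambda_BG anywhere.

Tracks are represented per chromosome as (interval-end, height) pairs
(bedGraph-like); dense per-base arrays appear only in test oracles.
Track algebra (add, max, alignment of two tracks onto merged
breakpoints) is exact, and streaming accumulation is tested equal to
batch summation to float tolerance.

## Scoring

Each position's treatment height is tested against the local background
mean with an upper-tail Poisson p-value, evaluated once per interval of
the merged treatment/control breakpoint set (float-identical to
per-base evaluation since both tracks are piecewise constant).
p-values are computed through `poisson.logsf` so deep tails survive
underflow. q-values are Benjamini-Hochberg with each distinct p
weighted by the bases carrying it — every base is one test — computed
on the -log10 scale; on unit-length intervals this reduces to ordinary
BH and is cross-checked against statsmodels in a test. Positions with
q at or below the cutoff are merged across gaps up to max_gap (default:
tag size), regions shorter than min_length (default: d) are dropped,
the summit is the leftmost maximal treatment position in the region,
and the peak's p/q/fold are taken at the summit.

Defaults: q cutoff 0.05, deduplication at one read per
(chrom, 5' coordinate, strand) locus applied per sample before any
pooling. The depth-dependent automatic duplicate limit used elsewhere
is deliberately not reproduced; the cap is an explicit parameter.

## Fragment-length estimation

When no fixed extension size is given, d is estimated from paired
strand peaks: windows of width 2 x 300 bp whose 5'-end count lies
within (5, 50)-fold of the genome-wide expectation are merged into
candidate regions; within each region the separation between the median
plus-strand and median minus-strand 5' positions estimates the fragment
span, and d is the mean separation over regions. Fewer than 100 usable
regions, or an estimate below twice the tag size, triggers fallback to
the user-supplied d (an error if none was given). On simulated
fragment-midpoint data with true d = 200 the estimate lands within a
few bp (196 in the acceptance run); the median-based procedure is this
package's own variant of the classical paired-peak model and is not
claimed to reproduce any particular implementation read-for-read.

## Evaluation procedures

Standardization maps each peak to every 1 kb bin it overlaps (end
coordinate exclusive, so a peak ending exactly on a boundary does not
enter the next bin; a peak at chr1:14520-15420 covers bins 14000 and
15000), each bin inheriting the best overlapping -log10 p. Conditions
compared on the same dataset are then truncated to the top n bins,
n being the smallest bin count among them, with boundary ties broken by
(chrom, bin_start) for determinism. Motif precision is the fraction of
peaks/bins sharing >= 1 bp with a precomputed motif-hit interval; AUPRC
sweeps the peak ranking by -log10 p with recall defined over motif-hit
intervals (an interpretation: per-hit-interval, not per-peak), area by
trapezoid over recall anchored at recall 0. Replicate overlap is the
percentage of one replicate's peaks overlapping the other's — it is
asymmetric, and both directions plus their mean are reported. The
overlap engine is a sorted sweep with a running end-maximum, tested
against quadratic brute force.

## Synthetic data generator

The generator emulates exactly the structure the model assumes: each
control has a smooth positive bias profile (default fifteen Gaussian
bumps, sd 5-50 kb, amplitude 2-10 over a 0.5 baseline, discretized at
100 bp) standing in for accessibility/GC/mappability bias; the
treatment's background 5' positions are drawn from the normalized
weighted mixture of the control profiles; spiked peaks add fragments
whose centers are uniform in the truth interval at a rate giving the
requested fold enrichment over lambda_BG, with read 5' ends at
center +- d/2 by strand. The profile contrast is calibrated so that a
degenerate mixture w = (1, 0) reproduces its source control's windowed
density at correlation > 0.99 at 1e6 reads — the regime in which weight
recovery is meaningfully testable.

What the generator does not emulate, and what passing tests therefore
do not show about real data: mappability holes and blacklist artifacts,
GC-dependent amplification interacting with fragment length, unmapped
or multi-mapping reads, chimeric/duplicated library structure beyond
simple per-locus duplication, chromatin-state-dependent fragment-size
variation, and any correlation between binding sites and background
bias. Real controls are also not exact nonnegative mixtures of each
other; the generator's treatment background is, by construction.

## Problem sizes and numerical choices

Unit tests run on 100 kb-1 Mb genomes; weight recovery is exercised at
the standard condition of three controls x 2e6 reads on 1 Mb, and
end-to-end peak recovery on a 2 Mb genome with 50 spiked 400 bp peaks
at 10-fold enrichment, 2e5 reads per sample. These sizes were chosen so
the entire suite and the acceptance script each finish in well under a
minute while keeping every statistical regime (attenuation, tail
p-values, BH across ~1e6 positions) representative.

Numerical conventions: all coordinates 0-based half-open internally
(BAM positions converted on load; the XLS-like table alone is 1-based
inclusive); treatment heights are rounded to integers for the Poisson
tail; summit ties break leftmost; peak output ordering is (chrom,
start) stable-sorted; reruns are byte-identical. Reads on chromosomes
absent from the genome table are dropped with a counted warning rather
than an error, since decoy/alt contigs are routine in real BAMs.

## Known limitations

- Single-end semantics only: paired-end data are reduced to read 5'
  ends with a user-fixed d.
- Sharp peaks only; no broad/gapped peak mode.
- No treatment-derived slocal/llocal candidates in the background
  maximum: exactly lambda_BG plus the three control scales are used,
  which is the weighted-control definition of the background.
- NNLS standard errors are diagnostics, not constrained-inference
  corrected intervals.
- The instance-weighted and L1-penalized regression variants are out of
  scope.
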