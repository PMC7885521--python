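# chipmix

ChIP-seq peak calling against a **nonnegatively weighted mixture of
control samples**.

## The problem

ChIP-seq enrichment is always judged relative to a control (input DNA,
IgG mock), but every control captures a different blend of background
biases — chromatin accessibility, mappability, GC/PCR effects — and no
single control matches the bias profile of a given treatment. When many
controls are available, pooling them equally is as arbitrary as picking
one. `chipmix` instead fits a *per-treatment* background model: a
nonnegative linear combination of all available controls chosen to best
explain the treatment's genome-wide read density, and then calls peaks
against that combined "smart" control.

## The model

Reads are counted in 200 bp sliding windows (50 bp step) and put on a
common scale by reads-per-billion normalization,

&nbsp;&nbsp;&nbsp;&nbsp;*n*<sub>mi</sub> = *r*<sub>mi</sub> · 10⁹ / TotalReadCount<sub>m</sub>,

for sample *m* and window *i*. With *k* controls giving feature vectors
*x*<sub>i</sub> = (*n*<sub>1i</sub>, …, *n*<sub>ki</sub>) and the
treatment giving targets *y*<sub>i</sub>, the control weights Θ and
offset Θ₀ solve the constrained least-squares problem

&nbsp;&nbsp;&nbsp;&nbsp;min<sub>Θ,Θ₀</sub> (1/2n) Σ<sub>i</sub> (*y*<sub>i</sub> − Θ·*x*<sub>i</sub> − Θ₀)² &nbsp; s.t. Θ ≥ 0, Θ₀ ≥ 0 &nbsp; (NNLS).

Controls that contribute nothing to modelling the treatment's background
get weight exactly zero (an active constraint, not a threshold). With a
single control and no fit requested, the weight defaults to exactly 1,
which makes the whole pipeline bit-identical to the classical unweighted
single-control caller.

Peak calling then follows the standard local-lambda mechanism: treatment
reads are extended to the fragment length *d* into a fragment-coverage
pileup; each control is smoothed by symmetric extension of its read
starts at three scales (*d*, 1 kb, 10 kb), depth-scaled to the
treatment, weighted by Θ, and accumulated one control at a time; the
background at every base is the pointwise maximum of the genome-wide
expectation λ<sub>BG</sub> = *N*·*d*/genome size and the three scale
tracks (each rescaled by *d*/*s* onto fragment units). Enrichment is an
upper-tail Poisson test per position with bp-weighted Benjamini–Hochberg
q-values across the genome.

The package also implements the matching evaluation procedures:
peak standardization (1 kb binning plus top-*n* truncation to the
smallest per-condition count), motif-hit precision and AUPRC (motif hits
are consumed as precomputed BED, never scanned), and replicate-overlap
reproducibility.

## Worked example

```python
import chipmix as cm

genome = cm.GenomeTable.from_dict({"chr1": 1_000_000})
profiles = tuple(cm.random_profiles(genome, 3, seed=7))
peaks = tuple(cm.spike_grid(genome, 25, 400, 10.0, seed=8))
spec = cm.FixtureSpec(genome, profiles, weights=(0.6, 0.3, 0.1),
                      control_depths=(300_000,) * 3, treatment_depth=300_000,
                      peaks=peaks, fragment_length=200)
fx = cm.generate_fixture(spec, seed=1)

run = cm.run_peak_calling(fx.treatment, fx.controls, fit=True, extsize=200)
print(run.weights.summary())
print(f"{len(run.peaks)} peaks called at q <= 0.05")
```

prints

```
Nonnegative control-mixture background model
============================================================
source: fitted    controls: 3    nonzero weights: 3
objective (1/2n * SSR): 3.2771e+09
offset theta0: 15310.4
------------------------------------------------------------
control                       weight      frac   approx SE
control1                    0.551286     0.597     0.00358
control2                    0.286896     0.311     0.00394
control3                   0.0852898     0.092     0.00525
============================================================
26 peaks called at q <= 0.05
```

The fitted weights recover the true mixture (0.6, 0.3, 0.1) that
generated the treatment background — slightly attenuated by Poisson
counting noise in the control windows — and the called peaks recover
all 25 spiked truth intervals (recall 1.0; one additional 251 bp call
brings precision to 25/26). `run.peaks.peaks` is a DataFrame of scored
intervals with summits, fold enrichment and −log₁₀ p/q, writable as
ENCODE narrowPeak via `cm.write_narrowpeak`.

The same pipeline is available from the shell:

```bash
chipmix make-fixture --outdir fx --seed 1
chipmix fit-weights -t fx/treatment.bed -c fx/control1.bed -c fx/control2.bed \
        -c fx/control3.bed -g fx/genome.chrom.sizes --outdir weights
chipmix callpeak -t fx/treatment.bed -c fx/control1.bed -c fx/control2.bed \
        -c fx/control3.bed -g fx/genome.chrom.sizes --extsize 200 \
        -q 0.05 --outdir out --bdg
chipmix evaluate --peaks out/treatment_peaks.narrowPeak --motifs motifs.bed \
        --out report.tsv
```

Every output directory contains a `manifest.json` recording the exact
configuration, read totals, *d*, λ<sub>BG</sub> and per-control scale
factors; reruns on identical inputs are byte-identical.

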