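# Methods

This note describes the models and procedures `fragaxis` implements,
the parameters that matter, what the synthetic generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinate conventions

All intervals are 0-based half-open. A fragment's upstream (U) end is
its `start` coordinate and its downstream (D) end is `end − 1`, the
last covered base; both are defined purely by genome coordinate order
(strand is ignored). The inclusive fragment size is therefore
`D − U + 1 = end − start`, and a pseudo-fragment built from a U peak
at −68 bp and a D peak at +74 bp has size 74 − (−68) + 1 = 143 bp.
Note that under this convention the analogous pair (−59, +63) gives
123 bp, one more than the "~122 bp" sometimes quoted for that pair
with an exclusive-length convention; we use the inclusive arithmetic
consistently because it makes the 143 bp example exact.

## The generative model

The simulator encodes the mechanistic picture that motivates the
analyses: apoptotic nucleases cut cfDNA preferentially in the linker
between nucleosomes, and at a 10-bp-spaced lattice of rotationally
exposed sites inside the core whose accessibility rises as local CpG
methylation falls.

**Nucleosome array.** `make_nucleosome_array(n, spacing)` places `n`
centers `spacing` bp apart (default 400 × 185 bp, the scale of a
constitutively well-positioned array), with optional Gaussian jitter.
The core is center ±73 bp (147 bp of wrapped DNA); the linker midpoint
is ±90 bp.

**Cut sites (`CutModel`).** Per nucleosome, U-end cut sites sit on a
10-bp lattice ending at −68 bp (−68, −58, …, −8) plus a dominant
linker site at −83 bp; D-end sites sit at +63 and +74 bp plus a linker
site at +82 bp. Cut positions get Gaussian noise (σ = 1.5 bp). The
geometry is chosen so the canonical linker-to-linker fragment is
82 − (−83) + 1 = 166 bp — the hallmark mononucleosomal mode — and so
intra-core cuts generate the sub-147 bp population with 10-bp size
periodicity and end peaks at −68/+63. With probability
`dinucleosome_fraction` (default 0.15) the D cut falls on the next
nucleosome; without this ingredient the model would emit essentially
no fragments ≥170 bp and the short/long partition analyses would
compare against an empty class.

**Methylation coupling.** Each intra-core site's cut weight
interpolates between `w_core_unmethylated` (1.0) and
`w_core_methylated` (0.25) as the local methylation level `m` (mean
CpG probability within the core) rises:
`w(m) = w_u + (w_m − w_u)·m^γ`, with sensitivity exponent γ = 1 by
default. The linker weight (3.0) is methylation-independent — the
accessibility mechanism acts on DNA wrapped around the histone
octamer, not on the linker. No quantitative form for this coupling is
established experimentally; the interpolation-with-exponent form is an
explicit modelling assumption, and γ is exposed so sensitivity
analyses can vary it.

**Methylation landscape.** CpG sites are placed every `cpg_step`
(10 bp) across the array span. Methylation is spatially correlated:
1 kb domains draw a regional mean around the tissue mean (Beta,
concentration 12), per-site probabilities draw around the regional
mean (Beta, concentration 30), and a fraction of domains (default
0.15) is forced to near-zero methylation. These hypomethylated
domains are drawn independently for *every* profile, not only the
tumor one: unmethylated islands exist in all tissues, healthy-plasma
data do contain hypomethylated reads, and independent domains give
tissue pairs the differential CpG sites that tissue-of-origin
analyses select on. The default profiles are "blood" (mean 0.8) and
"tumor" (mean 0.4), reflecting global tumor hypomethylation. Per-read
CpG states are Bernoulli draws from the site probabilities, matching
binary per-read bisulfite/enzymatic calls.

**Reference and motifs.** The synthetic reference is uniform A/C/G/T
with `CG` written at every landscape CpG site. At a configurable
fraction of nucleosomes (default 0.5) the linker cut sites are seeded
with the CCCA motif (forward at the U site, reverse-complement ending
at the D site). Because linker cutting dominates where DNA is
methylated, this makes CCCA the signature of the *methylated*
component — which is what lets methylation-proportional capture
(below) shift CCCA usage upward, the direction observed in paired
shotgun/cfMeDIP data. Seeding the tumor-preferred (hypomethylated,
intra-core) sites instead would invert that direction.

**MeDIP-style capture.** `simulate_medip_capture` retains each
fragment with probability `min(1, w·m)` where `m` is its count of
methylated CpGs. The default `w = 0.05` is set against the
generator's CpG density (~12 methylated CpGs per mononucleosomal
fragment in blood-profile DNA): weights ≳0.1 saturate the probability
for nearly every fragment and capture nothing preferentially, while
0.05 retains roughly half the pool with a clear methylation bias.

**Mixtures.** `mix_samples` draws each output fragment from a tumor
pool with probability equal to the tumor DNA load, else from a control
pool, tracking per-fragment provenance. `sample_fragments` with a
nonzero `tumor_fraction` does the same at generation time using the
tumor methylation profile.

**What the generator does not emulate.** Sequencing reads, base
qualities and bisulfite-conversion errors; alignment and mapping
ambiguity; single-strand library artefacts; chromosome-scale genome
structure (a sample lives on one synthetic contig); inter-individual
variation in nucleosome positioning; and the full complexity of
nuclease biology (a single cut-weight family stands in for
DNASE1L3/DNASE1/DFFB preferences). Passing tests on this generator
therefore demonstrate that the analysis chain is wired correctly and
recovers planted structure — not that the same effect sizes will be
observed in real plasma.

## Analysis procedures

**End profiling.** Each U and D end is assigned independently to the
nearest nucleosome center (ties between two centers go to the left
one); ends farther than the window W (default 93 bp, covering the ±90
spacing boundary with margin) from every center are tallied as
unassigned, so assigned + unassigned = 2 × fragments. Histograms over
−W..+W are kept per orientation. The within-core fraction is the
share of assigned ends with |offset| ≤ 73 bp. The short/long
partition uses ≤147 / ≥170 bp with the middle excluded.

**Peak calling.** The per-orientation frequency series is smoothed
with a 3-bp centred moving average (edge-normalised), then
`scipy.signal.find_peaks` is applied with a minimum separation of 5 bp
(resolving the 10-bp lattice) and a prominence floor. The default
floor is `min(1.5 × median nonzero frequency, 0.1 × smoothed
maximum)`: a plain median degenerates to zero on profiles with long
zero stretches, and a pure median-based floor can sit exactly at the
prominence of genuine minor lattice peaks; the 10%-of-maximum cap is
the usual "minor peaks at least 10% of the dominant peak" rule. Both
terms are stated explicitly so callers can override them. Peak ties
are resolved deterministically (ascending position output; mode ties
in size histograms break toward the smaller size).

**Periodicity.** Profiles are detrended by subtracting a loess fit
(tricube weights, degree 1, span 0.3 of the series — the smoother span
is not canonical, 0.3 removes the core/linker envelope while leaving
10-bp structure); residuals are re-centred to exactly zero mean. The
periodogram is a plain boxcar FFT spectrum with `scaling='spectrum'`,
so total one-sided density equals the residual mean square (a Parseval
identity used as a test invariant). The dominant period is the
density argmax restricted to a period band (default 5–20 bp), ties
toward the shorter period. No tapering or padding is applied by
default; `pad_to` refines the frequency grid when needed. The signal
fed to the FFT is the full ±W window profile. At W = 93 the Fourier
grid has no point at exactly 0.100 cycles/bp, so a perfect 10-bp
lattice reports 10.39 or 9.84 bp depending on spectral leakage.

**Methylation partitioning.** A read with ≥2 CpGs (alternative: 5)
is hyper-methylated if its average binary state exceeds 0.80 and
hypo-methylated if below 0.20 — strict inequalities, boundary averages
unclassified. Class size distributions are compared with a paired t
test across matched 1-bp bins of the two *cumulative* distributions: a
paired t on the normalised per-bin frequencies themselves is
degenerate (the differences sum to zero identically), whereas a size
shift raises one CDF above the other in every bin. The genomewide
curve takes per-fragment mean methylation, averages it within 1-bp
size bins (50–400 bp), and fits a count-weighted OLS of mean
methylation on size; per-fragment-then-per-size averaging is a choice
(the alternative is per-CpG pooling) and is stated in the API docs.

**End motifs.** For each fragment both 5′ ends contribute a 4-mer:
the k bases starting at the U end read forward, and the
reverse-complement of the k bases ending at the D end. Single-end
mode counts only U ends, for datasets where only the sequenced read's
own 5′ end is trustworthy. Ends at contig edges or containing
non-ACGT bases are skipped and counted. Paired usage comparisons
(shotgun vs capture) use a two-tailed paired t test.

**E-index.** The ending-preference model counts, per genomic locus,
how often pooled deduplicated control fragments place a U end and a D
end there; counts stay raw (one model scores every sample, so the
pool's depth cancels in comparisons — but note the score scales with
pool size, so scores are only comparable against the same model).
A sample's E-index is the mean over its fragments of
`M_U + M_D`, with positions absent from the model contributing zero
(no pseudocount — the score is a plain sum of counts). Controls
evaluated against a model should be held out of its pool; the package
scores held-out samples and leaves leave-one-out pooling to the
caller. AUCs use the convention that lower E-index indicates cancer;
the Z-test against AUC = 0.5 uses the Hanley–McNeil standard error,
group comparisons use two-sided Mann–Whitney U, and tumor-load
association uses Pearson correlation. The two-feature combination
with methylation density is a leave-one-out logistic regression
(features standardised per training fold) — a deliberate, simple
choice where no canonical method exists.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed and is
bit-reproducible under it; the pipeline derives per-sample seeds from
one global seed via `numpy` seed sequences. Default scales: a
simulated plasma sample is 200,000 fragments (`SampleSpec`); the
fixture bundle writes 6 controls + 2 cancers at 20,000 fragments each;
the demo pipeline runs 12 controls + 6 cancers at 50,000; the test
suite and acceptance script use panels of 5,000-fragment samples
against models pooled from 20,000-fragment controls, sizes at which
the planted effects are comfortably detectable while a full run stays
in the minutes range on one core. All are overridable.

## Known limitations

* The landscape and generator are single-chromosome; the analysis
  modules themselves handle multi-chromosome inputs.
* The E-index model is an in-memory sparse map per chromosome; for
  genome-wide human-scale pools a disk-backed representation would be
  needed.
* Peak calling assumes approximately shot-noise-free pooled profiles;
  very shallow profiles need an explicit prominence floor.
* The Hanley–McNeil Z-test is a large-sample approximation and is
  anti-conservative for perfectly separated small panels (SE → 0).
* `fragments_from_paired_alignments` trusts the aligner's proper-pair
  flag and TLEN field; exotic chimeric templates are simply skipped.
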