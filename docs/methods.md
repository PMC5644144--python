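# Methods

## The question and the statistic

In most animals with a functional DNA methylation system, germ-line
methylation is concentrated in gene bodies. Methylated cytosines deaminate to
thymine at an elevated rate, so over evolutionary time historically
methylated genes lose CpG dinucleotides. The normalized CpG content of a
region of effective length *N* (unambiguous A/C/G/T bases), with *C*
cytosines, *G* guanines and *CpG* occurrences of the CpG dinucleotide,

    CpG[o/e] = N · CpG / (C · G),

measures this erosion: values near 1 mean CpG occurs as often as base
composition predicts; values well below 1 indicate historical depletion. In a
genome with an intact germ-line methylation system the per-gene CpG[o/e]
distribution is bimodal — a low-mean, historically methylated class and a
high-mean, unmethylated class — whereas a lineage without methylation shows a
single component. This package computes the statistic over gene bodies and
over fixed-width genome fragments, fits univariate Gaussian mixtures to the
resulting distributions, selects the component count by BIC, and reports a
conservative bimodal/unimodal verdict.

Counting rules: dinucleotides use an overlapping scan (width 2, step 1), so
"CGCG" contains two CpGs. Any window touching an ambiguity code (N etc.) is
skipped, and ambiguous bases do not count toward *N*, *C* or *G*. Taking *N*
as the unambiguous base count rather than raw string length keeps N-runs in
draft assemblies from inflating o/e: N-runs would otherwise raise the
numerator's *N* while the counted *C*, *G* and *CpG* stay put. CpG[o/e] is
exactly strand-symmetric (CpG is its own reverse complement; C and G swap),
which the tests verify, so minus-strand gene bodies can be reverse-
complemented for interface cleanliness without affecting any value.

## Sequence universes

Gene bodies default to the spliced exonic sequence (mode `spliced`), with a
contiguous `span` mode available; minus-strand genes are returned 5'→3' in
the gene's sense. Coordinates are 0-based half-open in memory and converted
from GFF3's 1-based inclusive convention exactly once, at the parser
boundary. Genome fragments are non-overlapping windows (default 1000 bp)
tiled from position 0 of each scaffold; the trailing partial window is
dropped and windows with more than 20% ambiguous bases are discarded and
counted.

### The uniform-1-kb gene-body protocol

The sampling variance of CpG[o/e] scales roughly with 1/length: a 200-bp
transcript at ~36% GC carries only a handful of expected CpGs, so its o/e
value scatters with an sd of ~0.3, while a 2-kb gene scatters with ~0.1.
On a realistic transcript-length distribution (mean ~709 bp, median ~234 bp)
a single gene class therefore produces a strongly leptokurtic o/e
distribution, and a BIC-selected Gaussian mixture will misattribute the
kurtosis to extra components — we observed exactly this on single-class
synthetic data. The modality call is therefore run on *uniform-length*
gene bodies: each gene's first 1 kb (5'-anchored, after orientation), with
sub-1-kb genes dropped (`PipelineParams.uniform_1kb`, i.e. `truncate_to=1000`
plus `min_length=1000`). This parallels the 1-kb genome fragments, restores
the approximately homoscedastic-Gaussian setting the mixture assumes, and is
the protocol used by the analysis drivers and the acceptance script. The
batch table itself defaults to the permissive `min_length=200` with no
truncation, for descriptive use.

## Mixture model and modality call

For values x₁..xₙ we fit K-component univariate Gaussian mixtures by EM, for
K = 1..k_max (default 4) under two variance families — equal variance across
components and unequal (the two one-dimensional model families of classical
model-based clustering, "E" and "V") — and rank all candidates by

    BIC = −2 log L + p · ln n   (minimized; p = (2K−1) + K or (2K−1) + 1).

Ties break toward smaller K, then the equal family (parsimony). The verdict
is `bimodal_methylation_signature` only if the BIC-best model has K ≥ 2 AND
ΔBIC = BIC(best K=1) − BIC(best) ≥ 6 (a "strong evidence" threshold on the
conventional BIC-difference scale) AND every adjacent component pair is
separated by at least 2 pooled standard deviations (|μᵢ₊₁−μᵢ| /
√((σᵢ²+σᵢ₊₁²)/2)). The two extra gates matter: heavy tails or skew can earn a
K=2 fit a modest BIC win with nearly coincident means, which is not
bimodality. Both thresholds are configurable and echoed into every report.

EM details: values are sorted internally (the likelihood is permutation-
invariant, and sorting makes fitted parameters *exactly* independent of input
order). The first start places component means at K evenly spaced quantiles;
the remaining starts (default 10 total) place them at K uniformly random
quantile levels — restarts thus depend on the data only through order
statistics, preserving exact permutation invariance, which per-row random
responsibility initialization could not. Each start runs a 50-iteration
burn-in and only the best is polished to convergence (absolute log-likelihood
improvement < 1e-8, cap 500 iterations). K=1 skips restarts, since EM reaches
the closed-form mean/variance MLE from any start. Variances are floored at
max(1e-6, 1e-4 · sample variance) to prevent singular components; constant
data with K ≥ 2 raises a degenerate-data error; the modality call requires at
least 50 observations. The per-iteration log-likelihood trace is retained on
the fit object and asserted non-decreasing in tests.

## The synthetic-data generator

The generator emulates the statistical structure of a small arthropod
genome/transcriptome so every pipeline stage can be exercised with no
external data. Sequences are drawn from a first-order Markov chain whose
rows all equal the base composition (p_A = p_T = (1−gc)/2, p_C = p_G = gc/2)
except the C row, whose C→G entry is multiplied by a depletion factor
d ∈ (0, 1.5] and renormalized. This is the minimal mechanism that produces a
controlled CpG[o/e]: it reproduces the *end state* of germ-line CpG decay
without simulating mutation through time. Because of the renormalization the
realized o/e is not d; the long-run expectation is the closed form

    E[CpG o/e] → P(G|C) / π_G,

with π the chain's stationary distribution, and `depletion_for_target_oe`
inverts this map numerically. All calibrations go through that inverse.

Preset study conditions (fixed once, from the organism's published summary
statistics): transcript GC 36.25% and genome GC 33.4%; a single-class
transcriptome calibrated to CpG[o/e] 0.70 (the unimodal scenario); a 50/50
two-class transcriptome calibrated to 0.35/0.85 (the bimodal scenario); a
background genome calibrated to 0.79 for the 1-kb fragment analysis. Gene
lengths are truncated-normal with mean 709 bp, sd 600 bp, floor 150 bp,
echoing a real transcriptome's mean; this deliberately includes the short
transcripts that make the uniform-1-kb protocol necessary. Annotated toy
genomes place genes round-robin across scaffolds with 200–800 bp intergenic
spacers and 1–3 exons per gene (introns 50–300 bp, generated with the
intergenic parameters so spliced vs span extraction is distinguishable);
scaffolds grow by concatenation, so genes cannot overlap or exceed scaffold
bounds by construction. Everything is bit-reproducible from (spec, seed).

What the generator does *not* emulate: positional structure along real genes
(5' CpG islands, exon/intron composition differences within a gene),
selection, repeat content, assembly artifacts beyond optional N-handling, and
any correlation between gene length and methylation class. Passing tests
therefore demonstrate that the pipeline recovers the truth under the stated
generative model, not that any particular real genome is unimodal.

## Problem sizes and numerical choices

The simulation studies use the sizes at which the method is meant to operate:
n = 2000 values for the mixture recovery and false-positive studies (20 and
40 replicate seeds), 2000-gene transcriptomes (~600–670 surviving the
uniform-1-kb filter) for the end-to-end re-enactments, 100-kb sequences for
generator calibration (grid d ∈ {0.3, 0.5, 0.8, 1.0} at gc 0.4, 10 seeds),
and a 3-Mb background genome (3000 windows) for the fragment analysis.
Histogram output uses 0.05-wide bins over [0, 2] with an open-ended overflow
bin. Reports are JSON with sorted keys and no timestamp by default, so
identical inputs and seed give byte-identical files.

## Known limitations

- The uniform-1-kb protocol discards sub-1-kb genes (~two-thirds of a
  transcriptome with median ~234 bp); the mean o/e it reports is the mean
  over the analyzed subset. An alternative (weighting or length-stratified
  mixtures) would use all genes at the cost of a more complex model.
- Gaussian components are an approximation; at 1 kb the per-gene o/e is
  mildly right-skewed, which the ΔBIC and separation gates absorb but do not
  model.
- The BIC values use the minimized convention and are comparable only within
  this package.
- The verdict thresholds (ΔBIC ≥ 6, separation ≥ 2) are explicit, configurable
  defaults, not estimates; published analyses that report only "unimodal" or
  "bimodal" give no thresholds to adopt.
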