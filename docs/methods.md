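# Methods

This note documents the models, conventions and numerical choices behind the
package: what each of the four cfDNA modalities measures, how the synthetic
cohorts are generated, and which design decisions were genuinely open.

## Problem setting

Plasma cell-free DNA (cfDNA) is released mainly by apoptosis, and because
nucleosome-bound DNA resists endonuclease digestion, the fragments that
survive carry an imprint of the chromatin of their tissue of origin.
Non-destructive methylation sequencing (enzymatic conversion rather than
bisulfite) preserves fragment boundaries, so a single targeted assay yields
both per-CpG methylation counts and fragment coordinates. From those two
inputs the package derives four modalities over promoter (TSS ± 1 kb),
polyadenylation-site (PAS ± 1 kb) and CpG-marker panels, and integrates them
in a stacked classifier for cancer-versus-control prediction.

## Coordinate conventions and filters

All intervals are 0-based, half-open (BED). Paired-end inputs collapse to
one fragment per pair spanning the outer coordinates. The fragment-size
filter keeps lengths in the inclusive range [80, 200] bp: below 80 bp is
sub-nucleosomal debris, above 200 bp is di-nucleosomal or high-molecular-
weight genomic contamination, and the mono-nucleosome mode (~167 bp, core
particle plus linker) sits comfortably inside. Fragment-length histograms
are computed on *unfiltered* fragments so the mode is visible in context.
Strand is ignored throughout; none of the derived signals is strand-aware.

Spike-in QC: each library carries fully unmethylated lambda phage DNA.
Apparent methylation on the lambda contig measures incomplete cytosine
conversion; a sample passes when its pooled lambda ratio is at most 0.01
(conversion ≥ 99%). The boundary value 0.01 passes ("more than 1%" fails).
A sample with no lambda coverage is *indeterminate* and is excluded unless
an explicit override is set.

## The four modalities

**Methylation.** Per-site ratio `n_meth / n_total`; a zero-coverage site is
missing, not zero. Region-level aggregation pools counts
(`Σ n_meth / Σ n_total`) rather than averaging site ratios — pooling is
robust to uneven coverage, and the same convention is used wherever a
region-level methylation value is needed (including the low-coverage
whole-genome mode, where promoter/enhancer regions are the feature unit).
Default features for CpG-marker panels are per-site.

**Nucleosome occupancy.** Per-bp pileup of size-filtered fragments, clipped
to the target region. Samples are made comparable by scaling each sample so
its panel-wide mean occupancy is 1 (the scale factor is recorded on the
profile). The feature is the mean occupancy per target region, or per 1-kb
sliding window with 10-bp steps when a panel uses long (2-kb) regions.

**Nucleosome fuzziness.** Peaks are called on the occupancy profile after a
centred moving-average smooth of width 73 bp (half a nucleosome: wide
enough to suppress per-bp noise at deep targeted coverage, narrow enough
not to displace 147-bp-scale summits). Local maxima below a sample-
normalised height of 0.5 are discarded; maxima closer than 147 bp merge,
keeping the higher summit (ties keep the leftmost). Fuzziness of a peak is
the *population* standard deviation (ddof 0) of the midpoints
`floor((start + end − 1)/2)` of fragments whose midpoint falls in the
147-bp span centred on the summit; at least two supporters are required,
otherwise the value is missing. The region feature is the mean fuzziness of
peaks whose summit lies inside the region. Fuzziness is disabled
automatically when mean coverage drops below 20 fragments per region —
positional dispersion cannot be estimated from a handful of midpoints.

**Windowed protection score (WPS).** For window size k = 120 (even), the
window at position p is `[p − k/2, p + k/2 − 1]`; the score is the number
of fragments spanning the whole window minus the number with an endpoint
(start or last covered base) inside it, each fragment counted once in the
endpoint term. The two sets are counted independently, so a fragment whose
start coincides with the window edge while spanning contributes both +1 and
−1. Fragments are not clipped to the region, so edge values equal what a
genome-wide computation would produce. No smoothing or running-median
subtraction is applied: that post-processing targets long-range trends in
whole-genome tracks, not 2-kb targets. The global [80, 200] size filter is
used by default; a stricter 120–180 bp fragment range is available as an
option.

## Feature processing and selection

All filters are computed on training samples only, inside every
cross-validation iteration:

1. drop features with any missing training value (features missing only in
   held-out samples are kept; their held-out values are imputed with the
   training median at predict time — training-side exclusion alone cannot
   serve prediction);
2. drop features with training variance ≤ 1e−8 (effectively constants; no
   published threshold exists, so the default removes only degenerate
   features and stricter cuts are configuration);
3. when more than `top_k` (default 100) features survive, run Boruta and
   keep the top 100.

Boruta: each iteration appends a permuted "shadow" copy of every *initial*
feature, fits a random forest (500 trees, depth 5) on `[candidates |
shadows]`, and scores a hit for every candidate beating the best shadow.
Two details matter for calibration on pure-noise inputs. First, importance
is the Z-score formulation (mean per-tree importance divided by its SD
across trees), which demotes features whose apparent importance is an
unstable artefact of tree-level overfitting; raw ensemble importance is
available as an option. Second, the shadow pool keeps its initial width
even as candidates are rejected — a shrinking pool would lower the
max-shadow bar exactly when the surviving candidates are the luckiest
ones, inflating false confirmations. Hit counts are tested against
Binomial(iter, ½) two-sidedly with Bonferroni correction over the initial
feature count (α = 0.05): significantly many hits confirm, significantly
few reject (rejected features leave the pool). Ranking is confirmed > tentative > rejected, by
mean importance within status, ties broken by feature id; tentative
features are eligible for the top-k below all confirmed ones. When the
filtered feature space is already within `top_k`, the Boruta fit is skipped
— it could not discard anything — unless `always_boruta` is set. The
low-coverage occupancy filter used in shallow whole-genome mode (drop any
feature that falls below its sample's mean in at least one sample) is
provided as a separate explicit operation.

## Models and evaluation

Base learner: random forest (500 trees by default; tree count is the main
runtime knob and is deliberately reduced in tests, see below). Outer
evaluation is leave-one-out cross-validation; the stacked model runs a
stratified 10-fold inner CV on each outer training set, re-running the full
selection pipeline per fold, to obtain out-of-fold base probabilities per
modality. Those probabilities are the design matrix of the meta-classifier.
The meta-classifier family is not pinned down by the protocol; the default
is an L2-regularised logistic regression — a low-variance choice for a
4-column input — with a random-forest alternative behind a flag. Per outer
iteration the per-modality models are refit on the full training set to
produce the held-out sample's base probabilities; those refits are exactly
single-modality LOOCV models, so single-modality reports come from the same
run. Inner folds are seeded per outer iteration (`seed XOR iteration`) so
every report is a pure function of (data, config, seed).

Metrics are computed once on the aggregated n held-out probabilities (LOOCV
yields one prediction per sample, hence a single ROC curve): AUC by the
rank/Mann–Whitney formulation with half-credit ties; sensitivity at the
smallest threshold whose specificity reaches 0.90; F1 and confusion matrix
at probability 0.5 unless configured otherwise. Three-class mode (e.g. two
cancer types versus control) uses argmax accuracy with ties resolved to the
lexicographically first class, plus the full confusion matrix. Pairwise
Spearman correlations of per-modality probabilities quantify how
complementary the modalities are; a constant probability vector yields a
missing entry.

Cross-cohort validation intersects the per-modality feature universes,
fits selection + stacking once on the training cohort, and applies the
frozen pipeline to the test cohort.

## Synthetic cohorts

The generator emulates the assay at the level the pipeline consumes — it
does not simulate reads or conversion chemistry.

*Fragments*: nucleosome centres on a 185-bp lattice (core + linker) phased
to the region anchor; per-molecule centre jittered by Normal(0, jitter_sd);
length Normal(167, 12) truncated to [50, 250]; molecule placed
midpoint-at-centre. Lattice sites within ±300 bp of a TSS/PAS anchor carry
weight `ndr_depth` (default 0.3) and per-site counts are Poisson, so the
nucleosome-depleted region (NDR) depresses both local and region coverage —
anchor occupancy is linear in `ndr_depth` and the aggregate anchor/flank
ratio sits below 0.8 under defaults.

*Methylation*: 2 CpG sites per 150-bp marker region, coverage
Poisson(60), methylated counts Binomial(coverage, rate), baseline rate
0.25. *Spike-in*: 100 lambda sites at coverage 100 with methylation rate
1 − conversion (default conversion 0.995).

*Class effects and noise*: a disjoint subset of regions per modality is
informative; there the cancer class uses a different parameter
(hypermethylation, NDR fill-in, extra jitter, or a shorter fragment-length
mean with the per-site rate scaled up so coverage mass — and hence the
occupancy feature — is unchanged while the protection score drops).
Per-sample latent shifts (methylation tone ±0.04, NDR tone ±0.10, chromatin
disorder ±1.2 bp, depth ±10% log-normal) are shared across regions within a
sample. These shared shifts are what cap single-modality AUCs below 1 and
keep errors partly independent across modalities — the regime in which
stacking is expected to help.

Preset conditions: `null` (no effects — calibration), `strong_occupancy`
(NDR fill-in 0.3 → 0.8 in 8 regions, a per-feature effect size of d ≈ 2),
`complementary` (disjoint moderate effects in all four modalities), and
`concordant` (strong effects everywhere). The complementary preset's effect
sizes were calibrated once, when the preset was designed, so that each
single modality lands in the ~0.6–0.9 AUC range rather than saturating;
its defining property is that the stacked model has headroom over every
single modality. Default cohort size is 30 + 30 samples, 40 CpG-marker
regions and 20 + 20 TSS/PAS regions at 300 fragments per region.

What the generator does *not* emulate: sequence-dependent coverage bias,
fragment-length ladders below the mono-nucleosome mode, tumour-fraction
dilution, batch effects, or correlated region-to-region chromatin domains.
Passing tests therefore demonstrate correctness of the computations and the
leakage-free behaviour of the training protocol under controlled
conditions, not clinical performance on real cohorts.

## Numerical choices and degenerate inputs

* Peak plateaus take the leftmost index; flat profiles yield no peaks.
* Midpoint of `[s, e)` is `floor((s + e − 1)/2)`; with zero jitter all
  simulated midpoints coincide and fuzziness is exactly 0.
* Zero-coverage methylation sites, regions without covered CpGs, regions
  without qualifying peaks, and fuzziness with fewer than two supporters
  are all missing values (NaN), which downstream NA filtering handles.
* AUC with one class absent, stacking with an incomplete base table, and
  single-class training folds raise errors naming the context.
* Every random-forest, fold-assignment and permutation seed derives
  deterministically from the run seed; reports reproduce bit-identically.

## Problem sizes in the test suite

The default model uses 500 trees; the heavy pipeline-level tests run the
same code with 10–50 trees and the default 60-sample cohorts so the whole
suite completes on a single CPU in well under half an hour. Tree count
affects only the variance of the forest's probability estimates, not any of
the properties under test, and the chosen sizes leave comfortable margins
(e.g. the stacked-versus-single comparison passed 10/10 seeds at 16 trees
during development).

## Known limitations

* Occupancy and fuzziness are re-implementations of the underlying
  quantities (full-fragment pileup; SD of supporting midpoints) rather than
  a port of any specific peak-calling toolchain; absolute values are not
  expected to match other tools, though region-level contrasts are.
* The windowed protection score is computed only in its long-fragment form
  (k = 120); the short-fragment variant is out of scope.
* LOOCV AUC under the null is slightly pessimistic (the training complement
  under-represents the held-out class); the calibration test bands account
  for this.
* The CLI reads whole cohorts into memory; panels of a few hundred regions
  and hundreds of samples are fine, whole-genome tracks are not the target.
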