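# Methods

## The problem this package models

Ribosome profiling measures translation by sequencing ribosome-protected mRNA
fragments (Ribo-seq) alongside total mRNA (RNA-seq); the per-gene ratio of
footprint density to mRNA abundance is the transcript's translational
efficiency (TE).  Both assays, however, are *compositional*: a library's reads
only report proportions.  If translation collapses uniformly across the
transcriptome — as happens in replicatively aged yeast — per-library (FPKM-
style) normalization silently renormalizes the collapse away and reports no
change.  External spike-in RNAs added in proportion to cell-equivalents of
input break this degeneracy: dividing gene counts by a spike-derived scale
factor yields expression per cell-equivalent, in which global shifts are
visible.

`riboteq` implements that spike-anchored pipeline together with a
ground-truth synthetic-data generator, so that every downstream claim — how
many genes lose TE, how a co-regulated class behaves, what positional
signatures accompany the loss — can be tested as parameter recovery.

## Synthetic experiment generator

One simulated experiment consists of 3 age groups (young, mid, old) x 2
assays (RNA, footprint) x 3 replicates = 18 libraries over a gene universe
plus spike-ins.

**Gene universe.** Defaults: 6553 genes; base mRNA abundance per cell is
log-normal (sdlog 1.2) so an abundant minority dominates the library, as in
real transcriptomes; ORF lengths are log-normal around 1.2 kb, clipped to
[300, 9000] nt and rounded to codons.  A 136-gene ribosomal-protein class
(RPG) is drawn from the top abundance decile — RPG mRNAs are among the most
abundant in yeast — and exactly one non-RPG gene is "GCN4-like", carrying
four short uORFs in a 600-nt leader.

**True effects.** In old cells every per-cell mRNA level rises by a global
factor (default 2.0; the magnitude is a modelling choice — the phenomenon is
a broad per-cell transcript increase, and a two-fold confound is large enough
that naive normalization visibly fails), except the RPG class, whose per-cell
transcripts fall by 23%.  A configured number of genes (default 3472) lose
TE in old cells by log-uniformly distributed fold reductions between a floor
and a ceiling (defaults 1.5 and 40); the draw with the largest uniform
variate is pinned to the ceiling so the configured maximum is always realized
in ground truth.  Mid-aged cells carry every old-cell effect at half its log
magnitude.  Effect sizes couple to young abundance through a Gaussian copula
(target Spearman 0.6 within the affected set), reproducing the observation
that abundant transcripts lose the most TE.

*Why a 1.5-fold floor?*  The affected set is defined operationally: it is the
set of genes a three-replicate design calls significantly decreased.  With
the generator's replicate noise (below), the full-power detection floor of a
moderated t at Q < 0.05 is a ~1.4-fold reduction; effects below that floor
cannot belong to the detected class of any such experiment, so the generator
does not produce them.  Both floor and ceiling are scenario parameters.

**Counts.** Expected gene counts are proportional to depth x per-cell mRNA x
length (x TE for footprints); spike counts to depth x nominal molecules x
length.  Every library receives an independent log-uniform depth factor
spanning a 4-fold range, multiplying all of its expectations — this is the
deliberate confound that library-size normalization cannot separate from
biology but spike-ins can.  Counts are negative-binomial with dispersion
0.004 (between-replicate CV ≈ 6.5% at high counts) and a mean of 4000 reads
per gene per library in young cells.  These two values are calibrated jointly
to the precision the emulated study must have had: detecting a 23% transcript
decrease in each of 136 genes with n = 3 per group requires a per-replicate
CV below ~7%, and no published dispersion was available to adopt instead.
The spike-in reference is ERCC-like: 92 species, log-spaced nominal amounts
spanning 4.5 orders of magnitude, ~5% of young gene reads.

**Demography.** An exponentially growing culture doubles every generation and
every division mints a never-divided daughter, so the division-count
distribution is p(k) = 2^-(k+1): 50% of cells have divided 0 times, 25% once,
12.5% twice.  `culture_age_distribution` returns this closed form plus the
residual tail mass; the two sum to one exactly.

**Positional profiles.** `simulate_profiles` draws per-codon footprint counts
from a multinomial whose weights encode a mode: `uniform`; `paused` (one
codon at 10x background); `start_enriched` (first 50 codons elevated); and
`gcn4_like` (uORFs at 10x the main-ORF density in young cells; in old cells
uORF occupancy falls to 0.4x while main-ORF occupancy stays flat — loss of
uORF engagement without downstream derepression).  Total reads are Poisson in
the summed weights, so profile totals track per-mRNA occupancy across ages.

## Normalization

The spike scale factor of sample *s* is
`factor_s = sum_spike count / sum_spike (length_kb x nominal molecules)`,
i.e. observed reads per (kb x molecule) of spike mass.  It equals sequencing
depth x cell-equivalents up to one capture-efficiency constant shared by all
samples of an assay; that constant cancels in every downstream ratio.
Expression is then `count / (length_kb x factor_s)` with spike rows dropped.
All species are pooled into a single factor (a symmetric trimmed variant is
available); no pseudocounts are added — zeros propagate and are resolved at
the TE stage.  The naive mode is classic FPKM and is retained as the contrast
that demonstrates why spike-ins are needed.

Replicate alignment (mean scaling, then quantile normalization to the
mean-of-sorted reference) is applied strictly within an age x assay group.
Pooling ages would force their distributions to agree and erase the global
signal.  Quantile normalization assigns the reference by stable sort
position, so every column in a group ends with identical sorted values; the
chosen order (spike -> per-cell -> within-group mean/quantile) is recorded in
each output's `# steps=` header.

## Differential TE

TE(g, s) = footprint expression / mRNA expression for each paired (age,
replicate).  Genes with a zero mRNA value in any paired sample are flagged
`undefined_rna_zero` and excluded from testing (zero footprint values, which
also break the log scale, are flagged `undefined_ribo_zero`); at default
depth no genes are typically excluded.  Age summaries use geometric means —
fold changes should be symmetric on the log scale — and the tested contrast
is old vs young; mid is reported but not tested.

Significance uses a moderated two-sample t on log2 TE replicate values: each
gene's pooled variance is shrunk toward the across-genes mean variance with
prior weight d0 = 4 (with n = 3 per group, raw variances on 4 df are too
unstable; the prior adds pseudo-replication without erasing gene-specific
variance), referred to a t distribution with d0 + 4 df, then
Benjamini-Hochberg across the tested universe.  A plain Welch t is available
by configuration.  "Significantly decreased" requires q < 0.05 *and* a
negative log2 fold change, matching the one-directional phenomenon (a global
decline; no transcript's TE rises).  Ranking sorts ascending log2 fold change
(most reduced first), ties broken by gene id.

Class-level contrasts (e.g. RPG vs rest) use the two-sided Wilcoxon rank-sum
test: full permutation enumeration when the number of class assignments is at
most 20 000 (covers any total n <= 10; correct under ties), otherwise the
tie-corrected normal approximation.  Abundance-vs-effect coupling is reported
as the Spearman correlation of log2 young abundance against TE log2 change.

## Positional diagnostics

All scores are ratios of a single profile, hence depth-invariant.
`pause_score` = max of the (centered, window 3) moving-average coverage over
the mean; exactly 1 for uniform occupancy.  `start_enrichment` = mean
coverage of the first 50 codons over the whole-ORF mean; ≈ 1 means no
initiation-proximal pile-up, < 1 indicates body enrichment (the
elongation-defect signature).  Window and head length are conventional
defaults, not fitted, and are configurable; the pause flag threshold (score
> 5) is reported, never baked into conclusions.  `uorf_main_ratio` compares
reads/nt inside uORF intervals against the main ORF.  `body_slope_ztest`
fits OLS slopes of metagene coverage against normalized position and compares
two conditions with z = Δslope / sqrt(se² + se²); its type-I error is
verified at ~5% by simulation.  Metagene profiles scale each gene to unit
mean and linearly interpolate to 100 gene-body bins, so uniform input yields
the constant 1.

## Comparative statistics

`binned_correlation` sorts matched pairs (by the x dataset; the sort axis is
configurable and recorded because published binned-dot plots rarely state it),
averages consecutive groups of 5, and reports Pearson r on both the binned
dots and the raw pairs — published r values of this kind are often ambiguous
between the two, so both are always given.  `overlap_fisher` scores a 2x2
membership table with the two-sided Fisher exact test under the
minimum-likelihood convention (all tables with probability ≤ the observed
one); the odds ratio is the sample cross-product ratio, Haldane-corrected by
0.5 only when a cell is zero (and flagged).  `set_enrichment` applies this
per collection set with BH correction across sets — a self-contained,
reproducible stand-in for web-service annotation-chart tools.

## Coordinates and formats

All coordinates are 0-based, half-open; codon index = nt offset / 3 from the
main-ORF start.  Annotation is BED12 with the main ORF as the thick region
and uORFs as blocks ending before thickStart (chromStart sits at the first
block, as browsers require; the leader length survives via thickStart).
Counts, expression, TE tables, truth tables, profiles: TSV, gzip transparent.
Gene sets: GMT.  Every pipeline run writes its resolved configuration, seed
and a manifest of artifact SHA-256 hashes; identical configuration and seed
reproduce identical hashes.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis must survive: a
confounded per-library depth, a global per-cell shift invisible to
compositional normalization, abundance-coupled effect sizes, a tight
co-regulated high-abundance class, overdispersed counts, and uORF-dominated
footprint geometry on one regulator gene.  It does not model read-level
artifacts (footprint length distributions, mapping bias, GC/length bias),
gene-specific dispersion trends, batch structure beyond depth, cryptic or
intergenic transcription, or correlated effects between neighbouring genes.
Passing recovery tests therefore validates the estimators against exactly
these modelled features, not against every failure mode of real libraries.

## Problem sizes used in tests

Unit tests run a scaled-down universe (300 genes, 24 spikes); the acceptance
suite runs the full 6553-gene scenario over five seeds for prevalence
recovery and three seeds for the RPG class, 1500 genes for the
spike-vs-naive contrast, 3000 for the null control, and 1000 Monte-Carlo
replicates for the slope z-test — sizes chosen so the whole suite completes
in seconds while keeping binomial/Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* The moderated test shrinks toward a single global prior variance; with a
  strong mean-variance trend a trended prior would be more powerful.
* The spike factor pools all species linearly, so it is dominated by the most
  abundant ones; the trimmed variant mitigates gross single-species failures
  but there is no per-species outlier model.
* Fold-change estimates are not shrunk; low-count genes have noisy log2FC
  even when their significance calls are calibrated.
* TE is a plug-in ratio of normalized means, not a count-model GLM with an
  interaction term; with three replicates the moderated-t route is simpler
  and adequate, but a GLM would propagate count uncertainty more faithfully.
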