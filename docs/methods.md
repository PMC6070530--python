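# Methods

`brainvar` quantifies sex differences in the *variability* of brain gene
expression across development and asks whether the genes driving them are
co-expressed with GWAS risk genes. This note describes the statistical
procedures, the synthetic cohorts used to validate them, and the numerical
and design choices a maintainer should know about.

## The expression-similarity statistic

All statistics operate on a preprocessed gene × sample matrix within a
*stratum*: the samples of one regional cluster (one of four groups of the
16 brain-region codes) in one age-bin (a sliding window of three
consecutive developmental periods; 13 periods spanning 6 post-conceptional
weeks to 40 years yield 11 overlapping bins).

Expression similarity for one sex is the mean of all pairwise Pearson
correlations between subjects' expression profiles across all genes (upper
triangle only). Because most donors contribute several regional samples,
and donor counts differ between sexes, estimation uses a three-stage
resampling scheme per repetition:

1. select one sample per donor uniformly at random (removes within-donor
   dependence);
2. per sex, bootstrap donors with replacement and reduce to the unique set
   (prevents self-correlations of duplicated donors);
3. subsample the larger sex's unique set, without replacement, to the
   smaller sex's count (equalises subject numbers).

The point estimate is the mean over `n_point_resamples` (default 100)
repetitions; the confidence interval is the empirical 2.5th/97.5th
percentile of the repetition values (linear interpolation between order
statistics). A repetition in which a sex cannot retain two unique donors
is redrawn a bounded number of times (default 10) and then skipped.

**Sex-difference test.** The cluster-level statistic is D = mean over the
cluster's included bins of (female − male similarity). Significance comes
from permuting sex labels at the donor level: one permutation per
repetition over the union of the cluster's donors, so every sample of a
donor — across regions *and* across the overlapping bins — carries the
same permuted label. This consistency matters: permuting bins
independently lets bin-level differences average out across bins in a way
the observed statistic cannot, and the test becomes sharply
anticonservative (measured type-I rate ≈0.27 at α=0.05 versus 0.03–0.05
for the consistent scheme). The test is two-sided via |D|; the empirical p
is the fraction of `n_null_resamples` (default 1000) permutations with
|D_perm| ≥ |D_obs|, Bonferroni-corrected over the clusters tested. An
empirical p of 0 is reported together with its resolution bound
`p_lt = 1/n_null_resamples`. The inner repetition count used when
re-scoring D inside each permutation defaults to `n_point_resamples`
(exchangeable with the observed statistic); it can be reduced for speed,
which only widens the null.

## Variability genes and transfer

Per stratum and sex, each gene's standard deviation across the selected
subjects is computed per repetition (ddof = 1) and averaged over
repetitions. Genes are ranked by the male/female ratio of these averaged
SDs; the top `top_k` (default 100) are the stratum's variability genes.
Genes whose female SD falls below 1e-8 are excluded (a constant gene would
give an infinite ratio); ratio ties break by larger male SD, then gene id.

Transfer to a second dataset is scored by the female-minus-male similarity
difference restricted to the gene set, compared one-sidedly against 1000
*variance-matched* random sets: each real gene is replaced by a random
gene whose SD (plain per-gene SD over the male samples of the included
strata) lies within `sd_match_tolerance` (default 5%) of it; replacement
genes are not reused within one null set, and the window doubles (at most
four times, logged) when empty.

## Co-expression with risk genes

One risk gene per GWAS locus: the gene closest to the locus's most
significant index variant, with distance 0 inside the gene body and
1-based inclusive coordinates; MHC-overlapping genes (default
chr6:25–34 Mb, overridable) are excluded, duplicates across loci collapse
to one entry, and unannotated candidates are dropped with a log entry.
Distance ties break lexicographically.

Co-expression between a variability set and the risk set is the median of
all cross-set pairwise Pearson correlations over male subjects (self-pairs
excluded, zero-variance genes dropped). It is computed inside the same
resampling scheme, stages 1–2 only and males only, and averaged over
repetitions. The null replaces the variability set by variance-matched
random sets scored identically; the empirical p is the fraction of null
values at least as high as observed (one-sided), with family-wise error
control over the tested variability sets (11 bins × 2 cortical clusters =
22 by default). Each null set is scored with a reduced inner repetition
count (default 10); this widens the null slightly and is therefore
conservative — set `n_coexpr_null_inner = n_point_resamples` for the
exchangeable variant, which the calibration suite uses.

Specificity comparisons rebuild the "risk" set by: a uniform random gene
per locus; a random gene from a random same-chromosome window of equal
size whose common-variant density (from a per-window count track, overlap
weighted) lies within 10% of the source locus, the window extended by
20 kb per side (uniform window starts, up to 10 000 attempts per locus);
a uniform random same-chromosome gene per reference gene; or an external
one-id-per-line gene list.

**Age windows.** Within a chosen set of bins, every run of four
consecutive distinct donor ages forms a window (sliding by one); per
window the pipeline reports the sex difference of similarity restricted to
the combined variability genes (when both sexes have ≥2 donors) and the
male-only co-expression with the risk set.

## Preprocessing

Order: RIN filter → age filter and autosome extraction → (RPKM floor,
RNA-seq only) → log2 → quantile normalisation → replicate collapsing (per
donor and region, median values, median RIN) → pH mean-imputation →
surrogate-variable estimation → residualization → PCA outlier removal.
The `transform_log` on the dataset records the executed sequence, and
re-application of a transform is a state error.

Boundary semantics are deliberate: the microarray donor rule removes
donors with *more than* 25% of samples below RIN 7.5; the RNA-seq sample
rule removes RIN ≤ 7.5; subjects strictly older than 40 years are removed;
the RPKM rule drops genes below 1 RPKM in *more than* 50% of male or of
female samples. Quantile normalisation replaces rank r in each column by
the mean of the r-th order statistics across columns; ties receive the
mean of the reference values over their span (so tied data deliberately
depart from the common multiset).

Residualization fits, per gene, ordinary least squares on an intercept
plus age, post-mortem interval, RIN, pH, batch dummies (when present) and
the surrogate variables — never sex, whose variance effects are the
signal. Rank-deficient designs are rejected with the collinear terms
named.

**Surrogate-variable count.** A permutation analogue of spectral surrogate
-variable analysis: residualize against the full model (including sex),
take the variance fractions of the singular spectrum of the row-
standardized residuals, and compare each leading rank against the
*maximum* of B = 20 null spectra obtained by independently permuting each
row of the input and re-residualizing. Exceeding all B permutations is an
exact rank test of level 1/(B+1) ≈ 4.8%; the count is the leading
consecutive run of exceedances. Re-residualizing the permuted matrix is
what makes null and observed spectra share the model's rank deficiency;
without it the observed leading ranks win almost always. On pure noise
(200 genes × 40 samples) the estimate is 0 in ≈95% of seeds; one or two
strongly loaded planted factors (loading SD 3× noise) are recovered
essentially always. Surrogate values are the corresponding right singular
vectors; the count can be fixed in the config to bypass estimation.

**Outliers.** Separately per sex (skipped below four samples): sample
scores on the first two principal components of the centered
covariate-adjusted matrix; a sample deviating more than 3 SD from the mean
on either axis is flagged, one shot, no refit. Note a small-sample
limitation: with n samples the largest attainable deviation is
(n−1)/√n SD, so a lone outlier cannot be flagged below n ≈ 12 per sex.

## The synthetic cohorts

The generator emulates the structure of a developmental brain atlas:
donors with period-constrained ages, several regional samples each,
optional technical replicates, RIN/PMI/pH covariates with missing pH,
optional batch offsets and injected outliers; expression is simulated on
the log2 scale and exponentiated, so the pipeline's own log2 runs.

Per gene g and sample s the log2 value is a baseline mean (N(6, 1)), plus
a cluster-level program offset (SD 1.6 per regional cluster), a region
offset (SD 0.2), a random-walk developmental trajectory across the 13
periods (step SD 0.25), a linear age trend on 30% of genes, small
RIN/PMI/pH effects, optional batch offsets, the latent-factor term, and
Gaussian noise with gene-specific SD σ_g ~ U(0.4, 1.4). The shared
programs are essential: per-gene residualization removes gene means, so
without structure that varies across the dataset but is shared within a
stratum, between-subject similarity would be ≈0 and a noise-inflation
signal would have nothing to dilute. With the defaults, baseline
similarity is ≈0.5, in the range real cohorts show.

Planted signal:

* *Variability genes* — a fraction (default 10%) of genes, drawn among
  those with σ_g ≤ 0.7 so that λ-inflated SDs stay inside the cohort SD
  range (keeping variance-matched nulls populated by factor-free genes),
  get their noise SD multiplied by λ (default 2) in male samples,
  optionally restricted to designated periods/regions.
* *Risk genes* — a disjoint set (default 30) sharing a standard-normal
  per-donor latent factor with the variability genes; loadings are scaled
  to the male noise level, c = sqrt(ρ*/(1−ρ*)) times the male SD, so the
  expected male cross-correlation between loaded genes is ρ* (default
  0.3). A consequence worth knowing: with λ > 1 and ρ* > 0 planted
  together, the factor also inflates female variance of the variability
  genes, compressing the SD ratio toward
  λ·sqrt((1+c²)/(1+λ²c²)) ≈ 1.45 and attenuating the similarity
  difference; validation therefore plants one signal at a time.

The toy genome places genes non-overlapping on chromosomes 1 and 2
(100 kb spacing); each risk gene receives a locus wide enough to harbour
neighbours with the index variant inside the gene body, so the
closest-gene rule recovers the planted set exactly; a decoy gene/locus
inside an MHC-like window on chromosome 6 and a duplicated locus exercise
the exclusion and dedup rules; the variant-density track is uniform.

What the generator does *not* emulate: realistic transcriptome-wide
covariance (modules beyond the single factor), platform-specific noise,
count statistics, genotypes, or donor-level expression heritability.
Passing tests therefore demonstrate the statistical machinery — donor-aware
resampling, calibration of the permutation and matched-null tests,
recovery of planted variance and co-expression structure — not fidelity to
any particular tissue atlas.

## Validation harnesses and problem sizes

The desk-scale study design used throughout validation
(`simulate.study_params`) has 10 donors per sex concentrated in
mid-development (periods 8–9), the 11 cortical regions of clusters 1–2,
and 1000 genes — statistics here are scale-free in gene count, and 1000
keeps the full suite around seven minutes on one CPU. Null calibration
uses 200 smaller signal-free cohorts (4 donors/sex, 4 regions, 150 genes)
at 20 point-resamples and 200 permutations, the sex-difference rejection
rate checked against the binomial 95% interval around 0.05 and the
co-expression p-values against uniformity (Kolmogorov–Smirnov, α=0.01).
Recovery and power use 25 seeds each: λ=2 recovers a median >0.8 of the
planted genes and a significant positive D in ≥80% of seeds; ρ*=0.3
yields co-expression p < 0.05 in ≥90% of seeds, with the ρ*=0 harness flat.
Harnesses fix the surrogate count at 0 (the config bypass), matching the
estimate the primary microarray cohort reportedly yields; with estimation
on, the planted cluster/age programs themselves would be absorbed as
surrogates. Surrogate estimation is validated separately on matrices with
known factor counts.

Exactness of the resampling machinery is pinned by a brute-force oracle:
an independent loop re-implementation consumes the identical documented
random substreams — one `random(n_donors)` array for stage 1, per-sex
`integers` bootstraps, a `choice` subsample — and must reproduce every
drawn donor/sample selection exactly and every estimate, CI and SD to
1e-12 (the vectorized and loop implementations order floating-point
operations differently).

## Randomness and determinism

One master seed governs everything. Every (stratum, repetition),
permutation and null replicate derives an independent substream as
`SeedSequence([seed, *keys])` with CRC32-hashed string keys, so results
are invariant to evaluation order and identical runs are byte-identical
(result writers emit a JSON manifest with seed, config echo, versions and
the transform log).

## Known limitations

* The permutation test needs several donors per sex; strata at the
  configured minimum of two donors per sex yield frequent draw retries
  and wide CIs, and a three-male-donor stratum can fail the co-expression
  draw requirement entirely (such strata/replicates are skipped with a
  log entry rather than fabricated).
* The outlier rule is per-axis on two PCs (not a joint Mahalanobis
  distance) and is blind below ≈12 samples per sex.
* The age-period table is a stand-in modelled on the public developmental
  atlas scheme; analyses of real cohorts should supply the published
  period boundaries as a TSV.
* `estimate_surrogate_count` is a permutation analogue, not a clone of
  any particular published implementation; its count is bypassable via
  config.
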