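# Methods

This note documents the models and procedures implemented in
`prosubtype`, the defaults that matter, what the synthetic-data
generators do and do not emulate, and the numerically delicate choices.

## Marker-gene selection

Two routes define the epithelial marker universe.

**Single-cell route.** For each target epithelial population (luminal,
basal, club-like, hillock-like, neuroendocrine), each gene is tested by
a two-sided Wilcoxon rank-sum against all remaining cells pooled.
P-values are Benjamini–Hochberg adjusted per population; a gene is
called when adjusted p < 0.05, linear fold change > 2, and the
population mean exceeds the rest mean.  The rank-sum test is chosen
because it is distribution-free and the community default for
single-cell differential expression; the fold-change threshold guards
against statistically significant but biologically negligible shifts in
large cell numbers.

**Sorted-bulk route.** On FPKM-like profiles of sorted populations, a
gene is selected when mean(all epithelial groups) / mean(stromal
groups) exceeds 5, or mean(one epithelial group) / mean(remaining
epithelial groups) exceeds 5.  Both comparisons are strict: a gene at
exactly 5-fold is excluded.  A pseudocount of 0.01 (FPKM units) is
added to numerator and denominator means so zero-expression genes yield
bounded ratios; the pseudocount is configurable and can be set to 0
when inputs are known positive.

The two lists are merged as a union on gene IDs, with genes present in
both tagged `both`.  Gene identifiers are opaque strings; an optional
symbol→ID map is applied at read or merge time, dropping unmapped genes
with a logged count (mimicking the practical step of restricting to
genes with a stable database identity).

## Purity gate and consensus clustering

Bulk tumor cohorts are gated on tumor purity before class discovery:
a sample is retained only when at least one DNA-based and one RNA-based
purity score are available and **every** available score is strictly
above 0.5.  Requiring both assay families guards against calling a
sample pure from one noisy estimator; samples without purity data are
excluded rather than imputed.

Consensus clustering follows the Monti et al. subsampling scheme:

* genes are standardized to mean 0 / SD 1 **once**, before resampling
  (zero-variance genes are excluded with a warning); this makes the
  procedure invariant to per-gene affine transforms;
* for each k in 2..15 (default), 20 iterations subsample 80% of the
  samples without replacement and partition them with the base
  clusterer under Euclidean distance;
* consensus(i, j) = co-clustering count / co-sampling count; pairs
  never co-sampled (possible at low iteration counts) get 0 with a
  warning;
* k is chosen to minimize the PAC — the fraction of off-diagonal
  consensus entries strictly inside (0.1, 0.9) — with ties going to the
  smaller k; the final assignment cuts an average-linkage tree on
  1 − consensus at the chosen k.

The default base clusterer is k-means with a **single** k-means++
initialization per subsample.  This is deliberate: with multi-restart
k-means, a wrong k still produces the same (best-inertia) partition on
almost every subsample, so its consensus matrix is near-binary and PAC
cannot distinguish it from the true k.  A single stochastic
initialization lets initialization variability expose unstable k, which
is exactly the signal PAC summarizes.  A one-dimensional self-organizing
map (1×k grid, Gaussian neighborhood, exponentially decaying learning
rate, 2000 update steps) is available via `base="som"` for users who
want the SOM formulation; it recovers planted partitions equally well
but is slower.

Degenerate input (all samples identical) yields consensus ≡ 1, PAC = 0
at every k, and k = 2 by the tie-break; the average-linkage cut may then
produce fewer than k distinct labels, which is logged rather than
raised.

## Signature matrix and deconvolution

Cluster-discriminating genes are those with Kruskal–Wallis BH-adjusted
q < 0.05 across the reference clusters, restricted to the marker
universe.  The signature entry (g, c) is the arithmetic mean
linear-scale expression of gene g over samples assigned to cluster c;
all-zero rows are dropped.

Deconvolution regresses each mixture on the signature columns with
ν-support-vector regression (linear kernel, C = 1) for
ν ∈ {0.25, 0.5, 0.75}, keeping the ν with the lowest RMSE between
fitted and observed values.  Before fitting, the signature matrix and
the mixture vector are each z-scored **as whole arrays** (single mean
and SD per array).  Whole-array standardization preserves the relative
scales of the signature columns; z-scoring each column separately would
rescale coefficient j by SD(column j) and bias the recovered
proportions whenever cluster profiles differ in dispersion.  Negative
coefficients are clipped to zero and the remainder renormalized to the
proportion-estimate (PE) vector.

Significance is a gene-permutation test: the mixture values are
permuted across genes `n_perm` times (default 100), the model refit at
the selected ν, and the p-value is the fraction of permutations whose
Pearson correlation between fitted and observed values reaches the
observed correlation.  Samples with p ≥ 0.05 are labeled
`unclassified` rather than forced into a subtype.  Significant samples
follow the PEmax rule: strictly above 0.5 → that cluster ("pure");
at or below 0.5 → `mixed` (the 0.5 boundary is mixed).

`nnls_proportions` solves the same standardized system by non-negative
least squares and serves as an independent cross-check; on noisy
Dirichlet mixtures the two routes agree within a few percent, and both
recover known proportions with mean absolute error below 0.01 at noise
CV 0.1.

## ssGSEA and drug-sensitivity scores

Genes are ordered by decreasing expression, ties broken by gene ID so
scores are reproducible across runs.  With N genes, set size m, and the
gene at position j carrying rank statistic N − j + 1, the running sum
steps up by (rank statistic)^w normalized over in-set genes for in-set
genes, and down by 1/(N − m) otherwise; the score is the sum of the
running sum over all positions divided by N (an integrated, rather than
extremum, statistic).  The default exponent w = 0.75 matches the
weighted formulation of Barbie et al.; at w = 0 the score is purely
rank-based, invariant under strictly monotone transforms of expression,
and a set and its complement score to exactly opposite values — both
properties are asserted in tests, alongside exact agreement with a
brute-force enumeration of the running sum on all subsets of small gene
universes.

The docetaxel responder score is ssGSEA(overexpressed responder genes)
minus ssGSEA(underexpressed responder genes), computed on raw scores
first and z-normalized (ddof = 1) across samples afterwards; the order
matters only by a scale factor, and subtract-then-normalize keeps the
two components on their common within-sample scale.  The gene sets are
supplied as GMT input (13 up / 43 down in the motivating application).
The paclitaxel-style set construction keeps genes whose Pearson
correlation with a per-sample sensitivity value is strictly above 0.3,
skipping zero-variance genes.

Score–PE association uses Spearman rank correlation with two-tailed
p-values over the samples shared between a score panel and a call set
(≥ 5 required).  Group-wise score comparisons use a Kruskal–Wallis
omnibus test followed by Dunn's pairwise z-tests on pooled mid-ranks
with tie correction, Bonferroni-adjusted over pairs (the conventional
default when the correction is not otherwise specified); all-identical
data returns p = 1 by convention.

## Serum markers and survival

PAP measured in U/L is calibrated to ng/mL by ordinary least squares on
paired measurements from both assays; converted values are floored at 0
with a warning.  The PSA/PAP ratio (PPR) is linear serum PSA over
calibrated PAP (always ng/mL first — mixing units across assays would
make the cutoff meaningless), undefined at PAP = 0, and dichotomized at
20 with the boundary in the low group.  The transcript analogue is
KLK3 log2 expression minus ACP3 log2 expression.

Kaplan–Meier curves use the product-limit estimator (via lifelines);
the reported median is the smallest observed time with S(t) ≤ 0.5,
missing when the curve never reaches 0.5.  The log-rank test
accumulates observed and expected events and the hypergeometric
variance over pooled distinct event times, with censored observations
at a tied time remaining at risk at that time (standard convention,
stated because inputs with heavy ties are common in day-resolution
data).  The hazard ratio uses the classical stratified Mantel–Haenszel
form HR = Σ(d_A·n_B/n) / Σ(d_B·n_A/n), which is consistent for the
true hazard ratio under proportional hazards; the simpler
(O_A/E_A)/(O_B/E_B) ratio was rejected because it is biased toward 1
for effects far from the null under long follow-up (measured ≈ 2.7 for
a true ratio of 3.4).  The 95% CI multiplies HR by exp(±1.96/√V) with V
the log-rank variance (Peto-style).  The in-house risk-table
computation is cross-checked against lifelines' log-rank test in the
suite.

The AVPC molecular-signature flag is true when at least two of PTEN,
TP53, RB1 carry any alteration (mutation, deletion, or both — each
gene counts once).  Enrichment scans run chi-square tests of
independence per categorical feature (no continuity correction by
default, configurable) with BH adjustment across features; constant
features are skipped.

## Synthetic-data generators

The generators exist so every stage can be scored against known truth
without external downloads.

* **Reference** (`simulate_reference`): 1000 genes; five epithelial and
  two stromal populations; per-population blocks of 20 disjoint marker
  genes at 10× fold change plus a 30-gene pan-epithelial block; 150
  cells per type.  Baseline gene means are log-normal (log-mean 1,
  log-SD 1, i.e. typical means of a few FPKM with a long right tail);
  single-cell counts are negative-binomial with dispersion 0.5
  (var = μ + 0.5μ², realistic single-cell overdispersion) and dropout
  probability 0.2; sorted-bulk columns are the type means with
  multiplicative log-normal noise (CV 0.1, three replicates per type).
* **Cluster profiles / mixtures**: four cluster profiles over 300 genes
  with 30-gene marker blocks at 8× fold; mixtures draw weights from a
  flat Dirichlet (α = 1) — yielding a realistic mix of dominated and
  genuinely mixed samples — and apply gene-wise log-normal noise.
* **Cohort** (`simulate_cohort`): exponential event times with group
  rate ln 2 / median; default groups mirror a 30-patient mCRPC
  docetaxel cohort — a PSA-high group (11/30, median rPFS 91 days,
  serum PSA ≈ 120, PAP ≈ 1.5 ng/mL) and a PAP-high group (19/30,
  median 210 days, PSA ≈ 20, PAP ≈ 5), log-normal serum values with
  log-SD 0.3 so the two groups separate cleanly at PPR = 20; overall
  survival medians 309/551 days.  Group sizes are apportioned
  deterministically (largest remainder), so the 11/19 split is exact;
  censoring is Bernoulli per patient (default rate 0.1) at a uniform
  fraction of the event time.
* **Planted clusters** (`simulate_planted_clusters`): isotropic
  Gaussian blobs whose minimum center separation is expressed in units
  of the noise **norm** SD (√n_genes per-coordinate SDs).  Separation
  measured per coordinate would leave 50-dimensional blobs overlapping
  in Euclidean distance and say nothing about the clustering machinery.

What the generators do **not** emulate: real library-size variation,
batch structure, gene–gene correlation beyond the planted blocks,
ambient RNA, doublets, non-proportional hazards, or informative
censoring.  Passing recovery tests therefore demonstrates that the
machinery is implemented correctly and calibrated under its own
assumptions — not that the biological conclusions transfer to any
particular real cohort.

## Problem sizes and numerical notes

The test suite and the acceptance script run the pipeline at deliberate
desk scale: 200 mixtures × 300 genes for deconvolution recovery, 40
samples × 50 genes × 10 seeds for consensus recovery, 1000 replicates
for null-calibration checks, and n = 10000 for estimator-consistency
checks — sizes at which the measured quantities are stable but a full
run stays in the minutes range on one CPU.  Permutation counts are
reduced (20–30) where only point estimates, not p-value resolution, are
under test.

Other numerical conventions: ssGSEA ties break by gene ID; duplicate
gene rows collapse by per-sample maximum at read time; z-normalization
uses ddof = 1 and returns missing values (with a warning) for constant
columns; consensus RNG derives an independent stream per (k, iteration)
from the master seed, so results are reproducible and trivially
parallelizable; PE vectors are renormalized after clipping and always
sum to 1 within 1e−9.

## Known limitations

* The exact marker-gene count of any real cohort depends on upstream
  preprocessing choices that are not part of this package; only the
  selection rules themselves are reproduced.
* The consensus SOM option uses a standard exponential-decay schedule;
  it is not bit-compatible with any particular historical
  implementation.
* The log-rank/Mantel–Haenszel machinery handles two groups only.
* The permutation p-value has resolution 1/n_perm; at the default 100
  permutations the smallest attainable value is 0, reported as such
  rather than smoothed.
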