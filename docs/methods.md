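# Methods

`scprogression` implements the statistical core of a paired longitudinal
single-cell analysis of leukemia progression: each patient contributes one
sample at an indolent disease stage and one after transition to active
disease, and every question is asked within or across these pairs. The
package ships a synthetic-cohort generator with planted ground truth, so
each stage can be validated end to end without any external data.

## Differential abundance of subclusters

For one pair, cells are assigned to subclusters (SNN modularity
clustering, below) and each cluster's share of cells is compared between
time points. The effect size for cluster *c* is the log2 fold-difference

    log2FD(c) = log2( p_A(c) / p_I(c) ),   p_T(c) = (n_T(c) + 0.5) / (N_T + 0.5 K)

with a Haldane-style +0.5 pseudo-count per cluster (K clusters, N_T cells
at time point T) so the statistic is finite for empty cells. Significance
comes from a two-sided permutation null that shuffles the time-point
labels over the pair's cells while keeping the cluster memberships fixed.
Holding cluster sizes fixed, a uniformly random label assignment makes
the vector of per-cluster active-cell counts exactly multivariate
hypergeometric (colors = cluster sizes, draws = N_A); the implementation
samples that law directly, which is distributionally identical to
explicit shuffling and runs vectorized. P-values use the add-one
convention p = (1 + #{|log2FD_b| >= |log2FD_obs|}) / (B + 1) with B =
10,000 by default; exact permutation ties are compared with a 1e-9
relative tolerance because the same composition reached through the
mirrored float ratio can differ in the last bit. BH FDR is computed
across the pair's clusters, and a cluster is called expanding when
FDR < 0.05 and log2FD >= +1, shrinking when FDR < 0.05 and log2FD <= -1,
stable otherwise. Calibration and power are verified against exhaustive
enumeration on an 8-cell instance, a 500-pair null simulation (rejection
rate in [0.03, 0.07] at alpha = 0.05), and 100 pairs with planted
four-fold shifts (sensitivity >= 0.9, misclassification <= 0.1).

## Cell-level differential expression

Per pair, genes detected in fewer than 1% of the pair's cells are
dropped; the remaining genes are tested with a two-sided Wilcoxon
rank-sum test on log-normalized expression. Groups of at most 8 cells
with no ties use the exact U distribution (computed by the classic
two-sample counting recurrence); otherwise the normal approximation with
tie correction and 0.5 continuity correction is used. Ranking is done
row-wise on a genes-by-cells layout with a vectorized run-length scan,
which matches `scipy.stats.rankdata` bit-for-bit and is the step that
dominates runtime at cohort scale. Fold changes are computed on de-logged
means with a pseudo-count of one, `log2((mean expm1 x_A + 1)/(mean expm1
x_B + 1))`, and DEGs require BH-adjusted p < 0.05 (strict) together with
|log2FC| >= 0.5 (non-strict).

## DEG recurrence across patients

The recurrence statistic S is the number of genes called DEG in at least
k pairs (k = 2 by default, direction ignored). Each of B = 10,000 null
draws resamples |DEG_i| genes uniformly without replacement from pair
i's own tested-gene universe — pairs filter genes independently, so the
universes differ — and the one-sided p-value is add-one as above. On two
pairs with a shared universe the null overlap is exactly hypergeometric,
which the tests verify by chi-square goodness of fit.

## Pseudobulk negative-binomial LRT

Raw counts are summed per group (cluster or sample). Each gene follows a
log-link NB2 GLM with offset log(total counts of the group); dispersions
are method-of-moments estimates from the full-model fitted means with a
residual-degrees-of-freedom correction n/(n-p), clipped to [1e-8, 10] and
shrunk toward the 10% trimmed-mean common dispersion with weight
n/(n + 10). The condition effect is tested by likelihood ratio against
the nested model (intercept, plus patient blocks when the design is
paired), p from chi-square with one degree of freedom; fits use a small
Fisher-scoring routine with a ridge of 1e-10 and linear predictors
clipped at +/-30. Because the offset is the total count, planted effects
concentrated on one sign shift the library size and are partially
absorbed; validation therefore plants sign-balanced effects. Null
simulations at the tested design (2,000 genes, 4 vs 4 groups, dispersion
0.1) give type-I error <= 0.08 at alpha = 0.05 and recover a planted
4-fold change with median log2FC error <= 0.15.

The pipeline aggregates raw counts rather than normalized values because
the NB model requires counts; per-cell normalization is deliberately not
applied before aggregation.

## Signature and metabolic scoring

*Module scores.* All genes are placed into 24 equal-frequency bins of
their mean normalized expression over the entire dataset being compared
(ties broken by a seeded jitter of 1e-9 on ordinal ranks so the binning
is deterministic). For each gene-set gene, 100 control genes are drawn
without replacement from its bin; controls are pooled across set genes
with duplicates retained. The per-cell score is the set's mean expression
minus the pooled controls' mean. Both means are computed on per-cell
shifted values (shift = the first set gene's value in that cell), which
is algebraically a no-op but makes the cancellation exact on constant
input. Unbiasedness (mean score ~ 0 for random sets) and planted-signature
detection (the boosted cluster ranks first in >= 95% of replicates) are
simulation-tested.

*Activity scores.* Cluster pseudobulk = per-gene mean of raw counts,
library-normalized to 1e4 and log1p transformed. Per gene, clusters get
mid-rank percentiles (rank - 0.5)/K; a set's activity per cluster is the
mean percentile over member genes minus 0.5. With this convention ties
land exactly at 0 and scores are bounded by [-0.5, 0.5] by construction.

*Metabolic fraction.* The share of a unit's protein-coding transcripts
belonging to metabolism-associated genes. Per-sample values pool counts
(equivalently, the count-weighted mean of per-cell fractions); genes
flagged metabolic but not protein-coding are warned about and
intersected away.

*Condition comparisons of sample means* use a permutation test that
handles mixed designs: within each fully sampled patient the two labels
are swapped with probability 1/2 (a sign flip of that patient's paired
contrast), while labels of unpaired samples are permuted among the
unpaired samples preserving condition counts; B = 10,000, two-sided,
add-one. On fully paired designs this reproduces the exact sign-flip
test, verified by enumeration at n = 8 pairs.

*Pseudotime orientation.* Trajectories are min-max rescaled to [0, 1]
and flipped when indolent cells average later than active cells, so 0
always reads as the indolent expression state. Constant input returns
0.5 everywhere with a warning. Trajectory inference itself is out of
scope; only the orientation rule is implemented.

## Somatic short-variant filtering

A variant is retained iff VAF >= 0.05, depth >= 10, alt reads >= 3,
population AF <= 0.01, dbSNP MAF <= 0.05 and TOPMed MAF <= 0.05 (all
boundaries inclusive on the passing side). Population-frequency INFO
keys are configurable because annotation dialects differ; absent
annotations pass their criterion, reflecting tumor-only calling where
many sites are unannotated. Failing records list every violated
criterion. The filter is monotone in each threshold (property-tested)
and idempotent. VAF trajectories match variants across time points on
the exact (chrom, pos, ref, alt) key; a variant absent at one time point
contributes 0 there and is flagged emergent/vanishing. htslib returns
Float INFO fields as float32; the reader reformats them to 6 significant
digits so decimal thresholds written to VCF compare exactly.

## Preprocessing

QC keeps cells with 250-4500 detected features and mitochondrial
fraction strictly below 20% (zero-count cells have pct_mito defined as
0 and fail the feature floor). Normalization scales each cell to 10,000
counts and applies log1p (natural log), preserving sparsity. The
embedding standardizes the 2,000 most variable genes (variance of
normalized values), clips at +/-10, and takes the top 15 principal
components; exact full SVD is used up to 1,000 retained genes and seeded
randomized SVD beyond that (deterministic per seed), with component
signs fixed by making each loading's largest-magnitude entry positive.
Clustering builds the Euclidean k-NN graph (k = 20, neighbor sets
include the cell itself), weights pairs by the Jaccard overlap of
neighbor sets, prunes weights below 1/15, and optimizes RB-configuration
modularity (Leiden, seeded, 2 iterations) at the requested resolution;
labels are relabeled by decreasing cluster size. The neighbor count and
prune threshold are upstream-tool defaults, recorded as assumptions. Of
note, modularity at resolution 1.5 legitimately refines a 200-cell
community into several parts — the same behavior the upstream tool
shows — so exact planted-partition recovery is only expected at
resolutions that keep communities whole. Anchor-based pair integration
is replaced by joint PCA over the concatenated pair: the synthetic data
carries no batch effect and integration internals are out of scope.

## The synthetic cohort

`SimConfig` defaults describe a paired cohort of 11 patients, 3,000
cells per sample and 5,000 genes (a desk-scale stand-in for a
~200,000-cell atlas; validation runs use 2-4 patients). Per patient and
time point, cells are allocated to 8 subclusters by a multinomial.
Planted cluster dynamics are exact: when expanding (+delta) and
shrinking (-delta) clusters are planted together, the indolent
proportions solve a small balance equation so that planted clusters
realize exactly the configured log2 fold-difference and all remaining
clusters keep identical proportions at both time points (the default
plants +2/-2, i.e. proportions 0.05->0.20 and 0.20->0.05 at K = 8).

Counts are gamma-Poisson (negative binomial, dispersion 0.3 — typical
for UMI data) with log-normal library sizes (median 2,500 counts) over a
shared log-normal baseline profile. All planted effects multiply the
mean, so true log2FCs equal configured values exactly: DEGs multiply a
patient's active-time-point mean (recurrent genes hit >= 2 patients,
private genes exactly one, sign random per gene); cluster marker
programs (25 genes at log2FC 2 per cluster) act at both time points and
give subclones the transcriptional identity that real tumor subclones
have — without them graph clustering could not recover the planted
partition, and cluster-level validation would be meaningless; signature
sets multiply their genes in planted expanding clusters. Mitochondrial
genes are mean-boosted to a 5% expected mitochondrial fraction, and
genes carry protein-coding (80%) and metabolic (10%) flags so QC and the
metabolic fraction are exercisable. Somatic variants draw binomial alt
reads at configured depths; the default panel has three ATM lesions
rising from 69.77% to 91.33% VAF between time points and stable
JAK/STAT subclones at low VAF.

What the generator deliberately omits: ambient RNA, doublets, batch
effects beyond patient identity, zero-inflation beyond NB, and any
gene-gene correlation structure within a cluster. Passing tests
therefore demonstrate the statistical machinery is correct and
calibrated under the stated model, not that the pipeline is robust to
artifacts real droplet data can carry.

## Determinism and problem sizes

One global seed drives everything: per-stage seeds are derived by
hashing the stage name with SHA-256 (kept below 2^31), so any stage can
be reproduced in isolation and the pipeline report is byte-identical
across reruns of the same config and seed. Validation problem sizes —
500 null pairs of 2,000 cells for calibration, 100 planted pairs of
3,000 cells for power, 2,000-gene pseudobulk simulations, and a
4-patient, 3,000-cells-per-sample, 5,000-gene cohort for the end-to-end
run — were chosen so each check finishes in seconds to a few minutes on
one CPU while leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

- The NB dispersion shrinkage (n/(n+10) toward a trimmed mean) is a
  closed-form stand-in for empirical-Bayes tagwise shrinkage; it is
  calibrated at pseudobulk scale but less efficient than the reference
  estimator for very few groups.
- Total-count offsets make pseudobulk fold changes compositional: a
  strongly one-sided transcriptional shift is partially absorbed into
  the library size.
- The recurrence test ignores deregulation direction when counting
  overlap (a direction-aware count can be assembled from the per-pair
  tables, but the shipped statistic follows the default convention).
- Leiden partitions are order-stable only when the modularity optimum is
  unambiguous; invariance tests use well-separated instances.
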