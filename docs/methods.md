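# Methods

This note documents the models and estimators in `dcmregnet`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs bit-reproducible.

## Single-cell processing

**QC.** Cells are retained when their detected-gene count g satisfies
200 ≤ g ≤ 5000 (the removal rule is "< 200 or > 5000", so boundary cells
stay). No mitochondrial-fraction filter is applied.

**Normalization.** `x → ln(1 + 10⁴·x / total(cell))`. This removes the
library-size factor exactly on the linear scale; the test suite checks
that normalized totals decorrelate from the planted library sizes.

**Highly variable genes.** A degree-2 polynomial is fit to log₁₀ variance
vs log₁₀ mean over expressed genes; genes are ranked by observed/trend
variance with ties broken by gene id. The method is a vst-style
standardized-variance selector; it is configurable because no single HVG
definition is canonical.

**PCA.** Per-gene z-scores clipped at ±10, exact full-SVD PCA, components
ordered by variance, sign fixed so the largest-magnitude loading is
positive — the embedding is deterministic.

**Batch alignment.** Each batch's PC-space centroid is subtracted and the
global centroid restored. This is a linear stand-in for iterative mixture
integration: it removes a constant per-batch offset exactly (which is how
the generator plants batch effects) and preserves within-batch geometry.
It will not correct nonlinear or cell-type-specific batch distortions.

**Clustering.** A kNN graph (Euclidean, k = 20) is reduced to a
shared-nearest-neighbor graph; edges with zero Jaccard neighborhood
overlap are dropped. Leiden then maximizes unweighted RB-modularity at the
configured resolution (0.7 for cell typing) with a fixed seed. Modularity
is maximized on the unweighted graph deliberately: weighting by Jaccard
overlap concentrates modularity locally and fragments homogeneous
populations (two 10-SD-separated Gaussian blobs split into 4+ clusters);
unweighted optimization returns the two blobs at the default resolution.
Labels are renumbered by decreasing cluster size so the labeling is
deterministic.

**Markers and annotation.** Wilcoxon rank-sum (normal approximation,
tie-corrected, continuity-corrected) on genes pre-filtered at
|log2FC| ≥ 0.25 and detection ≥ 10% on at least one side, with BH
correction per comparison. log2FC is defined as
`log2((mean(expm1 x)+1)/(mean(expm1 y)+1))`, stable at zeros. Annotation
scores each cluster by the mean across-cluster z-score of a reference
type's markers and assigns the argmax, breaking ties by the declared type
order and reporting the winning margin.

## Metacells

Cells are over-clustered **within each group** so micro-clusters are
group-pure (the downstream contrast is between groups, and group-mixed
metacells would average it away). Retained metacells sum their members'
raw counts — summing preserves the count nature of the data — and the sum
is log-normalized; micro-clusters with ≤ 10 members are discarded
(strictly greater-than-10 retention; a `strict` flag relaxes it).
Averaging members' log-normalized profiles is available behind a flag.

The `overcluster` function defaults to resolution 50, the granularity the
full-scale study used at ~12k cells. Resolution does not transfer across
dataset sizes or graph implementations: at the synthetic default of 3,000
cells that setting produces ~3-cell fragments that the >10-cell filter
would discard entirely, so the pipeline configuration uses resolution 10,
which reproduces the intended ~20-cells-per-metacell granularity
(~120 metacells from 3,000 cells, covering ≈97% of cells).

## Regulon inference

For every gene, the importance of each candidate TF is the magnitude of
its coefficient in a ridge regression of the (standardized) gene on all
(standardized) TF expressions over metacells (λ = 1). This replaces
stochastic gradient-boosting co-expression inference with a deterministic
estimator of the same contract; the benchmark in the test suite reports
planted-edge recovery (AUROC > 0.9 at default effect sizes) so the
substitution is auditable. Importances below a configurable floor (0.01)
are zeroed. Constant genes get zero importances with a warning.

Assembly keeps each TF's top-`n` edges by importance, drops edges without
motif support, and discards TFs left with fewer than 10 targets. The
division of labor mirrors the co-expression → motif-pruning cascade of
regulon pipelines: co-expression proposes, motif evidence disposes. In
the synthetic pipeline configuration the pre-pruning truncation is
effectively disabled (top-n = n_genes): correlated responsive TFs split
ridge credit for genuinely shared targets, which can push a true edge
deep into one TF's ranking, and with a decoy-free motif table truncation
only costs sensitivity. The function default stays at 50 for use with
noisy motif evidence. Only activating "(+)" regulons are modeled, and the
TF is excluded from its own gene set by default (configurable) to avoid
self-enrichment in ssGSEA.

## Activity scoring (AUCell-style)

For a unit, genes are ranked by decreasing expression with ties broken by
ascending gene id — a deliberate divergence from tie randomization that
buys bit-reproducibility. With `k = ceil(0.05·G)` the score is the area
under the target-recovery step curve over ranks 1..k, normalized by the
maximum achievable area for the effective target set; scores live in
[0, 1] and depend on within-unit ranks only, hence are invariant to any
strictly increasing transform of a unit's expression. The top fraction
0.05 follows the common aucMaxRank convention.

Regulon specificity per cell type is `RSS = 1 − sqrt(JSD₂(p, q))` with
`p` the regulon's activity normalized over units and `q` the normalized
type indicator; base-2 JSD bounds the score in [0, 1].

Rank-based scoring has a compositional side effect worth noting: when a
responsive regulon's targets rise in the disease group, all other genes'
relative ranks fall, so null regulons acquire a small but systematic
negative group shift. The selection floor (below) is what keeps this from
contaminating the responsive set.

## CSI modules

`CSI(A,B)` is the fraction of the other N−2 regulons whose correlation
with A **and** with B does not exceed `PCC(A,B)` (non-strict inequality;
strictness configurable). Values lie on the exact grid
{0, 1/(N−2), …, 1}. Undefined correlations from constant activity columns
are stored as 0 with a warning. Modules come from average-linkage
agglomerative clustering of Euclidean distances between CSI rows, cut at
k = 8 (the module count the full-scale analysis reports; configurable),
renamed M1..Mk by decreasing size.

## Variance decomposition

Per regulon, activity over units (metacells by default) is modeled as

    y = μ + a_celltype + b_group + e,
    a ~ N(0, σ²_ct),  b ~ N(0, σ²_grp),  e ~ N(0, σ²_e),

with both factors random and an intercept as the only fixed effect. The
restricted likelihood is profiled: for variance ratios γ = σ²/σ²_e the
criterion `(n−1)·log σ̂²_e(γ) + log|W| + log(1'W⁻¹1)` is minimized over
log-γ by L-BFGS-B from a 3×3 multi-start grid (ratios 0.01, 0.1, 1 per
component), with Woodbury/determinant-lemma identities reducing every
evaluation to algebra on the q×q level matrix. Ratios driven to the lower
bound are reported as exact zero components; a fit is flagged converged
when the optimizer succeeds at the optimum or two starts agree on it. The
response is centered before the sufficient statistics are formed — the
intercept absorbs the shift and the statistics stay well-conditioned.
Estimates are shift-invariant and scale-equivariant; in balanced one-factor
designs the optimum equals the ANOVA moment estimator max(0, (MSB−MSW)/n),
which the test suite uses as a closed-form oracle.

Estimating σ²_grp from a two-level factor is statistically fragile; it is
retained because the disease contrast is the quantity of interest, and
the recovery benchmark (planted fractions 0.3/0.4/0.3, 500 units) bounds
the error of the group proportion at < 0.05 mean absolute.

**Knee selection.** Within each module, regulons are sorted by p_grp
descending, the y-axis min–max normalized, the x-axis mapped to rank
fractions, and segment slopes computed. The selection keeps every regulon
above the inflection where the curve flattens for good — the prefix ends
one past the last segment steeper than −1. A strictly linear curve (all
slopes exactly −1) and a flat curve select nothing. Two floors complement
the relative rule, both motivated by "variance predominantly explained by
group": selected regulons must have p_grp ≥ 0.05 (null fits sit near
zero, but min–max normalization would otherwise let the knee fire on pure
noise), and any regulon with p_grp ≥ 0.25 is selected outright (a module
composed entirely of responsive regulons has no null tail for the knee to
cut against). Modules with ≤ 2 usable regulons fall back to the floor
alone, since min–max normalization forces their mean slope to −1 and the
knee rule is degenerate there. All thresholds are configurable.

## Bulk validation

**Moderated t.** Per gene, log2FC = mean(DCM) − mean(Normal) on a
declared log2-scale matrix; pooled two-group variances s²_g with
d = n₁+n₂−2 df are shrunk toward a prior (d₀, s₀²) estimated by the
method of moments on log s²_g (digamma/trigamma matching, trigamma
inverted by Newton iteration; an observed spread at or below the sampling
spread yields d₀ = ∞, i.e. complete shrinkage). The moderated t uses
d₀+d degrees of freedom; BH gives the FDR; the screening filter is
|log2FC| > 0.5 and FDR < 0.05. As d₀ → 0 the statistic reduces to the
ordinary t (tested numerically). Zero-variance genes get missing p-values
and never pass the filter.

**ssGSEA.** Per sample, genes are ranked by decreasing expression
(average ranks at ties); walking the ranked list, in-set positions
accumulate `rank^0.25 / Σ_in-set rank^0.25` and out-set positions
`1/(G−|S|)`; the enrichment score is the sum of the running difference
over all positions (the integral form). With normalization on, the whole
score matrix is divided by its max−min range. Scores are rank-based and
invariant to monotone within-sample transforms. Group comparison is a
two-sided Wilcoxon per set with BH across sets, direction the sign of the
median difference (DCM − Normal), stars at 0.05/0.01/0.001.

## Hub targets and diagnostics

Regulons significant in every cohort are intersected by name; those with
the same direction everywhere are the consistent set (only these feed
target counting by default). Targets occurring in ≥ 2 consistent regulons
are the multi-targets; intersecting them with every cohort's screened
DEGs gives the hub targets, each reported with the regulons that carry
it. ROC AUC uses the rank (Mann–Whitney) identity with half-credit for
ties, oriented so the cohort's observed fold-change direction predicts
the disease class; 95% CIs come from a stratified bootstrap (resampling
within class, 2000 replicates, percentile interval, seed-deterministic).
Over-representation of hit lists in gene sets is a one-sided
hypergeometric test with BH, the universe defaulting to the expression
matrix's genes.

## Synthetic data

The generator plants exactly the structure the analysis is meant to find.
Per cell: a type drawn from its group's composition (defaults follow the
reported myocardial shift — cardiomyocytes 59.2% → 36.3%, endothelial
20.7% → 30.1%, fibroblasts 7.3% → 10.9%, remainder spread over pericytes,
smooth muscle, macrophages, T cells, epithelial cells); latent regulon
activities `a_r = celltype_offset[r, type] + shift_r·1[DCM] + N(0,1)`;
gene log-means = type baseline + Σ loadings·activity + small per-batch
offset; negative-binomial counts with gene-level dispersion
(lognormal around 0.3) and lognormal library sizes (median 5,000). Key
defaults and their rationale:

- **40 TFs × 25 targets, 5 responsive.** Enough regulons that 8 CSI
  modules are non-trivial; target loadings U(0.25, 0.6), activating only.
- **Cell-type offsets N(0, 2²), unit residual.** Cell identity dominates
  regulon activity variance, as in real myocardium; the disease shift is
  secondary.
- **Group shift 2 activity-SD scaled per regulon by U(0.7, 1.3).**
  Responsive regulons differ in realized effect size, which spreads their
  group-variance fractions and gives the knee rule a knee.
- **TF self-loading 1.2 and TF baselines N(1, 0.5) on the log scale.**
  The TF transcript is the only observable proxy for its regulon's
  activity; with drop-out-prone TF expression, expression-based inference
  has no signal path (a known failure mode of co-expression methods, out
  of scope here).
- **Shared target pool.** Responsive regulons draw 40% of their targets
  from a small common pool, creating multi-regulon targets — the
  synthetic analogue of co-regulated hub genes under a TF family. Decoy
  regulons draw from a disjoint pool so every planted bulk group
  difference is attributable to the responsive family and hub recovery is
  exactly checkable.
- **Bulk cohorts** are log2 composition-weighted mixtures of type
  profiles with the responsive effects applied in the DCM group plus
  N(0, 0.3) noise, shaped 16/86 and 136/82 like the validation cohorts.
- **Motif table** flags planted edges with probability 1.0 and decoys
  with 0.0 in the pipeline default (a high-precision motif-database
  stand-in; any decoy support preferentially admits correlated
  responsive-family targets, which are differential in bulk and would
  corrupt the hub set). The noisy (0.9, 0.1) regime is exercised in the
  assembly benchmark.

What the generator does **not** emulate: transcriptome-scale gene counts
(2,000 genes), doublets, ambient RNA, nonlinear batch effects, repressive
regulons, platform-specific microarray noise, or TF activity decoupled
from TF transcript abundance. Passing the planted-truth benchmarks
therefore demonstrates the pipeline's internal correctness and
end-to-end identifiability under its stated model — not performance on
real myocardium, where motif evidence is noisy, effects are weaker and
regulon structure is far denser.

## Reproducibility and problem sizes

Every stochastic stage derives its seed from the single configuration
seed; reruns are bit-identical. The default synthetic run uses 3,000
cells × 2,000 genes, ~120 metacells, 40 regulons and two bulk cohorts
(102 and 218 samples) and completes in well under a minute on one core.
The benchmark suites use 500-unit activity matrices with 50 replicates
(variance-component recovery) and 20 seeds × 50 regulons (selection
recovery), sizes at which the Monte-Carlo error of the checked quantities
is comfortably below the asserted tolerances.

## Known limitations

- The group variance component rests on two levels; its proportion is
  recoverable under the planted design but has large sampling variance in
  general designs.
- Batch centering corrects constant offsets only.
- The knee rule's floors (0.05, 0.25) are calibrated to the null scale of
  this pipeline's activity scores; other activity measures may need
  different floors.
- Ridge importances are linear; strongly nonlinear TF–target
  relationships would be under-ranked.
- ssGSEA group comparisons inherit the compositional coupling of
  rank-based scores (a large coordinated shift in one gene set slightly
  depresses all others).
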