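# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical edge-case handling.  It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute.

## Quality control and normalization

Cells are filtered on three criteria with strict comparisons: total reads
< 100,000, genes detected < 1,000, sparsity (zero-count gene fraction)
> 0.95.  A cell exactly at a threshold is retained.  The per-cell ERCC
spike-in fraction is reported but is deliberately not a removal criterion —
no spike-in threshold is part of the filter set.  Genes with a zero-count
fraction strictly above 0.95 across retained cells are removed; flagged
technical (spike-in) genes are exempt from this filter because they are
needed downstream for trend fitting regardless of biological sparsity.
The three cell rules commute and both filters are idempotent (tested).

**Deconvolution size factors.**  Cells are placed on a ring ordered by
library size.  For each pool size s in (21, 41, 61, 81, 101) truncated to
the cell count (floor: one pool size of min(21, n)), every window of s
consecutive ring positions forms a pool.  The pooled count vector is
compared with the average pseudo-cell (the per-gene mean over all cells) by
the median ratio over genes with positive pseudo-cell expression, giving
one equation per pool: the sum of member-cell factors equals the pool
ratio, up to one global scale fixed at the end by rescaling to geometric
mean 1.  The stacked system is solved by least squares.

Two numerical choices matter here.  First, window-sum systems determine
smooth (along-ring) combinations of factors strongly but cell-idiosyncratic
(high-frequency) components only weakly — the window-sum operator's
spectrum decays toward ±1 at high frequency while the aggregate direction
carries weight Σs ≈ 305.  Per-cell ridge anchors toward library-size
factors with weight 10 regularize exactly those weak directions (and fix
rank and scale) while leaving the pooled composition signal dominated by
the pool equations.  Second, non-positive least-squares solutions trigger a
non-negative refit (NNLS); cells still degenerate after that fall back to
library-size factors, with a log message.  Spike-in genes are excluded from
factor estimation (they do not scale with cell content) but stay in the
matrix.

Normalized expression is log2(count / factor + 1).  The pseudo-count of 1
matches the bulk arm's offset; the single-cell scale uses the same value
for comparability.

## Highly variable genes

Per gene, mean μ and CV² = s²/μ² are computed on size-factor-normalized
counts on the **linear** scale.  Fitting CV² against the log2-scale mean is
available behind `log2_means=True`, but the linear-scale fit is the default
because the χ² excess test below is only exact for the linear-scale
parameterization.  The trend CV²(μ) = a₁/μ + α₀ is fitted by a Gamma-family
GLM with identity link on 1/μ, started from the ordinary least-squares
solution (the GLM emits expected domain warnings for this link; they are
suppressed; if IRLS fails the OLS fit is kept).  Fit genes are the flagged
spike-ins when at least 20 are present, otherwise all genes with mean above
the 10th percentile of positive means.  Constant genes record CV² = 0 and
are excluded from fitting.  A trend non-positive anywhere over the observed
means raises a degenerate-fit error with the fitted parameters in the
message.

The test statistic is (n−1)·CV²_g / CV²(μ_g), referred to the upper tail of
χ²(n−1); p ≤ 0.01 flags a gene as highly variable, with no multiplicity
correction before the cut (an optional BH mode exists).  Under NB counts
the χ² reference is approximate; the suite checks empirically that the
false-positive rate at 0.01 stays within [0.002, 0.03] when the trend is
fitted on spike-ins, and that the null p-value distribution is not
anti-conservative (one-sided Kolmogorov bound).

## Clustering and embedding

Dissimilarity is 1 − Spearman ρ with midranks; zero-variance cells carry no
rank information, so their off-diagonal dissimilarity is set to the maximum
(2.0) with a warning, and the pipeline excludes them from clustering.  The
dendrogram is UPGMA (scipy average linkage).

Dynamic tree cut implements the adaptive "tree" variant: recursing from the
root (equivalently, scanning candidate cut heights from high to low), a
split is accepted only when both branches hold at least `min_module_size`
leaves (default 30) and the merge height is strictly positive — zero-height
merges join indistinguishable units and are never split.  When exactly one
branch is undersized, the large branch is cut further and the undersized
leaves are merged into the accepted cluster nearest by average
dissimilarity (logged).  No admissible split yields a single cluster.  The
"hybrid" variant was not implemented because its extra parameters are not
pinned down by the minimum-module-size description alone; this choice is
a known divergence risk when reproducing exact cluster counts on real
data.  Labels are
canonicalized (1..K by decreasing size) so results are invariant to input
order.

t-SNE is a contract: any faithful implementation is admissible; here
scikit-learn's, seeded (default 42, recorded in output metadata), PCA
initialization, perplexity 50 by default with the validity requirement
perplexity < (n−1)/3.

## Pseudotime

Cells are cosine-normalized (unit Euclidean norm over HVG expression;
all-zero cells are a named error).  The diffusion map: symmetric
union-kNN graph (k = 21) on Euclidean distances; Gaussian kernel with
per-cell local bandwidth σᵢ = distance to the ⌈k/2⌉-th neighbor (a global-σ
mode exists); density normalization W̃ = W/(qᵢqⱼ) (anisotropic α = 1);
row-normalization to a stochastic matrix P.  P is symmetrized as
D^{1/2} P D^{−1/2} for a stable dense eigendecomposition; the trivial
constant eigenvector (λ ≈ 1) is dropped and the next `n_components`
(default 3) eigenvector/eigenvalue pairs are returned, components scaled by
their eigenvalues, with signs fixed so each component's largest-magnitude
entry is positive.  A disconnected graph triggers a warning; components are
computed on the largest connected component and other cells remain
unassigned (label 0, excluded from state statistics).

Pseudotime is DC1, sign-oriented so mean anchor-gene (maturation-marker)
expression increases along it; absent anchors leave the sign as computed,
with a warning.  Meta-stable states are the exact optimal 1-D k-means
partition of DC1 into 4 contiguous groups, solved by dynamic programming
over the sorted values (O(kn²), deterministic, no seed); the all-equal
degenerate case returns a canonical equal-size contiguous split.  Branches
are reported descriptively from the sign of DC2 relative to the DC2 level
of the DC1-extreme deciles; the state partition itself uses DC1 only.

## Differential expression

Per gene, ordinary least squares on log2 expression with an intercept, a
treatment-coded two-level group contrast, and categorical blocking factors
(donor and plate column in the single-cell arm).  A contrast lying in the
span of the blocking columns is a design error naming the factors; aliased
blocking columns are dropped greedily and logged.  Residual variance s²_g
has df d = n − rank(X).

Moderation fits a scaled inverse-χ² prior to the s²_g by the closed-form
moment match on log s²: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), d₀
solves ψ′(d₀/2) = Var(e) − mean ψ′(d_g/2) via a Newton iteration for the
trigamma inverse, and s₀² = exp(mean e + ψ(d₀/2) − log(d₀/2)).  Non-positive
excess variance gives d₀ = ∞ (complete shrinkage to s₀²); an exactly
constant s² vector returns that value as s₀² directly (the natural fixed
point).  The moderated statistic is t̃ = β̂ / √(s̃²v) with v the contrast's
unscaled variance, referred to t with d + d₀ df (normal when d₀ = ∞).
Genes with zero moderated variance and zero effect receive t̃ = 0, p = 1
rather than being dropped.  BH step-up adjusts p-values; the default
significance threshold is q ≤ 0.01.

Variance moderation — not coefficient shrinkage — is the implemented
method; a ridge-style coefficient-shrinkage option exists but is off by
default, since the moderated-t framework this follows shrinks variances.

Bulk samples are normalized by median-of-ratios factors (median over genes
positive in every sample of count/geometric-mean), log2 offset 1.
Downsampling to a common depth draws, per sample, exactly the target number
of reads without replacement from the sample's counts (multivariate
hypergeometric) — the count-level equivalent of read subsampling; samples
already at or below the target pass through, logged.

## τ and the TRA arm

The per-gene tissue-specificity index over N tissue groups is
τ = Σ(1 − x̂ᵢ)/(N − 1) with x̂ᵢ = xᵢ/max<sub>j</sub> xⱼ.  Max-normalization
is applied because without it the sum is unbounded; this is the standard
definition of the index and the only reading under which τ ∈ [0, 1].  τ is
computed on linear-scale atlas values by default, with a log2(x+1) option
(the index's original formulation log-transforms; the linear default keeps
the arithmetic directly traceable to the formula).  Boundaries are
inclusive: τ ≥ 0.8 ⇒ TRA, τ ≤ 0.4 ⇒ constitutive.  All-zero profiles have
no defined τ and are excluded as "unclassified" (counted and logged), so
the three category proportions plus the unclassified fraction account for
every gene exactly once.

"Expressed" in a population defaults to mean size-factor-normalized count
≥ 1 across the population's replicates, evaluated after common-depth
downsampling; the threshold is configuration, stamped into reports, because
there is no single canonical operational definition.  The τ-shift comparison reports
per-population quantiles plus a one-sided Mann–Whitney p-value per ordered
pair, descriptively (no FDR).  PCA over expressed TRA genes is
gene-centered SVD; correlation clades use Pearson r on TRA-gene expression
with average linkage on 1 − r, flattened to 2 clades by default.  Atlas and
expression matrices join on exact gene-id string match; unmatched genes are
counted and logged, and the pipeline aborts when overlap falls below 50 %.

## Synthetic data

The generators encode the reference conditions each stage is tested
against.

*Atlas* (default 10,000 genes × 107 groups; 10 % TRA, 60 % constitutive,
30 % intermediate; multiplicative lognormal noise CV 0.1): TRA genes
express in 1–3 tissues and are exactly zero elsewhere (τ = 1 at breadth 1
and zero noise); constitutive genes are uniform (τ = 0); intermediate genes
have a peak over a broad moderate baseline (25–55 % of peak), placing τ
between the two thresholds.

*Single cell* (default 200 cells × 2,000 genes, 3 donors, 12 plate
columns, 40 spike-in-like technical genes): latent time per cell is
Uniform(0,1) (a bimodal option concentrates density at the ends to mimic a
two-branch pattern); 30 genes rise monotonically (CCR7/CCL19-like), 30 fall
(CCR6-like), 20 are transient (AIRE-like), nonzero only inside latent-time
window [0.75, 1.0] with a smooth onset — exactly zero outside the window
but continuous inside, so the expression manifold has no artificial jump.
Counts are NB with variance μ + αμ² (α = 0.1; α = 0 recovers Poisson);
cell size factors are lognormal (sdlog 0.25, geometric mean 1); donor and
plate-column batch effects are multiplicative lognormal per (factor, gene)
(sdlog 0.10 / 0.05); mean library size 200,000 with ~2 % of reads in
spike-ins, chosen so cells satisfy the default QC thresholds by
construction (≥ 95 % pass, tested).  These are realistic
plate-based-protocol magnitudes chosen once and fixed.

*Bulk* (default mTEC-like + two DC-like populations, 3 replicates each,
2,000 genes, 200 planted TRA genes, NB α = 0.05, 2 M reads): the
promiscuous population expresses the TRA set with a per-gene lognormal
profile shared across its replicates; half the TRA genes carry a low leak
(0.5–3 relative units) shared by **all** populations — as peripheral
tissues express some TRAs — and the other half are exactly silent outside
the promiscuous program.  The leak is what gives DC-like replicates
correlated TRA-gene profiles (without it, their correlation over TRA genes
is pure counting noise and clade structure is undefined); the silent subset
is the panel for absent-in-DC homolog-style checks.

What the generators do **not** emulate: UMI chemistry, gene length effects,
ambient RNA, doublets, zero inflation beyond NB sampling, correlated gene
programs outside the planted ones, and real ortholog structure.  Passing
tests therefore demonstrate that the implementations recover the targets
they were built to recover under NB noise with batch structure — not
performance on arbitrary real data.

## Problem sizes and determinism

The test suite and acceptance script run everything at desk scale: atlases
up to 10,000 × 107, single-cell matrices up to 2,000 × 200, bulk designs of
9 samples, 10,000-draw downsampling checks, and 2,000–5,000-gene DE
simulations; these sizes make every stage's recovery target measurable in
seconds while keeping estimator noise well below the asserted margins.  All
randomness flows through explicit seeds (generator specs, t-SNE,
downsampling); reruns with identical configs produce byte-identical TSV
outputs, which the pipeline tests assert.

## Known limitations

* The χ² HVG test inherits the approximation error of a normal-theory
  variance test applied to NB data; calibration is verified empirically at
  the defaults, not guaranteed at extreme means or dispersions.
* The tree-variant dynamic cut can differ from the hybrid variant on real
  dendrograms; exact reproduction of cluster counts from other toolchains
  may require
  the hybrid's extra parameters.
* Deconvolution's ridge anchors trade a small bias toward library-size
  factors in cell-idiosyncratic directions for stability; under extreme
  composition effects confined to single cells the correction is partial.
* The design contrast is two-level; multi-level comparisons must be run
  as separate pairwise contrasts.
* Branch assignment is a descriptive DC2-sign report, not a probabilistic
  branching model.
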