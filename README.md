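# etac

Single-cell and bulk RNA-seq analysis pipeline for characterizing
extra-thymic AIRE-expressing cells (eTACs) — mature CCR7⁺ dendritic-cell
states found in secondary lymphoid tissue — and for asking whether, like
AIRE⁺ medullary thymic epithelial cells (mTECs), they promiscuously express
tissue-restricted antigens (TRAs).

The package is written for computational immunologists working with
SmartSeq2-scale single-cell counts and population-level bulk RNA-seq, and
covers two analysis arms end to end, starting from count matrices:

**Single-cell arm** — quality control → normalization → highly variable
genes → clustering/embedding → diffusion pseudotime → differential
expression:

* cell filters: total reads < 100 k, genes detected < 1 000, or sparsity
  > 95 % remove a cell (strict comparisons); genes with > 95 % zero counts
  are dropped;
* cell size factors by **pool deconvolution**: cells are ordered on a ring
  by library size, pools of consecutive cells are compared with the average
  pseudo-cell by median count ratio, and the linear system
  Σ_{j∈pool} f_j = θ_pool is solved by least squares; expression is
  log₂(count/factor + 1);
* **HVG detection** by fitting the squared coefficient of variation against
  the mean, CV² (μ) = a₁/μ + α₀ (Gamma GLM, identity link, preferring
  ERCC-like spike-ins), and testing each gene's excess with
  (n−1)·CV²_g / CV²(μ_g) ~ χ²(n−1), calling p ≤ 0.01;
* clustering on 1 − Spearman ρ with average linkage and a **dynamic tree
  cut** (minimum module size 30); 2-D embedding by seeded t-SNE
  (perplexity 50);
* **diffusion-map pseudotime** on cosine-normalized HVG expression
  (symmetric kNN graph, k = 21, local-bandwidth Gaussian kernel, anisotropic
  α = 1 normalization); the first diffusion component is pseudotime and
  exact 1-D k-means partitions it into 4 meta-stable states;
* per-gene DE by blocked linear models (donor, plate column) with
  empirical-Bayes variance moderation and a **moderated t-test**
  (s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), t on d_g + d₀ df), BH FDR 1 %.

**TRA arm** — the tissue-specificity index over a tissue atlas
(107 groups in the emulated design), with x̂ᵢ = xᵢ / maxⱼ xⱼ:

    τ = Σ_{i=1..N} (1 − x̂ᵢ) / (N − 1)

τ ≥ 0.8 ⇒ TRA, τ ≤ 0.4 ⇒ constitutive, otherwise miscellaneous.  Bulk
samples are thinned to a common depth (multivariate hypergeometric,
emulating read subsampling to ~20 M), normalized by median-of-ratios
factors, and compared by TRA proportions among expressed genes,
τ-distribution shifts, PCA over expressed TRA genes, Pearson-correlation
clades and a homolog expression panel.

A `synthetic_data` layer (`make_tissue_atlas`, `make_sc_experiment`,
`make_bulk_populations`) generates every input class with known ground
truth — planted TRA/constitutive/intermediate atlas genes, a latent
maturation trajectory with monotone and transient (AIRE-like) marker
programs, donor/plate batch structure and NB noise — so each stage has a
recoverable target without any downloads.

## Worked example

```python
import numpy as np
import etac

atlas, truth = etac.make_tissue_atlas(etac.AtlasSpec(n_genes=2000, seed=4))
tra = truth.index[truth["true_category"] == "TRA"].tolist()
bulk, bt = etac.make_bulk_populations(
    etac.BulkSimSpec(seed=4), gene_ids=list(atlas.gene_ids), tra_gene_ids=tra)

ds = etac.downsample_counts(bulk, 1_000_000, seed=1)
normed = etac.normalize_bulk_log2(ds, etac.median_ratio_size_factors(ds))
cls = etac.classify_genes(atlas)
props = etac.tra_proportions(normed, cls, bt["population"])
print(props[["TRA", "constitutive", "miscellaneous"]].round(3))
print("tau of (10, 5, 0, 0):", round(etac.tau_index(np.array([10.0, 5, 0, 0])), 4))
```

prints

```
        TRA  constitutive  miscellaneous
mTEC  0.100         0.602          0.298
eTAC  0.053         0.634          0.313
cDC   0.053         0.634          0.313
tau of (10, 5, 0, 0): 0.8333
```

The mTEC-like population (promiscuous TRA program on) shows the highest
proportion of expressed genes classified as TRA, while the two DC-like
populations sit at the low shared background — the planted contrast the
generator encodes.  The last line is the τ-index of a four-tissue profile
(10, 5, 0, 0): after max-normalization the per-tissue deficits are
(0, 0.5, 1, 1), so τ = 2.5/3 ≈ 0.8333 and the gene is classified TRA.

A console script exposes each stage (`etac simulate|qc-norm|hvg|cluster|
pseudotime|de|downsample|tau|tra-report|run-sc|run-tra`); `run-sc` and
`run-tra` orchestrate whole arms from a YAML config and stamp every output
directory with the config hash and seeds.

## Layout

```
src/etac/
  io.py          count matrices, tissue atlas, gene lists (TSV/MTX)
  qc.py          cell/gene filters, deconvolution size factors, log2 norm
  hvg.py         CV²-trend fit and χ² excess-variability test
  cluster.py     Spearman dissimilarity, UPGMA, dynamic tree cut, t-SNE
  pseudotime.py  diffusion map, exact 1-D k-means states, orientation
  de.py          blocked models, EB moderation, moderated t, BH, bulk norm
  tra.py         τ index, TRA classification, population-level reports
  simulate.py    synthetic atlas / single-cell / bulk generators with truth
  pipeline.py    arm orchestration, config, provenance stamping
  cli.py         `etac` console script
```

See `docs/methods.md` for the statistical details, default parameters and
known limitations.
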