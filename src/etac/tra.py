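"""Tissue-specificity (tau) scoring, TRA classification and enrichment views.

The tau index summarizes how narrowly a gene is expressed across N tissue
groups (107 in the emulated atlas design).  With per-tissue expression x_i
max-normalized to x^_i = x_i / max_j x_j,

    tau = sum_{i=1..N} (1 - x^_i) / (N - 1),

so tau = 0 for a perfectly uniform profile and tau = 1 for single-tissue
expression.  Genes with tau >= 0.8 are tissue-restricted antigens (TRA),
tau <= 0.4 constitutive, the rest miscellaneous; all-zero profiles are
unclassified.  The reporting layer reproduces the population-level TRA
comparisons: category proportions over expressed genes, tau-distribution
shifts, PCA restricted to expressed TRA genes, Pearson-correlation clades,
and the homolog expression panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from .io import EtacError, GeneSet, TissueAtlas
from .qc import NormalizedMatrix

logger = logging.getLogger("etac")

CATEGORIES = ("TRA", "constitutive", "miscellaneous")


@dataclass
class TauClassification:
    """Per-gene tau with category (NaN tau = all-zero profile, unclassified)."""

    gene_ids: list[str]
    tau: np.ndarray
    category: np.ndarray          # object array over CATEGORIES + "unclassified"
    tau_tra: float = 0.8
    tau_const: float = 0.4
    n_groups: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.tau, "category": self.category},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )

    def genes_in(self, category: str) -> list[str]:
        return [g for g, c in zip(self.gene_ids, self.category) if c == category]


def tau_index(profile: np.ndarray, log_transform: bool = False) -> float:
    """Tissue-specificity index of one gene's expression profile.

    ``log_transform`` applies log2(x + 1) before max-normalization (the
    convention of the original tau definition; linear scale is the default
    here).  All-zero profiles have no defined tau and return NaN.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a vector over >= 2 tissue groups")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("profile must be finite and non-negative")
    if log_transform:
        x = np.log2(x + 1.0)
    mx = x.max()
    if mx == 0:
        return float("nan")
    xhat = x / mx
    return float(np.sum(1.0 - xhat) / (x.size - 1))


def classify_genes(
    atlas: TissueAtlas,
    tau_tra: float = 0.8,
    tau_const: float = 0.4,
    log_transform: bool = False,
) -> TauClassification:
    """tau per gene over the atlas, categorized with inclusive boundaries
    (tau >= tau_tra -> TRA; tau <= tau_const -> constitutive)."""
    expr = atlas.expression
    mx = expr.max(axis=1)
    x = np.log2(expr + 1.0) if log_transform else expr
    mx_t = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = np.where(mx_t[:, None] > 0, x / np.maximum(mx_t, 1e-300)[:, None], 0.0)
        tau = np.sum(1.0 - xhat, axis=1) / (atlas.n_groups - 1)
    tau = np.where(mx > 0, tau, np.nan)
    category = np.where(
        np.isnan(tau), "unclassified",
        np.where(tau >= tau_tra, "TRA",
                 np.where(tau <= tau_const, "constitutive", "miscellaneous")),
    ).astype(object)
    n_excluded = int(np.isnan(tau).sum())
    if n_excluded:
        logger.info("tau: %d all-zero genes left unclassified", n_excluded)
    return TauClassification(
        gene_ids=list(atlas.gene_ids), tau=tau, category=category,
        tau_tra=tau_tra, tau_const=tau_const, n_groups=atlas.n_groups,
    )


# ---------------------------------------------------------------------------
# Population-level reporting
# ---------------------------------------------------------------------------

def _population_means(normed: NormalizedMatrix, populations: pd.Series) -> pd.DataFrame:
    """Per-population mean of linear-scale normalized counts (genes x pops)."""
    linear = 2.0 ** normed.values - normed.offset
    pops = populations.loc[list(normed.unit_ids)].astype(str)
    out = {}
    for pop in pd.unique(pops):
        out[pop] = linear[:, (pops == pop).to_numpy()].mean(axis=1)
    return pd.DataFrame(out, index=normed.gene_ids)


def expressed_genes(
    normed: NormalizedMatrix,
    populations: pd.Series,
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """Boolean genes x populations table of the "expressed" rule.

    Default rule: a gene is expressed in a population when its mean
    size-factor-normalized count across the population's replicates is
    >= ``min_mean`` (applied after any common-depth downsampling upstream).
    """
    return _population_means(normed, populations) >= min_mean


def tra_proportions(
    normed: NormalizedMatrix,
    classification: TauClassification,
    populations: pd.Series,
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """Per-population proportions of expressed genes in each tau category.

    Proportions are over classified expressed genes (TRA + constitutive +
    miscellaneous sum to 1 per population); the unclassified expressed count
    is reported alongside.  A population with zero expressed genes is flagged
    with NaN proportions.
    """
    cls = classification.to_frame()
    shared = [g for g in normed.gene_ids if g in set(classification.gene_ids)]
    if not shared:
        raise EtacError("no overlap between expression matrix and classification")
    expressed = expressed_genes(normed, populations, min_mean).loc[shared]
    cats = cls.loc[shared, "category"]
    rows = {}
    for pop in expressed.columns:
        exp_genes = expressed.index[expressed[pop]]
        sub = cats.loc[exp_genes]
        classified = sub[sub != "unclassified"]
        if len(classified) == 0:
            warnings.warn(f"population {pop!r} has no classified expressed genes",
                          stacklevel=2)
            rows[pop] = {c: np.nan for c in CATEGORIES} | {
                "n_expressed": len(sub), "n_unclassified": len(sub)}
            continue
        counts = classified.value_counts()
        rows[pop] = {c: counts.get(c, 0) / len(classified) for c in CATEGORIES}
        rows[pop]["n_expressed"] = len(sub)
        rows[pop]["n_unclassified"] = int((sub == "unclassified").sum())
    return pd.DataFrame(rows).T


def tau_shift_summary(
    normed: NormalizedMatrix,
    classification: TauClassification,
    populations: pd.Series,
    min_mean: float = 1.0,
    quantiles: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population tau distribution over expressed genes + pairwise shifts.

    The pairwise statistic is a one-sided Mann-Whitney U (alternative: row
    population's tau greater than column's), reported descriptively.
    """
    cls = classification.to_frame()
    shared = [g for g in normed.gene_ids if g in set(classification.gene_ids)]
    expressed = expressed_genes(normed, populations, min_mean).loc[shared]
    tau = cls.loc[shared, "tau"]
    dists = {
        pop: tau.loc[expressed.index[expressed[pop]]].dropna()
        for pop in expressed.columns
    }
    summary = pd.DataFrame({
        pop: {f"q{int(q * 100)}": vals.quantile(q) for q in quantiles}
        | {"mean": vals.mean(), "n": len(vals)}
        for pop, vals in dists.items()
    }).T
    pops = list(dists)
    shifts = pd.DataFrame(index=pops, columns=pops, dtype=float)
    for a in pops:
        for b in pops:
            if a == b or len(dists[a]) == 0 or len(dists[b]) == 0:
                continue
            if dists[a].equals(dists[b]):
                shifts.loc[a, b] = 1.0  # identical sets: no shift
                continue
            shifts.loc[a, b] = scipy.stats.mannwhitneyu(
                dists[a], dists[b], alternative="greater"
            ).pvalue
    return summary, shifts


def pca_on_tra(
    normed: NormalizedMatrix,
    classification: TauClassification,
    populations: pd.Series,
    min_mean: float = 1.0,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene-centered PCA of samples over expressed TRA genes.

    A gene enters when it is classified TRA and expressed in at least one
    population.  Returns per-sample scores and descending variance fractions.
    """
    tra_genes = set(classification.genes_in("TRA"))
    expressed = expressed_genes(normed, populations, min_mean)
    used = [g for g in normed.gene_ids
            if g in tra_genes and g in expressed.index and expressed.loc[g].any()]
    if len(used) < 2 or len(normed.unit_ids) < 2:
        raise EtacError("PCA needs >= 2 samples and >= 2 expressed TRA genes")
    sub = normed.subset_genes(used)
    centered = (sub.values - sub.values.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / max(len(normed.unit_ids) - 1, 1)
    frac = var / var.sum()
    k = n_components or min(len(s), 10)
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=pd.Index(normed.unit_ids, name="unit_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return scores, frac[:k]


def correlation_clades(
    normed: NormalizedMatrix,
    classification: TauClassification,
    n_clades: int = 2,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Sample-sample Pearson r over TRA genes + average-linkage clades.

    Clustering operates on dissimilarity 1 - r; ``n_clades`` controls the
    reported flat clade membership.  Zero-variance samples are excluded with
    a warning.
    """
    tra_genes = [g for g in normed.gene_ids if g in set(classification.genes_in("TRA"))]
    if len(tra_genes) < 2:
        raise EtacError("need >= 2 TRA genes for correlation clades")
    sub = normed.subset_genes(tra_genes)
    sd = sub.values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance sample(s)",
                      stacklevel=2)
    ids = [u for u, k in zip(sub.unit_ids, keep) if k]
    r = np.corrcoef(sub.values[:, keep].T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=ids, columns=ids)
    linkage = sch.linkage(ssd.squareform(1.0 - r, checks=False), method="average")
    clades = pd.Series(
        sch.fcluster(linkage, t=n_clades, criterion="maxclust"),
        index=ids, name="clade",
    )
    return corr, linkage, clades


def homolog_panel(
    normed: NormalizedMatrix,
    homologs: GeneSet,
    populations: pd.Series,
) -> tuple[pd.DataFrame, list[str]]:
    """Log2 expression of a homolog gene set per sample with population means.

    Genes absent from the matrix are reported as missing, not errors.
    Returns (table with per-sample values + per-population means, missing).
    """
    present = [g for g in homologs.gene_ids if g in normed.gene_ids]
    missing = [g for g in homologs.gene_ids if g not in normed.gene_ids]
    if missing:
        logger.info("homolog panel: %d/%d genes missing from the matrix",
                    len(missing), len(homologs))
    if not present:
        return pd.DataFrame(), missing
    sub = normed.subset_genes(present)
    table = sub.to_frame()
    pops = populations.loc[list(normed.unit_ids)].astype(str)
    for pop in pd.unique(pops):
        table[f"mean[{pop}]"] = sub.values[:, (pops == pop).to_numpy()].mean(axis=1)
    return table, missing
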