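"""Spearman dissimilarity, UPGMA dendrogram, dynamic tree cut, t-SNE contract.

Cells are compared by 1 - Spearman's rho over highly variable genes (midranks
for ties), clustered by average linkage, and partitioned with the adaptive
"tree" variant of dynamic tree cut: splits are scanned from the top of the
dendrogram downward and accepted only when both branches carry at least
``min_module_size`` leaves; undersized side branches are merged into the
nearest accepted cluster by average dissimilarity.  The 2-D embedding is a
seeded t-SNE (default perplexity 50).
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
from sklearn.manifold import TSNE

from .io import EtacError
from .qc import NormalizedMatrix

logger = logging.getLogger("etac")


@dataclass
class ClusterParams:
    min_module_size: int = 30
    linkage: str = "average"        # fixed by the method
    dissimilarity: str = "1-spearman"

    def __post_init__(self) -> None:
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")


@dataclass
class ClusterAssignment:
    """Cluster labels (1..K by decreasing size; 0 = unassigned) + dendrogram."""

    unit_ids: list[str]
    labels: np.ndarray
    dendrogram: np.ndarray          # scipy linkage matrix
    merged_small: list[tuple[int, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.labels}, index=pd.Index(self.unit_ids, name="unit_id")
        )


def spearman_dissimilarity(
    matrix: NormalizedMatrix | np.ndarray, unit_ids: list[str] | None = None
) -> pd.DataFrame:
    """units x units matrix of 1 - Spearman rho (midranks; entries in [0, 2]).

    Zero-variance units carry no rank information; their off-diagonal
    dissimilarity is set to the maximum (2.0) with a warning.
    """
    if isinstance(matrix, NormalizedMatrix):
        values, unit_ids = matrix.values, list(matrix.unit_ids)
    else:
        values = np.asarray(matrix, dtype=float)
        unit_ids = unit_ids or [str(i) for i in range(values.shape[1])]
    n_genes, n_units = values.shape
    if n_units < 2 or n_genes < 3:
        raise EtacError("need >= 2 units and >= 3 genes for rank correlation")
    ranks = scipy.stats.rankdata(values, axis=0)  # midranks per unit
    sd = ranks.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance unit(s); dissimilarity set to 2",
            stacklevel=2,
        )
        sd = np.where(degenerate, 1.0, sd)
    centered = (ranks - ranks.mean(axis=0)) / sd
    rho = centered.T @ centered / n_genes
    rho[degenerate, :] = -1.0
    rho[:, degenerate] = -1.0
    dis = 1.0 - rho
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(dis, index=unit_ids, columns=unit_ids)


def average_linkage_tree(dissimilarity: pd.DataFrame | np.ndarray) -> np.ndarray:
    """UPGMA merge tree (scipy linkage matrix) from a square dissimilarity."""
    dis = np.asarray(dissimilarity, dtype=float)
    condensed = ssd.squareform(dis, checks=False)
    return sch.linkage(condensed, method="average")


def _leaves(linkage: np.ndarray, node: int, n: int, cache: dict) -> list[int]:
    if node in cache:
        return cache[node]
    if node < n:
        out = [node]
    else:
        left, right = int(linkage[node - n, 0]), int(linkage[node - n, 1])
        out = _leaves(linkage, left, n, cache) + _leaves(linkage, right, n, cache)
    cache[node] = out
    return out


def dynamic_tree_cut(
    dendrogram: np.ndarray,
    params: ClusterParams | None = None,
    dissimilarity: pd.DataFrame | np.ndarray | None = None,
    unit_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Adaptive tree-variant dynamic cut of a UPGMA dendrogram.

    Recursing from the root (i.e. scanning candidate cut heights from high to
    low), a split is accepted only when both branches have at least
    ``min_module_size`` leaves and a strictly positive merge height
    (zero-height merges join indistinguishable units).  When one branch is
    undersized, the large branch is cut further and the undersized leaves are
    merged into the nearest accepted cluster by average dissimilarity (which
    must then be supplied).  With no admissible split the result is a single
    cluster.  Labels are canonical: 1..K by decreasing cluster size, ties by
    smallest leaf index.
    """
    params = params or ClusterParams()
    linkage = np.asarray(dendrogram)
    n = linkage.shape[0] + 1
    if unit_ids is None:
        if isinstance(dissimilarity, pd.DataFrame):
            unit_ids = list(dissimilarity.index)
        else:
            unit_ids = [str(i) for i in range(n)]
    cache: dict[int, list[int]] = {}
    m = params.min_module_size
    merged_small: list[tuple[int, int]] = []
    dis = None if dissimilarity is None else np.asarray(dissimilarity, dtype=float)

    def cut(node: int) -> tuple[list[list[int]], list[list[int]]]:
        """Returns (accepted clusters, orphan leaf groups awaiting merge)."""
        if node < n:
            return [[node]], []
        row = linkage[node - n]
        left, right = int(row[0]), int(row[1])
        height = float(row[2])
        nl = len(_leaves(linkage, left, n, cache))
        nr = len(_leaves(linkage, right, n, cache))
        if height <= 0 or (nl < m and nr < m):
            return [_leaves(linkage, node, n, cache)], []
        if nl >= m and nr >= m:
            cl, ol = cut(left)
            cr, orr = cut(right)
            return cl + cr, ol + orr
        big, small = (left, right) if nl >= m else (right, left)
        clusters, orphans = cut(big)
        return clusters, orphans + [_leaves(linkage, small, n, cache)]

    clusters, orphans = cut(2 * n - 2) if n > 1 else ([[0]], [])
    if len(clusters) == 1 and orphans:
        # nothing to split against: everything is one cluster
        clusters = [[i for c in clusters + orphans for i in c]]
        orphans = []
    for orphan in orphans:
        if dis is None:
            raise EtacError("dissimilarity required to merge undersized branches")
        avg = [dis[np.ix_(orphan, c)].mean() for c in clusters]
        target = int(np.argmin(avg))
        clusters[target] = clusters[target] + orphan
        merged_small.append((len(orphan), target))
        logger.info("merged undersized branch of %d units into a neighbor", len(orphan))

    clusters.sort(key=lambda c: (-len(c), min(c)))
    labels = np.zeros(n, dtype=int)
    for k, members in enumerate(clusters, start=1):
        labels[members] = k
    return ClusterAssignment(
        unit_ids=list(unit_ids), labels=labels, dendrogram=linkage,
        merged_small=merged_small,
    )


def tsne_embed(
    matrix: NormalizedMatrix | np.ndarray,
    perplexity: float = 50.0,
    seed: int = 42,
    unit_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Seeded 2-D t-SNE of units (rows of the result).

    The perplexity must satisfy perplexity < (n_units - 1) / 3.
    """
    if isinstance(matrix, NormalizedMatrix):
        data, unit_ids = matrix.values.T, list(matrix.unit_ids)
    else:
        data = np.asarray(matrix, dtype=float).T
        unit_ids = unit_ids or [str(i) for i in range(data.shape[0])]
    n_units = data.shape[0]
    if perplexity >= (n_units - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for {n_units} units "
            f"(needs perplexity < {(n_units - 1) / 3:.1f})"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
    )
    coords = tsne.fit_transform(data)
    return pd.DataFrame(
        coords, index=pd.Index(unit_ids, name="unit_id"), columns=["tsne1", "tsne2"]
    )
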