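"""Diffusion-map pseudotime with meta-stable states.

The maturation trajectory is inferred from a diffusion map built on the
cosine-normalized HVG expression matrix: a symmetric k-nearest-neighbor graph
(default k = 21) with a Gaussian kernel under per-cell local bandwidths
(distance to the ceil(k/2)-th neighbor), density-normalized (anisotropic
alpha = 1) and row-normalized to a random-walk transition matrix.  The first
three non-trivial eigenvector/eigenvalue pairs are the diffusion components;
DC1, oriented so that maturation-marker expression increases along it, serves
as pseudotime.  Meta-stable states are the exact optimal 1-D k-means
partition of DC1 into 4 contiguous groups (dynamic programming — no seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
import scipy.spatial.distance as ssd

from .io import EtacError, GeneSet
from .qc import NormalizedMatrix

logger = logging.getLogger("etac")


class DegenerateUnitError(EtacError):
    pass


@dataclass
class DiffusionParams:
    k_neighbors: int = 21
    n_components: int = 3
    kernel_scale: str = "local"  # "local" (per-cell bandwidth) or "global"

    def __post_init__(self) -> None:
        if self.k_neighbors < 2:
            raise ValueError("k_neighbors must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class TrajectoryResult:
    """Diffusion components, pseudotime, meta-stable states and branches.

    ``state_labels`` are 1..n_states (0 = unassigned / disconnected cells);
    ``pseudotime`` is the oriented first diffusion component.
    """

    unit_ids: list[str]
    diffusion_components: np.ndarray      # units x n_components
    eigenvalues: np.ndarray               # descending, trivial pair excluded
    pseudotime: np.ndarray | None = None
    state_labels: np.ndarray | None = None
    branch: np.ndarray | None = None
    state_means: pd.DataFrame | None = None   # per-state marker means
    assigned: np.ndarray | None = None        # False for disconnected cells

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            self.diffusion_components,
            index=pd.Index(self.unit_ids, name="unit_id"),
            columns=[f"DC{i + 1}" for i in range(self.diffusion_components.shape[1])],
        )
        if self.pseudotime is not None:
            out["pseudotime"] = self.pseudotime
        if self.state_labels is not None:
            out["state"] = self.state_labels
        if self.branch is not None:
            out["branch"] = self.branch
        return out


def cosine_normalize(matrix: NormalizedMatrix | np.ndarray) -> np.ndarray:
    """Scale each unit's expression vector to Euclidean norm 1.

    Returns a units x genes array.  All-zero units are degenerate (no
    direction) and raise :class:`DegenerateUnitError` naming the unit.
    """
    if isinstance(matrix, NormalizedMatrix):
        data, ids = matrix.values.T, matrix.unit_ids
    else:
        data = np.asarray(matrix, dtype=float).T
        ids = [str(i) for i in range(data.shape[0])]
    norms = np.linalg.norm(data, axis=1)
    if np.any(norms == 0):
        bad = [ids[i] for i in np.flatnonzero(norms == 0)[:5]]
        raise DegenerateUnitError(f"all-zero unit(s) cannot be cosine-normalized: {bad}")
    return data / norms[:, None]


def _knn_kernel(dist: np.ndarray, k: int, kernel_scale: str) -> scipy.sparse.csr_matrix:
    n = dist.shape[0]
    nn_idx = np.argsort(dist, axis=1)[:, 1 : k + 1]  # exclude self
    if kernel_scale == "local":
        half = int(np.ceil(k / 2))
        sigma = dist[np.arange(n), nn_idx[:, half - 1]]
        sigma = np.maximum(sigma, 1e-12)
    else:
        sigma = np.full(n, np.maximum(np.median(dist[np.arange(n), nn_idx[:, -1]]), 1e-12))
    rows = np.repeat(np.arange(n), k)
    cols = nn_idx.ravel()
    adj = scipy.sparse.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(float)  # symmetric union kNN graph
    adj.setdiag(1.0)
    coo = adj.tocoo()
    w = np.exp(-(dist[coo.row, coo.col] ** 2) / (sigma[coo.row] * sigma[coo.col]))
    return scipy.sparse.csr_matrix((w, (coo.row, coo.col)), shape=(n, n))


def diffusion_map(
    matrix: NormalizedMatrix | np.ndarray,
    params: DiffusionParams | None = None,
    unit_ids: list[str] | None = None,
) -> TrajectoryResult:
    """Diffusion components of cosine-normalized expression.

    Disconnected kNN-graph components trigger a warning: the decomposition is
    computed on the largest connected component and the remaining cells are
    left unassigned (components NaN, ``assigned`` False).
    Components are scaled by their eigenvalues; the trivial constant
    eigenvector is dropped and signs are fixed so each component's largest-
    magnitude entry is positive.
    """
    params = params or DiffusionParams()
    if isinstance(matrix, NormalizedMatrix) and unit_ids is None:
        unit_ids = list(matrix.unit_ids)
    unitized = cosine_normalize(matrix)
    n = unitized.shape[0]
    if unit_ids is None:
        unit_ids = [str(i) for i in range(n)]
    if n <= params.k_neighbors:
        raise EtacError(f"need more than k={params.k_neighbors} cells (have {n})")

    dist = ssd.squareform(ssd.pdist(unitized, metric="euclidean"))
    kernel = _knn_kernel(dist, params.k_neighbors, params.kernel_scale)

    n_comp_graph, comp_labels = scipy.sparse.csgraph.connected_components(
        kernel, directed=False
    )
    assigned = np.ones(n, dtype=bool)
    if n_comp_graph > 1:
        warnings.warn(
            f"kNN graph has {n_comp_graph} connected components; using the largest",
            stacklevel=2,
        )
        largest = np.argmax(np.bincount(comp_labels))
        assigned = comp_labels == largest
        kernel = kernel[np.ix_(assigned, assigned)].tocsr()

    W = kernel.toarray()
    q = W.sum(axis=1)
    W_tilde = W / np.outer(q, q)            # anisotropic alpha = 1 correction
    d = W_tilde.sum(axis=1)                 # row sums of corrected kernel
    # P = D^-1 W~ is similar to the symmetric S = D^-1/2 W~ D^-1/2
    d_isqrt = 1.0 / np.sqrt(d)
    S = W_tilde * np.outer(d_isqrt, d_isqrt)
    evals, evecs = scipy.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs * d_isqrt[:, None]          # right eigenvectors of P
    # drop the trivial (constant, eigenvalue ~1) pair
    lam = evals[1 : params.n_components + 1]
    comps = psi[:, 1 : params.n_components + 1] * lam[None, :]
    # deterministic sign: largest-|.| entry positive
    for j in range(comps.shape[1]):
        i_max = np.argmax(np.abs(comps[:, j]))
        if comps[i_max, j] < 0:
            comps[:, j] *= -1.0

    full = np.full((n, comps.shape[1]), np.nan)
    full[assigned] = comps
    return TrajectoryResult(
        unit_ids=list(unit_ids),
        diffusion_components=full,
        eigenvalues=lam,
        assigned=assigned,
    )


def kmeans_1d(values: np.ndarray, n_states: int) -> tuple[np.ndarray, float]:
    """Exact optimal 1-D k-means via dynamic programming.

    Finds the contiguous partition of the sorted values into ``n_states``
    groups minimizing within-cluster sum of squares; deterministic, no seed.
    Returns labels aligned to the input order (1..k ordered along the value
    axis) and the optimal WCSS.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n_states > n:
        raise ValueError("more states than points")
    if np.ptp(x) == 0:
        # degenerate: any partition has WCSS 0; canonical equal-size split
        order = np.argsort(x, kind="stable")
        labels = np.empty(n, dtype=int)
        for k, chunk in enumerate(np.array_split(order, n_states), start=1):
            labels[chunk] = k
        return labels, 0.0
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csum2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(i: int, j: int) -> float:  # cost of xs[i:j]
        s, s2, m = csum[j] - csum[i], csum2[j] - csum2[i], j - i
        return s2 - s * s / m

    INF = np.inf
    cost = np.full((n_states + 1, n + 1), INF)
    back = np.zeros((n_states + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_states + 1):
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + seg_cost(i, j)
                if c < best:
                    best, arg = c, i
            cost[k, j], back[k, j] = best, arg
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for k in range(n_states, 0, -1):
        i = back[k, j]
        labels_sorted[i:j] = k
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, float(cost[n_states, n])


def assign_metastable_states(
    pseudotime: np.ndarray, n_states: int = 4
) -> tuple[np.ndarray, pd.DataFrame]:
    """Meta-stable states from 1-D k-means on pseudotime (DC1).

    Unassigned cells (NaN pseudotime) receive label 0 and are excluded from
    state statistics.  Returns labels and per-state pseudotime means/sizes.
    """
    pt = np.asarray(pseudotime, dtype=float)
    ok = np.isfinite(pt)
    labels = np.zeros(pt.size, dtype=int)
    sub_labels, _ = kmeans_1d(pt[ok], n_states)
    labels[ok] = sub_labels
    means = pd.DataFrame(
        {
            "pseudotime_mean": [pt[labels == k].mean() for k in range(1, n_states + 1)],
            "n_cells": [(labels == k).sum() for k in range(1, n_states + 1)],
        },
        index=pd.Index(range(1, n_states + 1), name="state"),
    )
    return labels, means


def _branch_labels(comps: np.ndarray, assigned: np.ndarray) -> np.ndarray:
    """Descriptive branch call from the sign of DC2 relative to the centroids
    of the DC1 extremes (reported only; states use DC1 alone)."""
    branch = np.zeros(comps.shape[0], dtype=int)
    if comps.shape[1] < 2:
        branch[assigned] = 1
        return branch
    dc1 = comps[assigned, 0]
    dc2 = comps[assigned, 1]
    lo, hi = np.quantile(dc1, [0.1, 0.9])
    ref = np.concatenate([dc2[dc1 <= lo], dc2[dc1 >= hi]])
    center = ref.mean() if ref.size else 0.0
    branch[assigned] = np.where(dc2 >= center, 1, 2)
    return branch


def orient_and_annotate(
    result: TrajectoryResult,
    anchor_genes: GeneSet,
    normed: NormalizedMatrix,
    n_states: int = 4,
    report_genes: GeneSet | None = None,
) -> TrajectoryResult:
    """Orient DC1 so anchor (maturation-marker) expression rises with
    pseudotime, then assign meta-stable states and per-state mean expression.

    Missing anchor genes leave the orientation as computed, with a warning.
    ``report_genes`` (default: the anchors) selects the genes tabulated per
    state, as in the marker/AIRE-along-pseudotime panels.
    """
    comps = result.diffusion_components.copy()
    assigned = result.assigned if result.assigned is not None else np.ones(comps.shape[0], bool)
    present = [g for g in anchor_genes.gene_ids if g in normed.gene_ids]
    dc1 = comps[:, 0]
    if not present:
        warnings.warn("no anchor genes found; pseudotime orientation unchanged",
                      stacklevel=2)
    else:
        anchor = normed.subset_genes(present).values.mean(axis=0)
        ok = assigned & np.isfinite(dc1)
        if np.corrcoef(dc1[ok], anchor[ok])[0, 1] < 0:
            comps[:, 0] = -dc1
    pseudotime = comps[:, 0]
    labels, _ = assign_metastable_states(pseudotime, n_states)
    report = report_genes or anchor_genes
    rows = {}
    for g in report.gene_ids:
        if g not in normed.gene_ids:
            continue
        expr = normed.subset_genes([g]).values[0]
        rows[g] = [expr[labels == k].mean() if (labels == k).any() else np.nan
                   for k in range(1, n_states + 1)]
    state_means = pd.DataFrame(
        rows, index=pd.Index(range(1, n_states + 1), name="state")
    ).T
    state_means.columns = [f"state_{k}" for k in range(1, n_states + 1)]
    return TrajectoryResult(
        unit_ids=result.unit_ids,
        diffusion_components=comps,
        eigenvalues=result.eigenvalues,
        pseudotime=pseudotime,
        state_labels=labels,
        branch=_branch_labels(comps, assigned),
        state_means=state_means,
        assigned=assigned,
    )
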