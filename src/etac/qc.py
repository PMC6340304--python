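"""Cell/gene quality filters, pool-deconvolution size factors, log2 normalization.

Cell filters use strict inequalities: a cell is removed iff its
total unique reads are < 100,000, OR it expresses < 1,000 genes, OR its
sparsity (fraction of zero-count genes) exceeds 95%.  The per-cell fraction of
expression attributable to ERCC-like spike-ins is reported but is not a
removal criterion.  Genes with > 95% zero counts across retained cells are
then dropped (spike-ins exempt).  Cell-specific size factors are estimated by
pool deconvolution: cells are placed on a ring ordered by library size, pools
of consecutive cells are compared with the average pseudo-cell by median
ratio, and the resulting overdetermined linear system is solved by least
squares.  Counts are divided by the factors and log2-transformed with a
pseudo-count of 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .io import CountMatrix, EtacError

logger = logging.getLogger("etac")


class InsufficientCellsError(EtacError):
    pass


class AlignmentError(EtacError):
    pass


@dataclass
class QCThresholds:
    """Cell and gene quality thresholds (all comparisons strict)."""

    min_total_reads: int = 100_000
    min_genes_detected: int = 1_000
    max_sparsity: float = 0.95
    max_gene_zero_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.max_sparsity <= 1 and 0 <= self.max_gene_zero_fraction <= 1):
            raise ValueError("sparsity thresholds must lie in [0, 1]")
        if self.min_total_reads < 0 or self.min_genes_detected < 0:
            raise ValueError("integer thresholds must be >= 0")


@dataclass
class SizeFactors:
    """Per-cell positive scale factors, rescaled to geometric mean 1."""

    unit_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("size factors must be positive")

    def to_series(self) -> pd.Series:
        return pd.Series(self.factors, index=self.unit_ids, name="size_factor")


@dataclass
class NormalizedMatrix:
    """log2-scale normalized expression: log2(count / factor + offset)."""

    gene_ids: list[str]
    unit_ids: list[str]
    values: np.ndarray
    offset: float = 1.0
    gene_meta: pd.DataFrame = None  # type: ignore[assignment]
    unit_meta: pd.DataFrame = None  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)

    def subset_genes(self, gene_ids) -> "NormalizedMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(list(gene_ids))
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return NormalizedMatrix(
            gene_ids=list(gene_ids), unit_ids=self.unit_ids,
            values=self.values[idx], offset=self.offset,
            gene_meta=None if self.gene_meta is None else self.gene_meta.iloc[idx],
            unit_meta=self.unit_meta,
        )


# ---------------------------------------------------------------------------
# Cell QC
# ---------------------------------------------------------------------------

def compute_cell_qc(counts: CountMatrix) -> pd.DataFrame:
    """Per-cell totals, genes detected, sparsity, and ERCC fraction.

    Sparsity is the fraction of genes (all genes, spike-ins included) with a
    zero count in the cell.  ``ercc_fraction`` is the share of the cell's
    reads attributable to flagged technical genes (0 when none are flagged).
    """
    mat = counts.counts
    total = mat.sum(axis=0)
    detected = (mat > 0).sum(axis=0)
    sparsity = 1.0 - detected / mat.shape[0]
    tech = counts.is_technical
    with np.errstate(invalid="ignore", divide="ignore"):
        ercc = np.where(total > 0, mat[tech].sum(axis=0) / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "total_reads": total,
            "genes_detected": detected,
            "sparsity": sparsity,
            "ercc_fraction": ercc,
        },
        index=pd.Index(counts.unit_ids, name="unit_id"),
    )


def filter_cells(
    counts: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove poor-quality cells; return the retained matrix and a report.

    A cell fails iff total_reads < min_total_reads OR genes_detected <
    min_genes_detected OR sparsity > max_sparsity (all strict).  The report
    has one row per cell with the QC metrics, each rule's verdict and the
    overall ``removed`` flag.
    """
    thresholds = thresholds or QCThresholds()
    qc = compute_cell_qc(counts)
    low_reads = qc["total_reads"] < thresholds.min_total_reads
    few_genes = qc["genes_detected"] < thresholds.min_genes_detected
    too_sparse = qc["sparsity"] > thresholds.max_sparsity
    removed = low_reads | few_genes | too_sparse
    report = qc.assign(
        fail_total_reads=low_reads,
        fail_genes_detected=few_genes,
        fail_sparsity=too_sparse,
        removed=removed,
    )
    if removed.all():
        warnings.warn("all cells removed by QC filters", stacklevel=2)
    retained = counts.subset(unit_mask=~removed.to_numpy())
    logger.info("cell QC: retained %d/%d cells", retained.shape[1], counts.shape[1])
    return retained, report


def filter_genes(
    counts: CountMatrix, max_gene_zero_fraction: float = 0.95
) -> CountMatrix:
    """Drop genes whose zero-count fraction across cells strictly exceeds the
    threshold.  ERCC-like technical genes are retained regardless (they feed
    the HVG trend fit, not the biology)."""
    n_units = counts.shape[1]
    zero_frac = (counts.counts == 0).sum(axis=1) / max(n_units, 1)
    drop = (zero_frac > max_gene_zero_fraction) & ~counts.is_technical
    kept = counts.subset(gene_mask=~drop)
    logger.info("gene filter: retained %d/%d genes", kept.shape[0], counts.shape[0])
    return kept


# ---------------------------------------------------------------------------
# Deconvolution size factors
# ---------------------------------------------------------------------------

def _default_pool_sizes(n_cells: int) -> list[int]:
    sizes = [s for s in (21, 41, 61, 81, 101) if s <= n_cells]
    if not sizes:
        sizes = [min(21, n_cells)]
    return sizes


def deconvolution_size_factors(
    counts: CountMatrix,
    pool_sizes: list[int] | None = None,
    exclude_technical: bool = True,
) -> SizeFactors:
    """Estimate cell size factors by pooling and deconvolution.

    Cells are arranged on a ring ordered by library size.  For every pool of
    consecutive cells (all ring rotations, all pool sizes), the pooled count
    vector is compared against the average pseudo-cell by the median ratio
    over genes with positive pseudo-cell expression.  Each pool yields one
    linear equation (the sum of its member factors equals the pool's median
    ratio, up to a global scale), and the overdetermined system is solved by
    least squares; per-cell library-size ridge anchors regularize the weakly
    determined cell-idiosyncratic components and keep the system full rank.
    Factors are rescaled to geometric mean 1.  Non-positive
    solutions trigger a non-negative refit, with library-size fallback for
    cells still degenerate.
    """
    mat = counts.counts.astype(float)
    if exclude_technical:
        mat = mat[~counts.is_technical]
    n_genes, n_cells = mat.shape
    pool_sizes = sorted(set(pool_sizes or _default_pool_sizes(n_cells)))
    if n_cells < min(pool_sizes):
        raise InsufficientCellsError(
            f"{n_cells} cells < smallest pool size {min(pool_sizes)}"
        )
    pool_sizes = [s for s in pool_sizes if s <= n_cells]

    lib = mat.sum(axis=0)
    order = np.argsort(lib, kind="stable")  # ring ordered by library size
    ref = mat.mean(axis=1)  # average pseudo-cell
    pos = ref > 0
    if not pos.any():
        raise EtacError("reference pseudo-cell has no positive genes")

    rows, rhs = [], []
    ring = mat[:, order]
    # cumulative sums along the ring (wrapped) give O(1) pool count vectors
    wrapped = np.concatenate([ring, ring], axis=1)
    csum = np.concatenate(
        [np.zeros((n_genes, 1)), np.cumsum(wrapped, axis=1)], axis=1
    )
    for s in pool_sizes:
        for start in range(n_cells):
            pooled = csum[:, start + s] - csum[:, start]
            theta = np.median(pooled[pos] / ref[pos])
            row = np.zeros(n_cells)
            members = [(start + j) % n_cells for j in range(s)]
            row[[order[m] for m in members]] = 1.0
            rows.append(row)
            rhs.append(theta)
    # Per-cell ridge anchors toward library-size factors.  Window-sum rows
    # determine high-frequency (cell-idiosyncratic) components weakly, so the
    # anchors regularize those toward library-size scaling while the pool
    # equations dominate the aggregate signal (weight 10 vs ~305 pool
    # memberships per cell); they also fix the rank deficiency and the scale.
    w = 10.0
    lib_factor = lib / lib.mean() if lib.mean() > 0 else np.ones(n_cells)
    anchors = w * np.eye(n_cells)
    A = np.vstack([np.array(rows), anchors])
    b = np.concatenate([np.array(rhs), w * lib_factor])

    factors, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(factors <= 0):
        logger.warning("deconvolution: non-positive factors, refitting with NNLS")
        factors, _ = scipy.optimize.nnls(A, b)
        bad = factors <= 0
        if bad.any():
            logger.warning(
                "deconvolution: %d cells fall back to library-size factors",
                int(bad.sum()),
            )
            factors[bad] = lib_factor[bad]
            factors[factors <= 0] = 1.0
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return SizeFactors(unit_ids=list(counts.unit_ids), factors=factors)


def library_size_factors(counts: CountMatrix, exclude_technical: bool = True) -> SizeFactors:
    """Naive per-cell factors proportional to total counts (baseline method)."""
    mat = counts.counts.astype(float)
    if exclude_technical:
        mat = mat[~counts.is_technical]
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        raise EtacError("cells with zero library size cannot be normalized")
    factors = lib / np.exp(np.mean(np.log(lib)))
    return SizeFactors(unit_ids=list(counts.unit_ids), factors=factors)


def normalize_log2(
    counts: CountMatrix, size_factors: SizeFactors, offset: float = 1.0
) -> NormalizedMatrix:
    """value(g, c) = log2(count(g, c) / factor(c) + offset)."""
    if list(size_factors.unit_ids) != list(counts.unit_ids):
        raise AlignmentError("size-factor unit ids do not match count matrix")
    values = np.log2(counts.counts / size_factors.factors[None, :] + offset)
    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids),
        unit_ids=list(counts.unit_ids),
        values=values,
        offset=offset,
        gene_meta=counts.gene_meta,
        unit_meta=counts.unit_meta,
    )
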