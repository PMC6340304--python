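"""Data model and readers/writers for count matrices, tissue atlases and gene lists.

All on-disk matrices are gene-major (genes as rows, cells/samples as columns).
TSV files carry a header row of unit ids and gene ids in the first column.
MatrixMarket (MTX) files are coordinate-integer with 1-based indices and are
accompanied by ``genes.tsv`` / ``units.tsv`` sidecar files (one id per line).
Unit/gene metadata travel in separate TSV tables keyed by id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class EtacError(Exception):
    """Base class for pipeline errors."""


class MalformedInputError(EtacError):
    """A file or matrix violates the input contract (e.g. negative counts)."""


class DuplicateIdError(EtacError):
    """Gene or unit identifiers contain duplicates."""


class UnmappedSampleError(EtacError):
    """An atlas sample column has no tissue-group assignment."""


class EmptyGroupError(EtacError):
    """A tissue group in the map matches no sample column."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise DuplicateIdError(f"duplicate {kind} ids: {dups[:5]}")


@dataclass
class CountMatrix:
    """Genes x units matrix of non-negative integer counts with annotations.

    ``unit_meta`` / ``gene_meta`` are indexed by unit/gene id.  ``gene_meta``
    may carry an ``is_technical`` boolean column flagging ERCC-like spike-in
    controls; ``unit_meta`` may carry ``donor``, ``plate_col``, ``population``
    and ``group`` columns used by downstream stages (required only at use
    time, never at load time).
    """

    gene_ids: list[str]
    unit_ids: list[str]
    counts: np.ndarray
    unit_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.unit_ids = [str(u) for u in self.unit_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.unit_ids, "unit")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise MalformedInputError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        if counts.size and np.issubdtype(counts.dtype, np.floating):
            if not np.all(np.isfinite(counts)):
                raise MalformedInputError("counts contain non-finite values")
            if np.any(counts != np.round(counts)):
                g, u = np.argwhere(counts != np.round(counts))[0]
                raise MalformedInputError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"unit {self.unit_ids[u]!r}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            g, u = np.argwhere(counts < 0)[0]
            raise MalformedInputError(
                f"negative count at gene {self.gene_ids[g]!r}, unit {self.unit_ids[u]!r}"
            )
        self.counts = counts.astype(np.int64, copy=False)
        if self.unit_meta is None:
            self.unit_meta = pd.DataFrame(index=pd.Index(self.unit_ids, name="unit_id"))
        else:
            self.unit_meta = self.unit_meta.loc[list(self.unit_ids)]
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        else:
            self.gene_meta = self.gene_meta.loc[list(self.gene_ids)]
        if len(self.unit_meta) != len(self.unit_ids):
            raise MalformedInputError("unit_meta rows do not match unit count")
        if len(self.gene_meta) != len(self.gene_ids):
            raise MalformedInputError("gene_meta rows do not match gene count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def is_technical(self) -> np.ndarray:
        """Boolean mask of ERCC-like technical genes (all False if unflagged)."""
        if "is_technical" in self.gene_meta.columns:
            return self.gene_meta["is_technical"].to_numpy(dtype=bool)
        return np.zeros(len(self.gene_ids), dtype=bool)

    def subset(self, gene_mask=None, unit_mask=None) -> "CountMatrix":
        gm = np.ones(len(self.gene_ids), bool) if gene_mask is None else np.asarray(gene_mask)
        um = np.ones(len(self.unit_ids), bool) if unit_mask is None else np.asarray(unit_mask)
        return CountMatrix(
            gene_ids=[g for g, k in zip(self.gene_ids, gm) if k],
            unit_ids=[u for u, k in zip(self.unit_ids, um) if k],
            counts=self.counts[np.ix_(gm, um)],
            unit_meta=self.unit_meta.loc[um],
            gene_meta=self.gene_meta.loc[gm],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.unit_ids)


@dataclass
class TissueAtlas:
    """Genes x tissue-group expression table used to compute the tau index.

    Expression values are non-negative reals on the quantification scale of
    the source atlas (e.g. RLE-normalized CAGE tag counts aggregated into N
    tissue groups; the emulated design uses N=107).
    """

    gene_ids: list[str]
    tissue_group_ids: list[str]
    expression: np.ndarray
    group_map: pd.DataFrame | None = None  # raw sample -> group assignments

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.tissue_group_ids = [str(t) for t in self.tissue_group_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.tissue_group_ids, "tissue group")
        if len(self.tissue_group_ids) < 2:
            raise MalformedInputError("a tissue atlas needs at least 2 groups")
        expr = np.asarray(self.expression, dtype=float)
        if expr.shape != (len(self.gene_ids), len(self.tissue_group_ids)):
            raise MalformedInputError("atlas expression shape mismatch")
        if expr.size and (not np.all(np.isfinite(expr)) or expr.min() < 0):
            raise MalformedInputError("atlas expression must be finite and >= 0")
        self.expression = expr

    @property
    def n_groups(self) -> int:
        return len(self.tissue_group_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expression, index=self.gene_ids, columns=self.tissue_group_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "TissueAtlas":
        frame = self.to_frame().loc[list(gene_ids)]
        return TissueAtlas(list(frame.index), self.tissue_group_ids, frame.to_numpy(),
                           group_map=self.group_map)


@dataclass
class GeneSet:
    """A named list of gene identifiers (e.g. murine Aire-dependent TRA homologs)."""

    name: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.gene_ids, "gene")

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_meta(path: str | Path | None, ids: list[str], kind: str) -> pd.DataFrame | None:
    if path is None:
        return None
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    missing = [i for i in ids if i not in meta.index]
    if missing:
        raise MalformedInputError(f"{kind} metadata missing ids: {missing[:5]}")
    return meta.loc[ids]


def read_count_matrix(
    path: str | Path,
    format: str = "tsv",
    unit_meta_path: str | Path | None = None,
    gene_meta_path: str | Path | None = None,
) -> CountMatrix:
    """Read a genes x units count matrix from TSV or MatrixMarket.

    For ``format="mtx"`` the file must be accompanied by ``genes.tsv`` and
    ``units.tsv`` sidecars in the same directory.  Ordering of ids is
    preserved from the files.  Negative or fractional counts raise
    :class:`MalformedInputError` naming the offending row/column; duplicated
    ids raise :class:`DuplicateIdError`.
    """
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = [str(g) for g in frame.index]
        unit_ids = [str(u) for u in frame.columns]
        counts = frame.to_numpy()
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_ids = Path(path).parent.joinpath("genes.tsv").read_text().split()
        unit_ids = Path(path).parent.joinpath("units.tsv").read_text().split()
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'mtx')")
    return CountMatrix(
        gene_ids=gene_ids,
        unit_ids=unit_ids,
        counts=counts,
        unit_meta=_read_meta(unit_meta_path, unit_ids, "unit"),
        gene_meta=_read_meta(gene_meta_path, gene_ids, "gene"),
    )


def write_count_matrix(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix in TSV or MTX (+ id sidecars) form."""
    path = Path(path)
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        sparse = scipy.sparse.coo_matrix(cm.counts)
        scipy.io.mmwrite(str(path), sparse, field="integer")
        path.parent.joinpath("genes.tsv").write_text("\n".join(cm.gene_ids) + "\n")
        path.parent.joinpath("units.tsv").write_text("\n".join(cm.unit_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_unit_meta(cm: CountMatrix, path: str | Path) -> None:
    cm.unit_meta.to_csv(path, sep="\t", index_label="unit_id")


def read_tissue_atlas(
    path: str | Path,
    group_map_path: str | Path,
    statistic: str = "mean",
) -> TissueAtlas:
    """Read a raw-sample atlas table and aggregate samples into tissue groups.

    ``group_map_path`` is a two-column TSV (``sample``, ``group``) assigning
    every raw sample column of the atlas to exactly one tissue group.  Samples
    within a group are aggregated by ``statistic`` ("mean", the default, or
    "median").  Unmapped sample columns raise :class:`UnmappedSampleError`;
    groups matching no sample raise :class:`EmptyGroupError`.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    group_map = pd.read_csv(group_map_path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(group_map.columns):
        raise MalformedInputError("group map needs 'sample' and 'group' columns")
    return aggregate_atlas(raw, group_map, statistic=statistic)


def aggregate_atlas(raw: pd.DataFrame, group_map: pd.DataFrame,
                    statistic: str = "mean") -> TissueAtlas:
    """Aggregate raw atlas sample columns into tissue groups."""
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    assignment = dict(zip(group_map["sample"].astype(str), group_map["group"].astype(str)))
    unmapped = [c for c in raw.columns if c not in assignment]
    if unmapped:
        raise UnmappedSampleError(f"samples without a tissue group: {unmapped[:5]}")
    groups = pd.unique(group_map["group"].astype(str))
    cols = {}
    for grp in groups:
        members = [s for s, g in assignment.items() if g == grp and s in raw.columns]
        if not members:
            raise EmptyGroupError(f"tissue group {grp!r} matches no sample column")
        block = raw[members]
        cols[grp] = block.mean(axis=1) if statistic == "mean" else block.median(axis=1)
    agg = pd.DataFrame(cols)
    return TissueAtlas(list(agg.index), list(agg.columns), agg.to_numpy(),
                       group_map=group_map)


def write_tissue_atlas(atlas: TissueAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene list, one id per line; blank lines ignored."""
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return GeneSet(name=name or Path(path).stem, gene_ids=ids)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gene_set.gene_ids) + "\n")
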