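"""Orchestration of the two analysis arms with config and provenance stamping.

``run_single_cell_arm`` executes QC -> normalization -> HVG -> clustering/
embedding -> pseudotime -> differential expression on a single-cell count
matrix.  ``run_tra_arm`` executes tau classification -> downsampling ->
median-of-ratios normalization -> the TRA report (proportions, tau shift,
PCA, correlation clades, homolog panel) and optionally moderated-t DE on a
bulk matrix.  Every run writes its configuration, a SHA-256 config hash and
all seeds into ``run_info.json`` in the output directory; stages are pure
functions of their on-disk inputs, so any stage rerun standalone reproduces
the in-pipeline result and identical configs yield byte-identical TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as _cluster
from . import de as _de
from . import hvg as _hvg
from . import pseudotime as _pt
from . import qc as _qc
from . import tra as _tra
from .io import (
    CountMatrix,
    EtacError,
    GeneSet,
    read_count_matrix,
    read_gene_set,
    read_tissue_atlas,
    TissueAtlas,
    write_count_matrix,
)

logger = logging.getLogger("etac")


def configure_logging(log_file: str | Path | None = None) -> None:
    """Structured stage logging to stderr and optionally a run log file."""
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class PipelineConfig:
    """All stage parameters for both arms; serialized into every output dir."""

    # inputs
    counts_path: str | None = None
    unit_meta_path: str | None = None
    gene_meta_path: str | None = None
    atlas_path: str | None = None
    atlas_group_map_path: str | None = None
    atlas_pre_aggregated: bool = False
    bulk_counts_path: str | None = None
    bulk_meta_path: str | None = None
    anchors_path: str | None = None
    homologs_path: str | None = None
    out_dir: str = "etac_out"
    # QC / normalization
    min_total_reads: int = 100_000
    min_genes_detected: int = 1_000
    max_sparsity: float = 0.95
    max_gene_zero_fraction: float = 0.95
    log2_offset: float = 1.0
    # HVG
    hvg_alpha: float = 0.01
    hvg_use_technical: bool = True
    # clustering / embedding
    min_module_size: int = 30
    perplexity: float = 50.0
    tsne_seed: int = 42
    run_tsne: bool = True
    # pseudotime
    diffusion_k: int = 21
    diffusion_components: int = 3
    n_states: int = 4
    # DE
    de_group: str | None = None
    de_blocks: list[str] = field(default_factory=lambda: ["donor", "plate_col"])
    fdr_threshold: float = 0.01
    # TRA arm
    tau_tra: float = 0.8
    tau_const: float = 0.4
    downsample_target: int = 20_000_000
    downsample_seed: int = 1
    expressed_min_mean: float = 1.0
    population_column: str = "population"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise EtacError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stamp(config: PipelineConfig, out: Path, arm: str, stages: list[str]) -> None:
    out.joinpath("run_info.json").write_text(
        json.dumps(
            {
                "arm": arm,
                "config_hash": config.hash(),
                "seeds": {"tsne": config.tsne_seed,
                          "downsample": config.downsample_seed},
                "stages": stages,
                "config": config.to_dict(),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


class StageFailure(EtacError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise EtacError(f"config is missing the {what} path")
    p = Path(path)
    if not p.exists():
        raise EtacError(f"{what} path does not exist: {p}")
    return p


def run_single_cell_arm(config: PipelineConfig) -> dict:
    """QC -> normalize -> HVG -> cluster/embed -> pseudotime -> DE.

    Returns a dict of in-memory artifacts; TSV/JSON files are written under
    ``config.out_dir``.  A stage failure aborts with the failing stage named;
    artifacts from completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_count_matrix(
        _require(config.counts_path, "single-cell counts"),
        format="tsv",
        unit_meta_path=config.unit_meta_path,
        gene_meta_path=config.gene_meta_path,
    )
    artifacts: dict = {}
    completed: list[str] = []

    def stage(name: str):
        def wrap(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - named-stage abort
                raise StageFailure(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            completed.append(name)
            return result
        return wrap

    def qc_stage():
        thresholds = _qc.QCThresholds(
            min_total_reads=config.min_total_reads,
            min_genes_detected=config.min_genes_detected,
            max_sparsity=config.max_sparsity,
            max_gene_zero_fraction=config.max_gene_zero_fraction,
        )
        retained, report = _qc.filter_cells(counts, thresholds)
        retained = _qc.filter_genes(retained, config.max_gene_zero_fraction)
        report.to_csv(out / "qc_report.tsv", sep="\t")
        factors = _qc.deconvolution_size_factors(retained)
        normed = _qc.normalize_log2(retained, factors, offset=config.log2_offset)
        normed.to_frame().to_csv(out / "normalized.tsv", sep="\t",
                                 index_label="gene_id")
        factors.to_series().to_csv(out / "size_factors.tsv", sep="\t")
        return retained, report, factors, normed

    retained, qc_report, factors, normed = stage("qc-norm")(qc_stage)
    artifacts |= {"qc_report": qc_report, "size_factors": factors, "normalized": normed}

    def hvg_stage():
        fit = _hvg.fit_cv2_trend(normed, use_technical=config.hvg_use_technical)
        called = _hvg.call_hvgs(fit, alpha=config.hvg_alpha)
        called.to_frame().to_csv(out / "hvg.tsv", sep="\t")
        return called

    hvg_fit = stage("hvg")(hvg_stage)
    artifacts["hvg"] = hvg_fit
    hvg_normed = normed.subset_genes(hvg_fit.hvg_gene_ids)

    def cluster_stage():
        dis = _cluster.spearman_dissimilarity(hvg_normed)
        tree = _cluster.average_linkage_tree(dis)
        assignment = _cluster.dynamic_tree_cut(
            tree, _cluster.ClusterParams(min_module_size=config.min_module_size),
            dissimilarity=dis,
        )
        assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t")
        embedding = None
        if config.run_tsne:
            embedding = _cluster.tsne_embed(
                hvg_normed, perplexity=config.perplexity, seed=config.tsne_seed
            )
            embedding.to_csv(out / "tsne.tsv", sep="\t")
        return assignment, embedding

    clusters, embedding = stage("cluster")(cluster_stage)
    artifacts |= {"clusters": clusters, "embedding": embedding}

    def pseudotime_stage():
        params = _pt.DiffusionParams(
            k_neighbors=config.diffusion_k, n_components=config.diffusion_components
        )
        result = _pt.diffusion_map(hvg_normed, params=params)
        anchors = (read_gene_set(config.anchors_path, "anchors")
                   if config.anchors_path else GeneSet("anchors", []))
        result = _pt.orient_and_annotate(result, anchors, normed,
                                         n_states=config.n_states)
        result.to_frame().to_csv(out / "trajectory.tsv", sep="\t")
        if result.state_means is not None and not result.state_means.empty:
            result.state_means.to_csv(out / "state_means.tsv", sep="\t",
                                      index_label="gene_id")
        return result

    trajectory = stage("pseudotime")(pseudotime_stage)
    artifacts["trajectory"] = trajectory

    def de_stage():
        meta = normed.unit_meta.copy()
        if config.de_group is None:
            # default contrast: the two largest clusters
            meta = meta.assign(cluster=clusters.labels)
            top2 = meta["cluster"].value_counts().index[:2]
            keep = meta["cluster"].isin(top2).to_numpy()
            if keep.sum() < 4 or len(top2) < 2:
                logger.warning("DE skipped: fewer than two usable clusters")
                return None
            sub = _subset_normed(normed, keep)
            sub_meta = meta.loc[keep]
            design = _de.DesignSpec(group="cluster", blocks=_usable_blocks(
                sub_meta, config.de_blocks))
            result = _de.differential_expression(
                sub, design, meta=sub_meta, fdr_threshold=config.fdr_threshold)
        else:
            design = _de.DesignSpec(group=config.de_group, blocks=_usable_blocks(
                meta, config.de_blocks))
            result = _de.differential_expression(
                normed, design, meta=meta, fdr_threshold=config.fdr_threshold)
        result.to_frame().to_csv(out / "de.tsv", sep="\t")
        return result

    artifacts["de"] = stage("de")(de_stage)
    _stamp(config, out, "single_cell", completed)
    return artifacts


def _subset_normed(normed: _qc.NormalizedMatrix, keep) -> _qc.NormalizedMatrix:
    import numpy as np

    keep = np.asarray(keep, dtype=bool)
    return _qc.NormalizedMatrix(
        gene_ids=list(normed.gene_ids),
        unit_ids=[u for u, k in zip(normed.unit_ids, keep) if k],
        values=normed.values[:, keep],
        offset=normed.offset,
        gene_meta=normed.gene_meta,
        unit_meta=None if normed.unit_meta is None else normed.unit_meta.loc[keep],
    )


def _usable_blocks(meta: pd.DataFrame, blocks: list[str]) -> list[str]:
    return [b for b in blocks if b in meta.columns and meta[b].nunique() > 1]


def run_tra_arm(config: PipelineConfig) -> dict:
    """tau -> downsample -> normalize -> TRA report (+ optional DE).

    Aborts when the atlas/bulk gene-universe overlap is below 50%, logging
    the overlap statistics either way.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    artifacts: dict = {}

    atlas_path = _require(config.atlas_path, "tissue atlas")
    if config.atlas_pre_aggregated:
        frame = pd.read_csv(atlas_path, sep="\t", index_col=0)
        atlas = TissueAtlas(list(frame.index.astype(str)),
                            list(frame.columns.astype(str)), frame.to_numpy())
    else:
        atlas = read_tissue_atlas(
            atlas_path, _require(config.atlas_group_map_path, "atlas group map")
        )
    bulk = read_count_matrix(
        _require(config.bulk_counts_path, "bulk counts"), format="tsv",
        unit_meta_path=config.bulk_meta_path,
    )
    overlap = len(set(atlas.gene_ids) & set(bulk.gene_ids))
    frac = overlap / max(len(bulk.gene_ids), 1)
    logger.info("atlas/bulk gene overlap: %d genes (%.1f%% of bulk)",
                overlap, 100 * frac)
    if frac < 0.5:
        raise EtacError(
            f"gene-universe overlap {100 * frac:.1f}% < 50%; aborting "
            f"({overlap}/{len(bulk.gene_ids)} bulk genes in the atlas)"
        )

    try:
        classification = _tra.classify_genes(
            atlas, tau_tra=config.tau_tra, tau_const=config.tau_const)
        classification.to_frame().to_csv(out / "tau.tsv", sep="\t")
        completed.append("tau")

        downsampled = _de.downsample_counts(
            bulk, config.downsample_target, seed=config.downsample_seed)
        write_count_matrix(downsampled, out / "downsampled.tsv")
        completed.append("downsample")

        norm = _de.median_ratio_size_factors(downsampled)
        normed = _de.normalize_bulk_log2(downsampled, norm)
        normed.to_frame().to_csv(out / "bulk_normalized.tsv", sep="\t",
                                 index_label="gene_id")
        completed.append("normalize")

        populations = bulk.unit_meta[config.population_column]
        proportions = _tra.tra_proportions(
            normed, classification, populations, min_mean=config.expressed_min_mean)
        proportions.to_csv(out / "tra_proportions.tsv", sep="\t",
                           index_label="population")
        tau_summary, tau_shifts = _tra.tau_shift_summary(
            normed, classification, populations, min_mean=config.expressed_min_mean)
        tau_summary.to_csv(out / "tau_summary.tsv", sep="\t",
                           index_label="population")
        tau_shifts.to_csv(out / "tau_shifts.tsv", sep="\t", index_label="population")
        scores, var_frac = _tra.pca_on_tra(
            normed, classification, populations, min_mean=config.expressed_min_mean)
        scores.assign().to_csv(out / "tra_pca.tsv", sep="\t")
        corr, linkage, clades = _tra.correlation_clades(normed, classification)
        corr.to_csv(out / "tra_correlation.tsv", sep="\t", index_label="unit_id")
        clades.to_csv(out / "tra_clades.tsv", sep="\t")
        panel = None
        missing: list[str] = []
        if config.homologs_path:
            homologs = read_gene_set(config.homologs_path, "homologs")
            panel, missing = _tra.homolog_panel(normed, homologs, populations)
            panel.to_csv(out / "homolog_panel.tsv", sep="\t", index_label="gene_id")
        summary = {
            "pca_variance_fractions": [float(v) for v in var_frac],
            "homologs_missing": missing,
            "n_tra_genes": len(classification.genes_in("TRA")),
        }
        out.joinpath("tra_summary.json").write_text(
            json.dumps(summary, indent=2) + "\n")
        completed.append("tra-report")
        artifacts |= {
            "classification": classification, "downsampled": downsampled,
            "normalized": normed, "proportions": proportions,
            "tau_summary": tau_summary, "tau_shifts": tau_shifts,
            "pca_scores": scores, "pca_variance_fractions": var_frac,
            "correlation": corr, "clades": clades, "homolog_panel": panel,
        }

        if config.de_group and config.de_group in bulk.unit_meta.columns:
            design = _de.DesignSpec(group=config.de_group, blocks=[])
            de_result = _de.differential_expression(
                normed, design, meta=bulk.unit_meta,
                fdr_threshold=config.fdr_threshold)
            de_result.to_frame().to_csv(out / "bulk_de.tsv", sep="\t")
            artifacts["de"] = de_result
            completed.append("de")
    except StageFailure:
        raise
    except EtacError:
        raise
    finally:
        _stamp(config, out, "tra", completed)
    return artifacts
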