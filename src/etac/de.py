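"""Blocked linear models with empirical-Bayes moderated t-tests, BH FDR,
median-of-ratios bulk normalization and count-level downsampling.

Per gene an ordinary least-squares model is fitted to log2 expression with a
treatment-coded group contrast and categorical blocking factors (donor, plate
column in the single-cell arm).  Residual variances are shrunk toward a
common prior fitted by the closed-form method of moments on log s^2 (the
log-F moment match used by limma's moderated t): with residual df d_g,

    e_g = log(s^2_g) - psi(d_g/2) + log(d_g/2)
    d0 solves psi'(d0/2) = Var(e) - mean(psi'(d_g/2))       (trigamma inverse)
    s0^2 = exp(mean(e) + psi(d0/2) - log(d0/2))
    s~^2_g = (d0 s0^2 + d_g s^2_g) / (d0 + d_g)

and the moderated t uses d_g + d0 degrees of freedom.  Significance is
called at a Benjamini-Hochberg FDR of 1% by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, EtacError
from .qc import NormalizedMatrix

logger = logging.getLogger("etac")


class DesignError(EtacError):
    pass


class DegenerateVarianceError(EtacError):
    pass


class NoReferenceGeneError(EtacError):
    pass


@dataclass
class DesignSpec:
    """Contrast group factor plus categorical blocking factors.

    ``group`` and each entry of ``blocks`` name columns of the unit metadata.
    Encoding is treatment-coded indicators with an intercept; the contrast is
    the indicator of the second group level versus the first.
    """

    group: str
    blocks: list[str] = field(default_factory=list)


@dataclass
class DEResult:
    gene_ids: list[str]
    effect: np.ndarray          # log2 fold change (contrast coefficient)
    residual_var: np.ndarray
    residual_df: np.ndarray
    moderated_var: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    d0: float
    s0_sq: float
    fdr_threshold: float = 0.01

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log2_fc": self.effect,
                "s2": self.residual_var,
                "df": self.residual_df,
                "s2_post": self.moderated_var,
                "t": self.t,
                "p_value": self.p,
                "q_value": self.q,
                "significant": self.q <= self.fdr_threshold,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


@dataclass
class BulkNorm:
    unit_ids: list[str]
    factors: np.ndarray
    offset: float = 1.0
    downsample_target: int = 20_000_000

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("bulk size factors must be positive")


# ---------------------------------------------------------------------------
# Design and per-gene fits
# ---------------------------------------------------------------------------

def build_design(meta: pd.DataFrame, design: DesignSpec) -> tuple[np.ndarray, int, list[str]]:
    """Treatment-coded design matrix with intercept; returns (X, contrast
    column index, column names).  Aliased blocking columns are dropped and
    logged; an aliased contrast raises :class:`DesignError`."""
    group = meta[design.group].astype(str)
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise DesignError(f"group factor {design.group!r} needs exactly 2 levels, "
                          f"found {levels}")
    cols = [np.ones(len(meta)), (group == levels[1]).to_numpy(float)]
    names = ["intercept", f"{design.group}[{levels[1]}]"]
    for block in design.blocks:
        vals = meta[block].astype(str)
        for lvl in sorted(vals.unique())[1:]:
            cols.append((vals == lvl).to_numpy(float))
            names.append(f"{block}[{lvl}]")
    X = np.column_stack(cols)
    # the contrast must not lie in the span of intercept + blocking columns
    blocks_only = np.delete(X, 1, axis=1)
    resid = X[:, 1] - blocks_only @ np.linalg.lstsq(blocks_only, X[:, 1], rcond=None)[0]
    if np.allclose(resid, 0, atol=1e-10):
        raise DesignError(
            f"contrast {names[1]} is confounded with blocking factors "
            f"{design.blocks}"
        )
    # drop aliased columns greedily (never the intercept or contrast)
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("design: dropping aliased column %s", names[j])
    X = X[:, keep]
    names = [names[j] for j in keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design rank-deficient after dropping aliased columns")
    return X, 1, names


def fit_blocked_models(
    matrix: NormalizedMatrix | pd.DataFrame,
    meta: pd.DataFrame | None,
    design: DesignSpec,
) -> tuple[pd.DataFrame, float]:
    """Per-gene OLS of log2 expression on the blocked design.

    Returns a frame of (effect, s2, df) per gene and the contrast's unscaled
    variance v (so Var(effect) = s^2 * v).
    """
    if isinstance(matrix, NormalizedMatrix):
        values = matrix.values
        gene_ids = list(matrix.gene_ids)
        meta = matrix.unit_meta if meta is None else meta
    else:
        values = matrix.to_numpy(dtype=float)
        gene_ids = [str(g) for g in matrix.index]
    if meta is None:
        raise DesignError("unit metadata required for the design")
    for level, cnt in pd.Series(meta[design.group].astype(str)).value_counts().items():
        if cnt < 2:
            raise DesignError(f"group level {level!r} has fewer than 2 units")
    X, contrast_idx, _ = build_design(meta, design)
    n, rank = X.shape[0], np.linalg.matrix_rank(X)
    pinv = np.linalg.pinv(X)
    beta = pinv @ values.T                        # coefficients x genes
    resid = values.T - X @ beta
    df = n - rank
    s2 = (resid**2).sum(axis=0) / df
    v = float(np.linalg.inv(X.T @ X)[contrast_idx, contrast_idx])
    table = pd.DataFrame(
        {"effect": beta[contrast_idx], "s2": s2, "df": float(df)},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return table, v


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration on the monotone map."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def empirical_bayes_moderate(
    s2: np.ndarray, df: np.ndarray | float
) -> tuple[float, float, np.ndarray]:
    """Fit the scaled inverse-chi^2 prior (d0, s0^2) and shrink variances.

    Uses the closed-form log-F moment match (see module docstring).  Genes
    with s^2 = 0 are accommodated through a small offset in the log; an
    all-zero variance vector is degenerate and raises.  Returns
    (d0, s0_sq, moderated s~^2); d0 = inf means complete shrinkage to s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    usable = df >= 1
    if usable.sum() < 10:
        raise EtacError("need >= 10 genes with residual df >= 1")
    if np.all(s2[usable] == 0):
        raise DegenerateVarianceError("all residual variances are zero")
    z = np.log(np.maximum(s2[usable], 1e-300))
    d = df[usable]
    if np.ptp(z) < 1e-12:
        # degenerate spread: the prior collapses onto the common variance
        s0_sq = float(np.exp(z.mean()))
        return np.inf, s0_sq, np.full_like(s2, s0_sq)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = e_var - float(np.mean(polygamma(1, d / 2.0)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, s2_post


def moderated_t_test(
    effect: np.ndarray,
    s2_post: np.ndarray,
    contrast_var: float,
    df: np.ndarray | float,
    d0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t = effect / sqrt(s~^2 v); two-sided p on df + d0.

    Genes with zero moderated variance and zero effect get t = 0, p = 1
    (logged); zero variance with a nonzero effect gets t = +/-inf, p = 0.
    """
    effect = np.asarray(effect, dtype=float)
    s2_post = np.asarray(s2_post, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), effect.shape)
    se = np.sqrt(s2_post * contrast_var)
    zero_se = se == 0
    if zero_se.any():
        logger.info("%d genes with zero moderated variance", int(zero_se.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_se, np.where(effect == 0, 0.0, np.inf * np.sign(effect)),
                     effect / np.where(zero_se, 1.0, se))
    total_df = df + d0
    if np.isinf(d0):
        p = 2.0 * scipy.stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(t), total_df)
    p = np.where(zero_se & (effect == 0), 1.0, p)
    return t, np.clip(p, 0.0, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: NormalizedMatrix | pd.DataFrame,
    design: DesignSpec,
    meta: pd.DataFrame | None = None,
    fdr_threshold: float = 0.01,
    shrink_coefficients: float = 0.0,
) -> DEResult:
    """Full moderated-t pipeline: blocked OLS -> EB moderation -> t -> BH.

    ``shrink_coefficients`` > 0 applies an optional ridge-style shrinkage
    effect <- effect * df/(df + lambda) before testing (off by default; the
    standard method moderates variances, not coefficients).
    """
    table, v = fit_blocked_models(matrix, meta, design)
    d0, s0_sq, s2_post = empirical_bayes_moderate(
        table["s2"].to_numpy(), table["df"].to_numpy()
    )
    effect = table["effect"].to_numpy()
    if shrink_coefficients > 0:
        effect = effect * table["df"].to_numpy() / (
            table["df"].to_numpy() + shrink_coefficients
        )
    t, p = moderated_t_test(effect, s2_post, v, table["df"].to_numpy(), d0)
    q = bh_adjust(p)
    return DEResult(
        gene_ids=list(table.index), effect=effect,
        residual_var=table["s2"].to_numpy(), residual_df=table["df"].to_numpy(),
        moderated_var=s2_post, t=t, p=p, q=q, d0=d0, s0_sq=s0_sq,
        fdr_threshold=fdr_threshold,
    )


# ---------------------------------------------------------------------------
# Bulk normalization and downsampling
# ---------------------------------------------------------------------------

def median_ratio_size_factors(counts: CountMatrix) -> BulkNorm:
    """Median-of-ratios size factors over genes positive in every sample."""
    mat = counts.counts.astype(float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise NoReferenceGeneError("no gene has positive counts in every sample")
    ref = np.exp(np.log(mat[all_pos]).mean(axis=1))  # per-gene geometric mean
    factors = np.median(mat[all_pos] / ref[:, None], axis=0)
    return BulkNorm(unit_ids=list(counts.unit_ids), factors=factors)


def normalize_bulk_log2(counts: CountMatrix, norm: BulkNorm) -> NormalizedMatrix:
    """log2(count / factor + 1) with median-of-ratios factors."""
    if list(norm.unit_ids) != list(counts.unit_ids):
        raise EtacError("bulk size factors misaligned with count matrix")
    values = np.log2(counts.counts / norm.factors[None, :] + norm.offset)
    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids), unit_ids=list(counts.unit_ids),
        values=values, offset=norm.offset,
        gene_meta=counts.gene_meta, unit_meta=counts.unit_meta,
    )


def downsample_counts(
    counts: CountMatrix, target_per_unit: int, seed: int
) -> CountMatrix:
    """Thin each unit's counts to exactly ``target_per_unit`` reads.

    Per unit the retained reads are a multivariate-hypergeometric draw
    (sampling without replacement from the unit's reads), the count-level
    equivalent of read subsampling.  Units already at or below the target
    pass through unchanged (logged).  Column sums of downsampled units equal
    the target exactly; reproducible by seed.
    """
    if target_per_unit < 0:
        raise ValueError("downsampling target must be >= 0")
    rng = np.random.default_rng(seed)
    out = counts.counts.copy()
    for j in range(out.shape[1]):
        total = int(out[:, j].sum())
        if total <= target_per_unit:
            if total < target_per_unit:
                logger.info(
                    "unit %s below target (%d < %d); passed through",
                    counts.unit_ids[j], total, target_per_unit,
                )
            continue
        out[:, j] = rng.multivariate_hypergeometric(out[:, j], target_per_unit)
    return CountMatrix(
        gene_ids=list(counts.gene_ids), unit_ids=list(counts.unit_ids),
        counts=out, unit_meta=counts.unit_meta, gene_meta=counts.gene_meta,
    )
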