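"""Highly-variable-gene detection from the CV^2-vs-mean technical trend.

Per gene the mean mu and squared coefficient of variation CV^2 are computed
on size-factor-normalized counts (linear scale — the parameterization with a
chi-squared excess test; a flag reproduces the log2-mean variant).  The
technical trend CV^2(mu) = a1/mu + alpha0 is fitted by a Gamma-family GLM
with identity link on 1/mu, preferring ERCC-like spike-in genes when enough
are present.  A gene's excess variability is scored by

    (n_cells - 1) * CV^2_g / trend(mu_g)  ~  chi^2(n_cells - 1)

under the null, and genes with upper-tail p <= alpha (default 0.01) are
flagged as highly variable.  No multiple-testing correction is applied
before the cut; an optional FDR mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io import CountMatrix, EtacError
from .qc import NormalizedMatrix, SizeFactors

logger = logging.getLogger("etac")

MIN_FIT_GENES = 20


class DegenerateFitError(EtacError):
    """The fitted CV^2 trend is non-positive over the observed mean range."""


@dataclass
class HVGFit:
    """Observed per-gene (mu, CV^2), fitted trend, chi^2 p-values and calls."""

    gene_ids: list[str]
    mean: np.ndarray
    cv2: np.ndarray
    a1: float
    alpha0: float
    n_cells: int
    p_value: np.ndarray | None = None
    hvg: np.ndarray | None = None
    alpha: float = 0.01

    def trend(self, mu: np.ndarray) -> np.ndarray:
        return self.a1 / np.asarray(mu, dtype=float) + self.alpha0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"mean": self.mean, "cv2": self.cv2},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )
        if self.p_value is not None:
            frame["p_value"] = self.p_value
            frame["hvg"] = self.hvg
        return frame

    @property
    def hvg_gene_ids(self) -> list[str]:
        if self.hvg is None:
            raise ValueError("call_hvgs has not been run")
        return [g for g, h in zip(self.gene_ids, self.hvg) if h]


def _normalized_values(
    source: NormalizedMatrix | CountMatrix,
    size_factors: SizeFactors | None,
    on_log_scale: bool,
) -> tuple[list[str], np.ndarray, int, np.ndarray]:
    """Linear- (or log2-) scale expression matrix + technical mask."""
    if isinstance(source, NormalizedMatrix):
        values = source.values if on_log_scale else 2.0 ** source.values - source.offset
        meta = source.gene_meta
        gene_ids = list(source.gene_ids)
    else:
        if size_factors is None:
            raise ValueError("size_factors required with raw counts")
        linear = source.counts / np.asarray(size_factors.factors)[None, :]
        values = np.log2(linear + 1.0) if on_log_scale else linear
        meta = source.gene_meta
        gene_ids = list(source.gene_ids)
    if meta is not None and "is_technical" in getattr(meta, "columns", []):
        tech = meta["is_technical"].to_numpy(dtype=bool)
    else:
        tech = np.zeros(len(gene_ids), dtype=bool)
    return gene_ids, np.asarray(values, dtype=float), values.shape[1], tech


def fit_cv2_trend(
    source: NormalizedMatrix | CountMatrix,
    size_factors: SizeFactors | None = None,
    use_technical: bool = True,
    log2_means: bool = False,
) -> HVGFit:
    """Fit the technical trend CV^2 = a1/mu + alpha0.

    Fit genes are the flagged ERCC-like technical genes when ``use_technical``
    and at least 20 are present; otherwise all genes with mean above the 10th
    percentile of positive means.  Genes with zero variance are recorded with
    CV^2 = 0 but excluded from fitting.  A trend that is non-positive at any
    observed mean raises :class:`DegenerateFitError`.
    """
    gene_ids, values, n_cells, tech = _normalized_values(source, size_factors, log2_means)
    mu = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, 0.0)

    positive = mu > 0
    if positive.sum() < MIN_FIT_GENES:
        raise EtacError(f"need >= {MIN_FIT_GENES} genes with positive mean")
    if use_technical and (tech & positive).sum() >= MIN_FIT_GENES:
        fit_mask = tech & positive & (var > 0)
        logger.info("CV2 trend fitted on %d technical genes", int(fit_mask.sum()))
    else:
        floor = np.quantile(mu[positive], 0.10)
        fit_mask = positive & (mu >= floor) & (var > 0)

    x = 1.0 / mu[fit_mask]
    y = cv2[fit_mask]
    X = sm.add_constant(x)
    # OLS start values, refined by a Gamma GLM with identity link
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    alpha0, a1 = float(ols[0]), float(ols[1])
    try:
        import warnings

        with warnings.catch_warnings():
            # identity link on Gamma is the method's parameterization; the
            # domain warning and IRLS separation chatter are expected
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                y, X, family=sm.families.Gamma(link=sm.families.links.Identity())
            )
            res = glm.fit(start_params=[max(alpha0, 1e-8), max(a1, 1e-8)], maxiter=100)
        if np.all(np.isfinite(res.params)):
            alpha0, a1 = float(res.params[0]), float(res.params[1])
    except Exception:  # keep the OLS fit when IRLS cannot improve it
        logger.warning("Gamma GLM for CV2 trend failed; using least-squares fit")

    fit = HVGFit(gene_ids=gene_ids, mean=mu, cv2=cv2, a1=a1, alpha0=alpha0, n_cells=n_cells)
    trend_at_obs = fit.trend(np.where(positive, mu, np.nan))
    if np.nanmin(trend_at_obs) <= 0:
        raise DegenerateFitError(
            f"fitted trend non-positive over observed means (a1={a1:.4g}, "
            f"alpha0={alpha0:.4g}, min mu={mu[positive].min():.4g})"
        )
    return fit


def call_hvgs(fit: HVGFit, alpha: float = 0.01, fdr: bool = False) -> HVGFit:
    """Chi^2 excess-variability test against the fitted trend.

    ``fdr=True`` applies Benjamini-Hochberg before thresholding instead of
    the default raw-p cut.
    """
    df = fit.n_cells - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = fit.trend(fit.mean)
        stat = np.where(fit.mean > 0, df * fit.cv2 / expected, 0.0)
    p = scipy.stats.chi2.sf(stat, df)
    p = np.where(fit.mean > 0, p, 1.0)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        q = multipletests(p, method="fdr_bh")[1]
        calls = q <= alpha
    else:
        calls = p <= alpha
    return HVGFit(
        gene_ids=fit.gene_ids, mean=fit.mean, cv2=fit.cv2, a1=fit.a1,
        alpha0=fit.alpha0, n_cells=fit.n_cells, p_value=p, hvg=calls, alpha=alpha,
    )
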