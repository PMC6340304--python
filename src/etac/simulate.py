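"""Synthetic-data generators with known ground truth for every pipeline input.

Three generators produce every pipeline input class:

* a tissue atlas (default 107 groups) with planted tissue-restricted,
  constitutive and intermediate genes under multiplicative lognormal noise;
* SmartSeq2-scale single-cell counts with donor/plate structure, lognormal
  cell size factors, negative-binomial noise, ERCC-like technical genes and
  a latent maturation trajectory carrying monotone-up (CCR7/CCL19-like),
  monotone-down (CCR6-like) and transient (AIRE-like, terminal-window)
  marker programs;
* bulk population profiles contrasting a promiscuous-TRA (mTEC-like)
  population with TRA-silent (DC-like) populations.

Counts follow NB(mean mu, dispersion alpha) with variance mu + alpha mu^2
(alpha = 0 recovers Poisson).  All generators are deterministic given their
spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSet, TissueAtlas


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance mu + alpha mu^2; Poisson when alpha == 0."""
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def _lognormal_cv(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sdlog = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-sdlog**2 / 2.0, sigma=sdlog, size=shape)


# ---------------------------------------------------------------------------
# Tissue atlas
# ---------------------------------------------------------------------------

@dataclass
class AtlasSpec:
    n_genes: int = 10_000
    n_tissue_groups: int = 107
    fraction_tra: float = 0.10
    fraction_constitutive: float = 0.60
    fraction_misc: float = 0.30
    tra_breadth: tuple[int, int] = (1, 3)   # tissues per TRA gene, inclusive
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.fraction_tra + self.fraction_constitutive + self.fraction_misc
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def make_tissue_atlas(spec: AtlasSpec) -> tuple[TissueAtlas, pd.DataFrame]:
    """Planted-structure atlas + per-gene truth labels.

    TRA genes express at a high level in their 1-3 assigned tissues and are
    exactly zero elsewhere (tau = 1 at breadth 1, noise 0); constitutive
    genes are uniform (tau = 0 at noise 0); miscellaneous genes peak in a few
    tissues over a broad moderate baseline, giving intermediate tau.
    """
    rng = np.random.default_rng(spec.seed)
    n, t = spec.n_genes, spec.n_tissue_groups
    n_tra = int(round(spec.fraction_tra * n))
    n_const = int(round(spec.fraction_constitutive * n))
    n_misc = n - n_tra - n_const
    labels = np.array(["TRA"] * n_tra + ["constitutive"] * n_const
                      + ["miscellaneous"] * n_misc, dtype=object)
    expr = np.zeros((n, t))
    lo, hi = spec.tra_breadth
    for g in range(n_tra):
        breadth = int(rng.integers(lo, hi + 1))
        tissues = rng.choice(t, size=breadth, replace=False)
        expr[g, tissues] = rng.uniform(50.0, 200.0)
    base_const = rng.uniform(5.0, 50.0, size=n_const)
    expr[n_tra : n_tra + n_const] = base_const[:, None]
    for g in range(n_tra + n_const, n):
        # graded: peak in a few tissues over a broad moderate baseline,
        # placing tau between the constitutive and TRA bands
        n_high = int(rng.integers(1, 6))
        peak = rng.uniform(20.0, 100.0)
        floor_frac = rng.uniform(0.25, 0.55)
        expr[g, :] = peak * floor_frac
        expr[g, rng.choice(t, size=n_high, replace=False)] = peak
    expr *= _lognormal_cv(rng, spec.noise_cv, expr.shape)
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    atlas = TissueAtlas(
        gene_ids=gene_ids,
        tissue_group_ids=[f"tissue_{j:03d}" for j in range(t)],
        expression=expr,
    )
    truth = pd.DataFrame({"true_category": labels},
                         index=pd.Index(gene_ids, name="gene_id"))
    return atlas, truth


# ---------------------------------------------------------------------------
# Single-cell experiment
# ---------------------------------------------------------------------------

@dataclass
class ScSimSpec:
    """Single-cell simulation with a latent maturation trajectory.

    Latent time per cell is Uniform(0, 1) (``bimodal=True`` concentrates
    cells at the two ends to mimic a two-branch density pattern).  Marker
    programs: ``n_up`` genes rise monotonically with latent time
    (CCR7/CCL19-like), ``n_down`` fall (CCR6-like), and ``n_transient``
    AIRE-like genes have nonzero mean only inside ``transient_window``
    (default the terminal quarter of the trajectory).  Batch effects are
    multiplicative lognormal per (donor, gene) and (plate column, gene).
    """

    n_cells: int = 200
    n_genes: int = 2000
    n_donors: int = 3
    n_plate_columns: int = 12
    n_technical_genes: int = 40
    n_up: int = 30
    n_down: int = 30
    n_transient: int = 20
    transient_window: tuple[float, float] = (0.75, 1.0)
    true_size_factor_sdlog: float = 0.25
    nb_dispersion: float = 0.10
    donor_effect_sdlog: float = 0.10
    plate_effect_sdlog: float = 0.05
    mean_library_size: float = 200_000.0
    program_fold: float = 6.0     # dynamic range of trajectory programs
    bimodal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.transient_window
        if not (0.0 <= a < b <= 1.0):
            raise ValueError("transient_window must be a sub-interval of [0, 1]")
        if self.n_up + self.n_down + self.n_transient + self.n_technical_genes > self.n_genes:
            raise ValueError("program plus technical genes exceed n_genes")


def make_sc_experiment(spec: ScSimSpec) -> tuple[CountMatrix, dict]:
    """Single-cell counts + full ground truth.

    Returns the count matrix (with donor/plate metadata and technical-gene
    flags) and a truth dict with ``latent_time``, ``true_size_factors``,
    ``programs`` (GeneSets for up/down/transient), and batch labels.
    """
    rng = np.random.default_rng(spec.seed)
    n_c, n_g = spec.n_cells, spec.n_genes
    if spec.bimodal:
        half = n_c // 2
        time = np.concatenate([
            rng.beta(2, 6, size=half), rng.beta(6, 2, size=n_c - half)
        ])
        time = time[rng.permutation(n_c)]
    else:
        time = rng.uniform(0.0, 1.0, size=n_c)

    tech = np.zeros(n_g, dtype=bool)
    tech[n_g - spec.n_technical_genes:] = True
    bio = ~tech
    n_bio = int(bio.sum())

    gene_ids = [f"gene_{i:05d}" for i in range(n_g - spec.n_technical_genes)] + [
        f"ERCC-{i:05d}" for i in range(spec.n_technical_genes)
    ]
    # program gene indices sit at the front of the biological block
    up_idx = np.arange(0, spec.n_up)
    down_idx = np.arange(spec.n_up, spec.n_up + spec.n_down)
    trans_idx = np.arange(spec.n_up + spec.n_down,
                          spec.n_up + spec.n_down + spec.n_transient)

    # baseline relative gene abundances (lognormal), scaled to the library size
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_g)
    fold = spec.program_fold
    profile = np.repeat(base[:, None], n_c, axis=1)
    t_row = time[None, :]
    profile[up_idx] = base[up_idx, None] * (1.0 + (fold - 1.0) * t_row)
    profile[down_idx] = base[down_idx, None] * (fold - (fold - 1.0) * t_row)
    a, b = spec.transient_window
    # smooth activation inside the window (exactly zero outside) keeps the
    # expression manifold continuous: a smoothstep ramp when the window runs
    # to the trajectory end, a raised-cosine bump for interior windows
    u = np.clip((time - a) / (b - a), 0.0, 1.0)
    if b >= 1.0 - 1e-9:
        act = u * u * (3.0 - 2.0 * u)
    else:
        act = np.sin(np.pi * u) ** 2
    act = np.where((time >= a) & (time <= b), act, 0.0)
    profile[trans_idx] = base[trans_idx, None] * fold * act[None, :]

    donors = rng.integers(0, spec.n_donors, size=n_c)
    plates = rng.integers(0, spec.n_plate_columns, size=n_c)
    donor_fx = rng.lognormal(0.0, spec.donor_effect_sdlog, size=(spec.n_donors, n_g))
    plate_fx = rng.lognormal(0.0, spec.plate_effect_sdlog,
                             size=(spec.n_plate_columns, n_g))
    batch = donor_fx[donors].T * plate_fx[plates].T   # genes x cells
    profile[bio] *= batch[bio]

    size_factors = rng.lognormal(0.0, spec.true_size_factor_sdlog, size=n_c)
    size_factors /= np.exp(np.mean(np.log(size_factors)))

    # normalize biological genes to the target library, apply size factors;
    # technical (spike-in) genes are independent of cell content
    col_sums = profile[bio].sum(axis=0)
    mu = np.zeros((n_g, n_c))
    mu[bio] = profile[bio] / col_sums[None, :] * spec.mean_library_size * size_factors
    if tech.any():
        tech_level = spec.mean_library_size * 0.02 / spec.n_technical_genes
        mu[tech] = base[tech, None] / base[tech].mean() * tech_level

    counts = _nb_sample(rng, mu, spec.nb_dispersion)
    unit_ids = [f"cell_{i:04d}" for i in range(n_c)]
    unit_meta = pd.DataFrame(
        {
            "donor": [f"donor_{d}" for d in donors],
            "plate_col": [f"col_{p:02d}" for p in plates],
        },
        index=pd.Index(unit_ids, name="unit_id"),
    )
    gene_meta = pd.DataFrame(
        {"is_technical": tech}, index=pd.Index(gene_ids, name="gene_id")
    )
    cm = CountMatrix(gene_ids=gene_ids, unit_ids=unit_ids, counts=counts,
                     unit_meta=unit_meta, gene_meta=gene_meta)
    truth = {
        "latent_time": pd.Series(time, index=unit_ids, name="latent_time"),
        "true_size_factors": pd.Series(size_factors, index=unit_ids,
                                       name="true_size_factor"),
        "programs": {
            "up": GeneSet("up", [gene_ids[i] for i in up_idx]),
            "down": GeneSet("down", [gene_ids[i] for i in down_idx]),
            "transient": GeneSet("transient", [gene_ids[i] for i in trans_idx]),
        },
        "donor": unit_meta["donor"],
        "plate_col": unit_meta["plate_col"],
    }
    return cm, truth


# ---------------------------------------------------------------------------
# Bulk populations
# ---------------------------------------------------------------------------

@dataclass
class BulkPopulation:
    name: str
    n_replicates: int = 3
    tra_program_on: bool = False
    tra_expression_level: float = 30.0
    library_size: float = 2_000_000.0


@dataclass
class BulkSimSpec:
    populations: list[BulkPopulation] = field(default_factory=lambda: [
        BulkPopulation("mTEC", tra_program_on=True),
        BulkPopulation("eTAC"),
        BulkPopulation("cDC"),
    ])
    n_genes: int = 2000
    n_tra_genes: int = 200
    tra_leak_fraction: float = 0.5     # share of TRA genes with a low leak
    tra_leak_level: tuple[float, float] = (0.5, 3.0)  # relative units
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.populations) < 2:
            raise ValueError("need >= 2 populations")
        if any(p.n_replicates < 1 for p in self.populations):
            raise ValueError("each population needs >= 1 replicate")


def make_bulk_populations(
    spec: BulkSimSpec,
    gene_ids: list[str] | None = None,
    tra_gene_ids: list[str] | None = None,
) -> tuple[CountMatrix, dict]:
    """Bulk NB profiles with a planted promiscuous-TRA program.

    Populations with ``tra_program_on`` express the planted TRA gene set at
    ``tra_expression_level`` (relative units); in the others a
    ``tra_leak_fraction`` subset of TRA genes carries a low shared leak (as
    peripheral tissues express some TRAs) and the rest stay at exactly 0.
    ``gene_ids`` / ``tra_gene_ids`` let the gene universe be shared with a
    synthetic atlas so classifications join exactly; by default the first
    ``n_tra_genes`` ids are the planted set (matching the atlas generator's
    layout).  Truth includes the leak-free ("silent") TRA subset, the panel
    to use for homolog-style absent-in-DC checks.
    """
    rng = np.random.default_rng(spec.seed)
    n_g = spec.n_genes if gene_ids is None else len(gene_ids)
    gene_ids = gene_ids or [f"gene_{i:05d}" for i in range(n_g)]
    if tra_gene_ids is None:
        tra_gene_ids = gene_ids[: spec.n_tra_genes]
    tra_mask = np.isin(np.array(gene_ids, dtype=object), np.array(tra_gene_ids, dtype=object))

    baseline = rng.lognormal(mean=2.0, sigma=1.0, size=n_g)
    baseline[tra_mask] = 0.0   # TRA genes silent unless the program is on
    tra_idx = np.flatnonzero(tra_mask)
    n_leak = int(round(spec.tra_leak_fraction * tra_idx.size))
    leak_idx = rng.choice(tra_idx, size=n_leak, replace=False)
    baseline[leak_idx] = rng.uniform(*spec.tra_leak_level, size=n_leak)
    silent_idx = np.setdiff1d(tra_idx, leak_idx)

    # per-gene promiscuous-program profile, shared by all replicates of a
    # program-on population (a flat level would leave replicate correlation
    # over TRA genes to pure counting noise)
    program_profile = np.zeros(n_g)
    program_profile[tra_idx] = rng.lognormal(mean=0.0, sigma=1.0, size=tra_idx.size)

    cols, ids, pops = [], [], []
    for pop in spec.populations:
        mean_rel = baseline.copy()
        if pop.tra_program_on:
            mean_rel = mean_rel + program_profile * pop.tra_expression_level
        mean_rel = np.maximum(mean_rel, 0.0)
        scale = pop.library_size / mean_rel.sum()
        for r in range(pop.n_replicates):
            cols.append(_nb_sample(rng, mean_rel * scale, spec.nb_dispersion))
            ids.append(f"{pop.name}_rep{r + 1}")
            pops.append(pop.name)
    counts = np.column_stack(cols)
    unit_meta = pd.DataFrame({"population": pops},
                             index=pd.Index(ids, name="unit_id"))
    cm = CountMatrix(gene_ids=list(gene_ids), unit_ids=ids, counts=counts,
                     unit_meta=unit_meta)
    gene_arr = np.array(gene_ids, dtype=object)
    truth = {
        "tra_genes": GeneSet("planted_tra", list(gene_arr[tra_mask])),
        "tra_silent": GeneSet("planted_tra_silent", list(gene_arr[silent_idx])),
        "tra_leaky": GeneSet("planted_tra_leaky", list(gene_arr[np.sort(leak_idx)])),
        "population": unit_meta["population"],
        "tra_on": {p.name: p.tra_program_on for p in spec.populations},
    }
    return cm, truth
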