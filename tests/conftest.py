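import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import etac

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sc_experiment():
    """Default-spec single-cell simulation (trajectory + batches + spike-ins)."""
    spec = etac.ScSimSpec(seed=2)
    cm, truth = etac.make_sc_experiment(spec)
    return cm, truth


@pytest.fixture(scope="session")
def sc_normalized(sc_experiment):
    """QC-filtered, deconvolution-normalized version of the default sim."""
    cm, truth = sc_experiment
    retained, _ = etac.filter_cells(cm)
    retained = etac.filter_genes(retained)
    factors = etac.deconvolution_size_factors(retained)
    return etac.normalize_log2(retained, factors), truth


@pytest.fixture(scope="session")
def bulk_with_atlas():
    """Matched synthetic atlas + bulk populations sharing one gene universe."""
    atlas, atlas_truth = etac.make_tissue_atlas(
        etac.AtlasSpec(n_genes=2000, seed=4)
    )
    tra_ids = atlas_truth.index[atlas_truth["true_category"] == "TRA"].tolist()
    bulk, bulk_truth = etac.make_bulk_populations(
        etac.BulkSimSpec(seed=4), gene_ids=list(atlas.gene_ids), tra_gene_ids=tra_ids
    )
    return atlas, atlas_truth, bulk, bulk_truth


@pytest.fixture
def small_counts():
    """Tiny deterministic count matrix with metadata for contract tests."""
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 20, size=(6, 4))
    gene_ids = [f"g{i}" for i in range(6)]
    unit_ids = [f"u{j}" for j in range(4)]
    unit_meta = pd.DataFrame(
        {"donor": ["d0", "d0", "d1", "d1"], "population": ["A", "A", "B", "B"]},
        index=pd.Index(unit_ids, name="unit_id"),
    )
    return etac.CountMatrix(gene_ids, unit_ids, counts, unit_meta=unit_meta)
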