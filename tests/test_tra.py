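"""Tau tissue-specificity scoring, TRA classification and reporting views."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import etac
from etac.qc import NormalizedMatrix
from etac.tra import TauClassification, expressed_genes


class TestTauIndex:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            ([3, 3, 3, 3, 3], 0.0),                    # uniform
            ([7, 0, 0, 0, 0], 1.0),                    # single tissue
            ([10, 5, 0, 0], (0 + 0.5 + 1 + 1) / 3),    # mixed, hand oracle
            ([1, 1], 0.0),
            ([0, 4], 1.0),
        ],
    )
    def test_hand_oracle(self, profile, expected):
        assert etac.tau_index(np.array(profile, float)) == pytest.approx(expected)

    def test_all_zero_is_nan(self):
        assert np.isnan(etac.tau_index(np.zeros(4)))

    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=2, max_size=20),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, profile, c):
        x = np.asarray(profile)
        if x.max() == 0:
            return
        assert etac.tau_index(c * x) == pytest.approx(etac.tau_index(x), abs=1e-9)

    def test_monotone_in_concentration(self):
        """Zeroing a non-maximal tissue (max fixed) never decreases tau."""
        rng = np.random.default_rng(50)
        for _ in range(20):
            x = rng.uniform(0, 10, 8)
            x[0] = 11.0  # fixed max
            tau0 = etac.tau_index(x)
            j = rng.integers(1, 8)
            y = x.copy()
            y[j] = 0.0
            assert etac.tau_index(y) >= tau0 - 1e-12

    def test_invalid_profiles(self):
        with pytest.raises(ValueError):
            etac.tau_index(np.array([1.0]))
        with pytest.raises(ValueError):
            etac.tau_index(np.array([1.0, -2.0]))


class TestClassifyGenes:
    def test_boundary_inclusion(self):
        # profiles engineered to land exactly on tau = 0.8 and tau = 0.4
        n = 6

        def profile(tau):
            # x = (1, 1-tau, ..., 1-tau) has tau-index exactly tau
            return np.array([1.0] + [1 - tau] * (n - 1))

        atlas = etac.TissueAtlas(
            ["tra_edge", "const_edge", "mid"],
            [f"t{i}" for i in range(n)],
            np.vstack([profile(0.8), profile(0.4), profile(0.6)]),
        )
        cls = etac.classify_genes(atlas)
        assert cls.to_frame().loc["tra_edge", "category"] == "TRA"
        assert cls.to_frame().loc["const_edge", "category"] == "constitutive"
        assert cls.to_frame().loc["mid", "category"] == "miscellaneous"

    def test_all_zero_gene_unclassified(self):
        atlas = etac.TissueAtlas(["z", "g"], ["a", "b"],
                                 np.array([[0, 0], [1, 0.0]]))
        cls = etac.classify_genes(atlas)
        frame = cls.to_frame()
        assert frame.loc["z", "category"] == "unclassified"
        assert np.isnan(frame.loc["z", "tau"])
        assert frame.loc["g", "category"] == "TRA"

    def test_every_gene_accounted_exactly_once(self, bulk_with_atlas):
        atlas, _, _, _ = bulk_with_atlas
        cls = etac.classify_genes(atlas)
        counts = pd.Series(cls.category).value_counts()
        assert counts.sum() == len(atlas.gene_ids)


def _normed_from_linear(linear, gene_ids, unit_ids):
    return NormalizedMatrix(gene_ids, unit_ids, np.log2(linear + 1.0))


def _toy_classification():
    return TauClassification(
        gene_ids=["tra1", "tra2", "const1", "misc1"],
        tau=np.array([0.9, 0.95, 0.1, 0.6]),
        category=np.array(["TRA", "TRA", "constitutive", "miscellaneous"],
                          dtype=object),
    )


class TestProportions:
    def test_pure_tra_population(self):
        cls = _toy_classification()
        linear = np.array([[5, 0], [5, 0], [0, 5], [0, 5.0]])
        normed = _normed_from_linear(linear, cls.gene_ids, ["traP", "otherP"])
        pops = pd.Series(["traP", "otherP"], index=["traP", "otherP"])
        props = etac.tra_proportions(normed, cls, pops)
        assert props.loc["traP", "TRA"] == 1.0
        assert props.loc["otherP", "TRA"] == 0.0
        row = props.loc["otherP", ["TRA", "constitutive", "miscellaneous"]]
        assert row.sum() == pytest.approx(1.0)

    def test_planted_contrast(self, bulk_with_atlas):
        atlas, _, bulk, truth = bulk_with_atlas
        ds = etac.downsample_counts(bulk, 1_000_000, seed=1)
        normed = etac.normalize_bulk_log2(ds, etac.median_ratio_size_factors(ds))
        cls = etac.classify_genes(atlas)
        props = etac.tra_proportions(normed, cls, truth["population"])
        on = [p for p, flag in truth["tra_on"].items() if flag]
        off = [p for p, flag in truth["tra_on"].items() if not flag]
        assert all(props.loc[a, "TRA"] > props.loc[b, "TRA"]
                   for a in on for b in off)


class TestTauShift:
    def test_identical_populations_no_shift(self):
        cls = _toy_classification()
        linear = np.tile(np.array([[5], [5], [5], [5.0]]), (1, 4))
        normed = _normed_from_linear(linear, cls.gene_ids, list("abcd"))
        pops = pd.Series(["P1", "P1", "P2", "P2"], index=list("abcd"))
        summary, shifts = etac.tau_shift_summary(normed, cls, pops)
        assert summary.loc["P1", "q50"] == summary.loc["P2", "q50"]
        assert shifts.loc["P1", "P2"] == 1.0

    def test_planted_shift(self, bulk_with_atlas):
        atlas, _, bulk, truth = bulk_with_atlas
        ds = etac.downsample_counts(bulk, 1_000_000, seed=1)
        normed = etac.normalize_bulk_log2(ds, etac.median_ratio_size_factors(ds))
        cls = etac.classify_genes(atlas)
        summary, _ = etac.tau_shift_summary(normed, cls, truth["population"])
        on = [p for p, f in truth["tra_on"].items() if f][0]
        off = [p for p, f in truth["tra_on"].items() if not f][0]
        assert summary.loc[on, "mean"] > summary.loc[off, "mean"]

    def test_adding_constitutive_genes_lowers_median(self):
        cls = TauClassification(
            gene_ids=[f"t{i}" for i in range(4)] + [f"c{i}" for i in range(4)],
            tau=np.array([0.9] * 4 + [0.05] * 4),
            category=np.array(["TRA"] * 4 + ["constitutive"] * 4, dtype=object),
        )
        high = np.vstack([np.full((4, 2), 5.0), np.zeros((4, 2))])
        mixed = np.full((8, 2), 5.0)
        pops = pd.Series(["hi", "hi", "mix", "mix"],
                         index=["a", "b", "c", "d"])
        normed = _normed_from_linear(np.hstack([high, mixed]),
                                     cls.gene_ids, list("abcd"))
        summary, _ = etac.tau_shift_summary(normed, cls, pops)
        assert summary.loc["mix", "q50"] < summary.loc["hi", "q50"]


class TestPCAAndClades:
    def test_variance_fractions_shape(self, bulk_with_atlas):
        atlas, _, bulk, truth = bulk_with_atlas
        ds = etac.downsample_counts(bulk, 500_000, seed=1)
        normed = etac.normalize_bulk_log2(ds, etac.median_ratio_size_factors(ds))
        cls = etac.classify_genes(atlas)
        scores, frac = etac.pca_on_tra(normed, cls, truth["population"])
        assert np.all(frac[:-1] >= frac[1:])
        assert frac.sum() <= 1.0 + 1e-9
        assert len(scores) == len(normed.unit_ids)

    def test_rank_one_structure_dominates_pc1(self):
        rng = np.random.default_rng(51)
        cls = TauClassification(
            gene_ids=[f"g{i}" for i in range(40)],
            tau=np.full(40, 0.9),
            category=np.array(["TRA"] * 40, dtype=object),
        )
        u = rng.normal(size=40)
        v = rng.normal(size=6)
        linear = np.exp(np.outer(u, v)) * 10
        noisy = linear * (1 + 0.01 * rng.normal(size=linear.shape))
        normed = _normed_from_linear(np.abs(noisy), cls.gene_ids,
                                     [f"s{j}" for j in range(6)])
        pops = pd.Series(["P"] * 6, index=normed.unit_ids)
        _, frac = etac.pca_on_tra(normed, cls, pops)
        assert frac[0] >= 0.95

    def test_duplicated_sample_identical_scores(self):
        cls = _toy_classification()
        rng = np.random.default_rng(52)
        linear = rng.uniform(1, 20, size=(4, 3))
        linear = np.column_stack([linear, linear[:, 0]])
        normed = _normed_from_linear(linear, cls.gene_ids, list("abcd"))
        pops = pd.Series(["P"] * 4, index=list("abcd"))
        scores, _ = etac.pca_on_tra(normed, cls, pops)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["d"], atol=1e-9)

    def test_replicates_merge_first_and_matrix_valid(self):
        rng = np.random.default_rng(53)
        cls = TauClassification(
            gene_ids=[f"g{i}" for i in range(8)],
            tau=np.full(8, 0.9),
            category=np.array(["TRA"] * 8, dtype=object),
        )
        prof = rng.uniform(1, 9, 8)
        linear = np.column_stack([prof, prof, rng.uniform(1, 9, 8)])
        normed = _normed_from_linear(linear, cls.gene_ids, ["r1", "r2", "x"])
        corr, linkage, clades = etac.correlation_clades(normed, cls)
        assert corr.loc["r1", "r2"] == pytest.approx(1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)
        assert clades["r1"] == clades["r2"] != clades["x"]

    def test_planted_clade_topology(self, bulk_with_atlas):
        """DC-like populations form one clade excluding the mTEC-like one."""
        atlas, _, bulk, truth = bulk_with_atlas
        ds = etac.downsample_counts(bulk, 1_000_000, seed=1)
        normed = etac.normalize_bulk_log2(ds, etac.median_ratio_size_factors(ds))
        cls = etac.classify_genes(atlas)
        _, _, clades = etac.correlation_clades(normed, cls)
        pops = truth["population"]
        on = {p for p, f in truth["tra_on"].items() if f}
        dc_clades = {clades[u] for u in clades.index if pops[u] not in on}
        mtec_clades = {clades[u] for u in clades.index if pops[u] in on}
        assert len(dc_clades) == 1
        assert dc_clades.isdisjoint(mtec_clades)


class TestHomologPanel:
    def test_empty_and_missing(self):
        cls = _toy_classification()
        linear = np.ones((4, 2))
        normed = _normed_from_linear(linear, cls.gene_ids, ["a", "b"])
        pops = pd.Series(["P", "P"], index=["a", "b"])
        table, missing = etac.homolog_panel(normed, etac.GeneSet("e", []), pops)
        assert table.empty and missing == []
        table, missing = etac.homolog_panel(
            normed, etac.GeneSet("m", ["tra1", "ghost"]), pops)
        assert missing == ["ghost"]
        assert "tra1" in table.index

    def test_planted_homologs_absent_outside_program(self, bulk_with_atlas):
        atlas, _, bulk, truth = bulk_with_atlas
        ds = etac.downsample_counts(bulk, 1_000_000, seed=1)
        normed = etac.normalize_bulk_log2(ds, etac.median_ratio_size_factors(ds))
        panel, _ = etac.homolog_panel(normed, truth["tra_silent"],
                                      truth["population"])
        on = [p for p, f in truth["tra_on"].items() if f][0]
        off = [p for p, f in truth["tra_on"].items() if not f]
        assert panel[f"mean[{on}]"].mean() > 5.0
        for pop in off:
            assert panel[f"mean[{pop}]"].mean() < 0.2


def test_expressed_rule_threshold():
    gene_ids = ["hi", "lo"]
    linear = np.array([[4.0, 4.0], [0.2, 0.2]])
    normed = _normed_from_linear(linear, gene_ids, ["a", "b"])
    pops = pd.Series(["P", "P"], index=["a", "b"])
    table = expressed_genes(normed, pops, min_mean=1.0)
    assert bool(table.loc["hi", "P"]) and not bool(table.loc["lo", "P"])
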