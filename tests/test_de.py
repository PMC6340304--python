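"""Blocked linear models, EB variance moderation, moderated t, BH, bulk
normalization and hypergeometric downsampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st

import etac
from etac.de import (
    DesignError,
    DesignSpec,
    NoReferenceGeneError,
    bh_adjust,
    build_design,
    empirical_bayes_moderate,
    fit_blocked_models,
    moderated_t_test,
)


def _frame(values, unit_ids):
    return pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                        columns=unit_ids)


class TestBlockedFits:
    def test_two_groups_no_blocking_exact(self):
        meta = pd.DataFrame({"grp": list("AAABBB")}, index=[f"u{i}" for i in range(6)])
        frame = _frame([[0, 0, 0, 1, 1, 1.0]], meta.index)
        table, v = fit_blocked_models(frame, meta, DesignSpec("grp"))
        assert table["effect"].iloc[0] == pytest.approx(1.0)
        assert table["s2"].iloc[0] == pytest.approx(0.0, abs=1e-24)
        assert v == pytest.approx(2 / 3)  # 1/3 + 1/3 for a balanced contrast

    def test_blocked_fit_matches_normal_equations(self):
        """Hand-worked 6-unit design with one blocking factor."""
        meta = pd.DataFrame(
            {"grp": list("ABABAB"), "blk": list("XXYYZZ")},
            index=[f"u{i}" for i in range(6)],
        )
        rng = np.random.default_rng(40)
        y = rng.normal(size=(3, 6))
        table, v = fit_blocked_models(_frame(y, meta.index), meta,
                                      DesignSpec("grp", ["blk"]))
        X = np.column_stack([
            np.ones(6),
            (meta["grp"] == "B").to_numpy(float),
            (meta["blk"] == "Y").to_numpy(float),
            (meta["blk"] == "Z").to_numpy(float),
        ])
        XtX_inv = np.linalg.inv(X.T @ X)
        for g in range(3):
            beta = XtX_inv @ X.T @ y[g]
            resid = y[g] - X @ beta
            assert table["effect"].iloc[g] == pytest.approx(beta[1])
            assert table["s2"].iloc[g] == pytest.approx(resid @ resid / 2)
        assert v == pytest.approx(XtX_inv[1, 1])
        assert table["df"].iloc[0] == 2

    def test_confounded_design_errors(self):
        meta = pd.DataFrame(
            {"grp": list("AAABBB"), "donor": list("XXXYYY")},
            index=[f"u{i}" for i in range(6)],
        )
        with pytest.raises(DesignError, match="confounded"):
            build_design(meta, DesignSpec("grp", ["donor"]))

    def test_group_needs_two_units_per_level(self):
        meta = pd.DataFrame({"grp": list("AAAB")}, index=[f"u{i}" for i in range(4)])
        with pytest.raises(DesignError, match="fewer than 2"):
            fit_blocked_models(_frame([[1, 2, 3, 4.0]], meta.index), meta,
                               DesignSpec("grp"))


class TestEmpiricalBayes:
    def test_equal_variances_are_fixed_point(self):
        s2 = np.full(50, 3.0)
        d0, s0_sq, post = empirical_bayes_moderate(s2, 10.0)
        assert s0_sq == pytest.approx(3.0, rel=1e-6)
        np.testing.assert_allclose(post, 3.0, rtol=1e-6)

    def test_prior_recovery_from_scaled_inv_chi2(self):
        """5000 genes with sigma^2 ~ scaled-inv-chi2(d0=4, s0^2=2), observed
        through chi2_10 sampling noise: moments recover the prior."""
        rng = np.random.default_rng(41)
        d = 10
        sigma2 = 4 * 2 / rng.chisquare(4, 5000)
        s2 = sigma2 * rng.chisquare(d, 5000) / d
        d0, s0_sq, _ = empirical_bayes_moderate(s2, float(d))
        assert d0 == pytest.approx(4.0, abs=1.0)
        assert s0_sq == pytest.approx(2.0, rel=0.10)

    def test_moderated_interpolates_between_gene_and_prior(self):
        rng = np.random.default_rng(42)
        s2 = rng.chisquare(5, 200) / 5
        d0, s0_sq, post = empirical_bayes_moderate(s2, 5.0)
        lo = np.minimum(s2, s0_sq) - 1e-12
        hi = np.maximum(s2, s0_sq) + 1e-12
        assert np.all((post >= lo) & (post <= hi))

    def test_all_zero_variances_error(self):
        with pytest.raises(etac.EtacError):
            empirical_bayes_moderate(np.zeros(50), 5.0)


class TestModeratedT:
    def test_d0_zero_equals_classical_t(self):
        """With no shrinkage the moderated t reduces to the ordinary
        two-sample t on residualized data."""
        rng = np.random.default_rng(43)
        meta = pd.DataFrame({"grp": ["A"] * 5 + ["B"] * 5},
                            index=[f"u{i}" for i in range(10)])
        y = rng.normal(size=(40, 10))
        table, v = fit_blocked_models(_frame(y, meta.index), meta, DesignSpec("grp"))
        t, p = moderated_t_test(table["effect"].to_numpy(), table["s2"].to_numpy(),
                                v, table["df"].to_numpy(), d0=0.0)
        for g in range(40):
            ref = scipy.stats.ttest_ind(y[g, 5:], y[g, :5], equal_var=True)
            assert t[g] == pytest.approx(ref.statistic, rel=1e-10)
            assert p[g] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_effect_zero_variance_convention(self):
        t, p = moderated_t_test(np.array([0.0]), np.array([0.0]), 0.5,
                                np.array([4.0]), d0=2.0)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_infinite_d0_uses_prior_only(self):
        t, p = moderated_t_test(np.array([1.0]), np.array([2.0]), 0.5,
                                np.array([4.0]), d0=np.inf)
        expected = 1.0 / np.sqrt(2.0 * 0.5)
        assert t[0] == pytest.approx(expected)
        assert p[0] == pytest.approx(2 * scipy.stats.norm.sf(expected))

    def test_null_calibration_with_blocking(self):
        rng = np.random.default_rng(44)
        n_units, n_genes = 24, 1000
        meta = pd.DataFrame({
            "grp": ["A"] * 12 + ["B"] * 12,
            "donor": [f"d{i % 3}" for i in range(n_units)],
            "plate_col": [f"p{i % 4}" for i in range(n_units)],
        }, index=[f"u{i}" for i in range(n_units)])
        sig2 = 4 * 0.5 / rng.chisquare(4, n_genes)
        y = rng.normal(0, np.sqrt(sig2)[:, None], (n_genes, n_units))
        res = etac.differential_expression(
            _frame(y, meta.index), DesignSpec("grp", ["donor", "plate_col"]),
            meta=meta)
        frac = (res.p < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        assert np.all(res.q >= res.p - 1e-15)


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_ties(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.2)), 0.2)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10))
    def test_matches_exhaustive_definition(self, pvals):
        """q_i = min over j with p_(j) >= p_(i) of m p_(j) / j (capped at 1),
        computed by brute force."""
        p = np.asarray(pvals)
        q = bh_adjust(p)
        m = p.size
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        brute = np.empty(m)
        for i in range(m):
            brute[i] = min(min(m * ranked[j] / (j + 1) for j in range(i, m)), 1.0)
        expected = np.empty(m)
        expected[order] = brute
        np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(45)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestMedianRatioNormalization:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.arange(1, 6)[:, None], (1, 3))
        cm = etac.CountMatrix([f"g{i}" for i in range(5)], list("abc"), counts)
        np.testing.assert_allclose(etac.median_ratio_size_factors(cm).factors, 1.0)

    def test_three_fold_sample(self):
        rng = np.random.default_rng(46)
        base = rng.integers(3, 60, size=30)
        cm = etac.CountMatrix([f"g{i}" for i in range(30)], ["a", "b"],
                              np.column_stack([base, 3 * base]))
        factors = etac.median_ratio_size_factors(cm).factors
        assert factors[1] / factors[0] == pytest.approx(3.0, rel=1e-12)

    def test_hand_worked_medians(self):
        counts = np.array([[2, 4, 8], [3, 6, 12], [10, 10, 10], [1, 2, 4]])
        cm = etac.CountMatrix(list("wxyz"), list("abc"), counts)
        geo = np.exp(np.log(counts).mean(axis=1))
        expected = np.median(counts / geo[:, None], axis=0)
        np.testing.assert_allclose(etac.median_ratio_size_factors(cm).factors,
                                   expected)

    def test_no_reference_gene(self):
        cm = etac.CountMatrix(["g1", "g2"], ["a", "b"], np.array([[1, 0], [0, 1]]))
        with pytest.raises(NoReferenceGeneError):
            etac.median_ratio_size_factors(cm)


class TestDownsampling:
    def test_exact_target_and_pass_through(self):
        rng = np.random.default_rng(47)
        counts = rng.integers(0, 50, size=(30, 3))
        counts[:, 2] = 0
        counts[0, 2] = 5  # unit below target passes through
        cm = etac.CountMatrix([f"g{i}" for i in range(30)], list("abc"), counts)
        target = 100
        out = etac.downsample_counts(cm, target, seed=1)
        sums = out.counts.sum(axis=0)
        assert sums[0] == target and sums[1] == target
        np.testing.assert_array_equal(out.counts[:, 2], counts[:, 2])

    def test_target_equal_to_total_is_identity(self):
        cm = etac.CountMatrix(["g1", "g2"], ["a"], np.array([[4], [6]]))
        out = etac.downsample_counts(cm, 10, seed=3)
        np.testing.assert_array_equal(out.counts, cm.counts)

    def test_target_zero(self):
        cm = etac.CountMatrix(["g1", "g2"], ["a"], np.array([[4], [6]]))
        assert etac.downsample_counts(cm, 0, seed=3).counts.sum() == 0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(48)
        cm = etac.CountMatrix([f"g{i}" for i in range(20)], ["a"],
                              rng.integers(0, 100, size=(20, 1)))
        a = etac.downsample_counts(cm, 200, seed=9).counts
        b = etac.downsample_counts(cm, 200, seed=9).counts
        np.testing.assert_array_equal(a, b)

    def test_split_draw_matches_single_draw_moments(self):
        """Drawing t1 then t2 from the remainder and summing has the same
        first moments as one draw of t1 + t2."""
        cm = etac.CountMatrix(["g1", "g2", "g3"], ["u"],
                              np.array([[8], [12], [20]]))
        t1, t2 = 10, 15
        split, single = [], []
        for seed in range(800):
            d1 = etac.downsample_counts(cm, t1, seed=seed)
            remainder = etac.CountMatrix(cm.gene_ids, cm.unit_ids,
                                         cm.counts - d1.counts)
            d2 = etac.downsample_counts(remainder, t2, seed=seed + 100_000)
            split.append(d1.counts[:, 0] + d2.counts[:, 0])
            single.append(etac.downsample_counts(cm, t1 + t2, seed=seed).counts[:, 0])
        split, single = np.array(split), np.array(single)
        # hypergeometric mean per gene: (t1+t2) * n_g / total
        expected = (t1 + t2) * cm.counts[:, 0] / cm.counts.sum()
        se = split.std(axis=0, ddof=1) / np.sqrt(len(split))
        np.testing.assert_allclose(split.mean(axis=0), expected, atol=4 * se.max())
        np.testing.assert_allclose(single.mean(axis=0), expected, atol=4 * se.max())
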