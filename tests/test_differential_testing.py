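"""Differential testing: t/F statistics, BH/Holm, selection and phasing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cumulostrat import (
    FeatureSelection,
    bh_fdr,
    holm_adjust,
    multi_group_anova,
    phasing_concordance,
    select_features,
    two_group_test,
)

from conftest import make_matrix


def _labels(n_a, n_b):
    return {f"s{j}": ("A" if j < n_a else "B") for j in range(n_a + n_b)}


class TestTwoGroupTest:
    def test_identical_groups_are_null(self):
        m = make_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        res = two_group_test(m, _labels(3, 3))
        row = res.table.iloc[0]
        assert row["statistic"] == 0 and row["p_value"] == 1 and row["effect"] == 0

    def test_hand_computed_pooled_t(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        res = two_group_test(m, _labels(3, 3), reference="A")
        row = res.table.iloc[0]
        assert row["effect"] == pytest.approx(3.0)
        assert row["statistic"] == pytest.approx(3.674234614174767, abs=1e-12)
        assert row["p_value"] == pytest.approx(0.021311641128756713, abs=1e-12)

    def test_zero_variance_unequal_means_is_degenerate(self):
        m = make_matrix([[1.0, 1.0, 2.0, 2.0]])
        res = two_group_test(m, _labels(2, 2))
        row = res.table.iloc[0]
        assert bool(row["degenerate"]) and row["p_value"] > 0

    def test_single_sample_group_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match=">=2"):
            two_group_test(m, _labels(1, 2))

    def test_direction_follows_effect_sign(self):
        m = make_matrix([[0.0, 0.1, 5.0, 5.2], [5.0, 5.2, 0.0, 0.1]])
        res = two_group_test(m, _labels(2, 2), reference="A")
        assert list(res.table["direction"]) == ["up", "down"]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 5), st.integers(2, 5))
    def test_agrees_with_scipy_pooled_t(self, seed, n_a, n_b):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, n_a + n_b))
        res = two_group_test(make_matrix(X), _labels(n_a, n_b), reference="A")
        t_ref, p_ref = stats.ttest_ind(X[:, n_a:], X[:, :n_a], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["statistic"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p_value"], p_ref, atol=1e-10)

    def test_welch_agrees_with_scipy(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 9))
        res = two_group_test(make_matrix(X), _labels(4, 5), reference="A", welch=True)
        t_ref, p_ref = stats.ttest_ind(X[:, 4:], X[:, :4], axis=1, equal_var=False)
        np.testing.assert_allclose(res.table["statistic"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p_value"], p_ref, atol=1e-10)


class TestAnova:
    def test_equal_group_means_are_null(self):
        m = make_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        groups = {f"s{j}": f"g{j // 3}" for j in range(9)}
        res = multi_group_anova(m, groups)
        assert res.table.iloc[0]["statistic"] == pytest.approx(0.0)

    def test_hand_computed_f(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        groups = {f"s{j}": f"g{j // 2}" for j in range(6)}
        res = multi_group_anova(m, groups)
        assert res.table.iloc[0]["statistic"] == pytest.approx(16.0, abs=1e-12)
        assert res.table.iloc[0]["p_value"] == pytest.approx(
            stats.f.sf(16.0, 2, 3), abs=1e-12
        )

    def test_two_levels_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="two_group_test"):
            multi_group_anova(m, _labels(2, 2))

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(8, 9))
        groups = {f"s{j}": f"g{j // 3}" for j in range(9)}
        res = multi_group_anova(make_matrix(X), groups)
        f_ref, p_ref = stats.f_oneway(X[:, :3], X[:, 3:6], X[:, 6:], axis=1)
        np.testing.assert_allclose(res.table["statistic"], f_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p_value"], p_ref, atol=1e-10)


def _bh_oracle(p):
    """Direct step-up formula: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _holm_oracle(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestMultipleTesting:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_uniformly_spaced_ps_collapse(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12)

    def test_holm_two_ps(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04], atol=1e-12)

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0], [1.5], [-0.1]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=30))
    def test_bh_and_holm_match_direct_formulas(self, ps):
        np.testing.assert_allclose(bh_fdr(ps), _bh_oracle(ps), atol=1e-10)
        np.testing.assert_allclose(holm_adjust(ps), _holm_oracle(ps), atol=1e-10)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bh_is_permutation_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, size=17)
        perm = rng.permutation(17)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)


class TestSelectionAndPhasing:
    def test_all_null_ps_select_nothing(self):
        m = make_matrix([[1.0, 2.0, 1.0, 2.0]])
        res = two_group_test(m, _labels(2, 2))
        assert len(select_features(res, "p", 0.05)) == 0

    def test_known_survivors(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 10))
        X[:5, 5:] += 8.0  # five planted features
        res = two_group_test(make_matrix(X), _labels(5, 5), reference="A")
        manual = set(res.table.index[res.table["p_value"] < 1e-4])
        sel = select_features(res, "p", 1e-4)
        assert sel.features == manual
        assert sel.up >= {f"f{i}" for i in range(5)} or manual == sel.features

    def test_q_rule_never_selects_superset_of_p_rule(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(100, 8))
        res = two_group_test(make_matrix(X), _labels(4, 4))
        sel_p = select_features(res, "p", 0.05)
        sel_q = select_features(res, "q", 0.05)
        assert sel_q.features <= sel_p.features

    def test_phasing_counts_on_fixed_sets(self):
        a = FeatureSelection(up={"g1", "g2"}, down={"g3"}, rule="p", alpha=0.05)
        b = FeatureSelection(up={"g1"}, down={"g3", "g4"}, rule="p", alpha=0.05)
        s = phasing_concordance(a, b)
        assert (s.concordant_up, s.concordant_down, s.cross_phase) == (1, 1, 0)
        assert s.intersection == 2

    def test_disjoint_selections_all_zero(self):
        a = FeatureSelection(up={"g1"}, down={"g2"}, rule="p", alpha=0.05)
        b = FeatureSelection(up={"g3"}, down={"g4"}, rule="p", alpha=0.05)
        s = phasing_concordance(a, b)
        assert s.intersection == 0 and s.only_a == 2 and s.only_b == 2

    def test_random_directions_balance_cross_and_concordant(self):
        rng = np.random.default_rng(19)
        genes = [f"g{i}" for i in range(2000)]
        a_up = set(genes[:1000])
        a_down = set(genes[1000:])
        flips = rng.random(2000) < 0.5
        b_up = {g for g, f in zip(genes, flips) if f}
        b_down = {g for g, f in zip(genes, flips) if not f}
        s = phasing_concordance(
            FeatureSelection(a_up, a_down, "p", 0.05),
            FeatureSelection(b_up, b_down, "p", 0.05),
        )
        # under random phasing, concordant ~ Binomial(2000, 1/2)
        p = stats.binomtest(s.concordant, s.intersection, 0.5).pvalue
        assert p > 0.001
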