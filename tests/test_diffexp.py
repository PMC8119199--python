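import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from senesig.datatypes import BulkExpressionMatrix
from senesig.diffexp import (
    DEOptions,
    adjust_pvalues,
    de_two_group,
    log2_transform,
    squeeze_variances,
)
from senesig.simulate import BulkSimConfig, ContrastConfig, simulate_bulk


def bulk_from_array(arr, n_treated, n_control, scale="log2"):
    n = n_treated + n_control
    cols = [f"t{i}" for i in range(n_treated)] + [f"c{i}" for i in range(n_control)]
    groups = {c: ("senescent" if i < n_treated else "control") for i, c in enumerate(cols)}
    values = pd.DataFrame(np.asarray(arr, dtype=float), columns=cols)
    values.index = [f"g{i}" for i in range(values.shape[0])]
    return BulkExpressionMatrix(values=values, scale=scale, sample_groups=groups)


class TestLog2Transform:
    def test_closed_form_at_zero(self, toy_bulk):
        toy_bulk.values.iloc[0, 0] = 0.0
        out = log2_transform(toy_bulk, pseudocount=1e-4)
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(1e-4))
        assert out.scale == "log2"

    def test_zero_pseudocount_rejected(self, toy_bulk):
        with pytest.raises(ValueError, match="pseudocount"):
            log2_transform(toy_bulk, pseudocount=0.0)

    def test_double_transform_rejected(self, toy_bulk):
        with pytest.raises(ValueError, match="already"):
            log2_transform(log2_transform(toy_bulk))

    def test_monotone(self, toy_bulk):
        out = log2_transform(toy_bulk)
        a, b = toy_bulk.values.to_numpy().ravel(), out.values.to_numpy().ravel()
        order = np.argsort(a)
        assert np.all(np.diff(b[order]) >= 0)


class TestTwoGroupContrast:
    def test_matches_brute_force_pooled_t(self):
        """moderation=none p equals a first-principles pooled-variance t."""
        rng = np.random.default_rng(3)
        arr = rng.normal(2.0, 1.0, size=(20, 6))
        m = bulk_from_array(arr, 3, 3)
        res = de_two_group(m, "senescent", "control", DEOptions(moderation="none"))
        for i in range(20):
            x, y = arr[i, :3], arr[i, 3:]
            sp2 = (2 * np.var(x, ddof=1) + 2 * np.var(y, ddof=1)) / 4
            t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
            p = 2 * stats.t.sf(abs(t), df=4)
            assert res.table["p_value"].iloc[i] == pytest.approx(p, abs=1e-10)
            assert res.table["log2_fc"].iloc[i] == pytest.approx(np.mean(x) - np.mean(y), abs=1e-12)
            assert res.table["mean_log2_expr"].iloc[i] == pytest.approx(np.mean(arr[i]), abs=1e-12)

    def test_identical_groups_give_zero_fc_p_one(self):
        arr = np.tile([[1.0, 2.0, 3.0]], (2, 1))
        arr = np.hstack([arr, arr])  # treated == control per gene
        m = bulk_from_array(arr, 3, 3)
        res = de_two_group(m, "senescent", "control", DEOptions(moderation="none"))
        assert (res.table["log2_fc"] == 0).all()

    def test_zero_variance_conventions(self):
        arr = np.array([[1.0, 1, 1, 1, 1, 1], [2.0, 2, 2, 1, 1, 1]])
        m = bulk_from_array(arr, 3, 3)
        with pytest.warns(UserWarning, match="zero variance"):
            res = de_two_group(m, "senescent", "control", DEOptions(moderation="none"))
        assert res.table["p_value"].iloc[0] == 1.0  # no difference, no variance
        assert res.table["p_value"].iloc[1] == 0.0  # difference with zero variance

    def test_swap_groups_negates_fc_keeps_p(self):
        rng = np.random.default_rng(5)
        m = bulk_from_array(rng.normal(size=(10, 8)), 4, 4)
        a = de_two_group(m, "senescent", "control")
        b = de_two_group(m, "control", "senescent")
        np.testing.assert_allclose(a.table["log2_fc"], -b.table["log2_fc"], atol=1e-12)
        np.testing.assert_allclose(a.table["p_value"], b.table["p_value"], atol=1e-12)

    def test_small_group_and_unknown_label_rejected(self):
        m = bulk_from_array(np.zeros((3, 4)), 1, 3)
        with pytest.raises(ValueError, match=">= 2 samples"):
            de_two_group(m, "senescent", "control")
        m = bulk_from_array(np.zeros((3, 6)), 3, 3)
        with pytest.raises(ValueError, match="unknown group"):
            de_two_group(m, "senescent", "sick")

    def test_moderated_converges_to_plain_as_n_grows(self):
        """The EB shrinkage weight is d0/(d0 + 2n - 2), so the moderated and
        plain p-values approach each other as replication grows."""
        gaps = []
        for n in (10, 50, 200):
            cfg = BulkSimConfig(
                n_genes=300,
                n_per_group=n,
                contrasts=[ContrastConfig("big", fold_change=2.0, n_private_induced=0)],
                n_shared_induced=30,
                seed=11,
            )
            mats, _ = simulate_bulk(cfg)
            logm = log2_transform(mats["big"])
            p_mod = de_two_group(logm, "senescent", "control", DEOptions(moderation="empirical_bayes"))
            p_plain = de_two_group(logm, "senescent", "control", DEOptions(moderation="none"))
            gaps.append(np.abs(p_mod.table["p_value"] - p_plain.table["p_value"]).max())
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.05


class TestAdjustPvalues:
    def test_bonferroni_identity_and_cap(self):
        np.testing.assert_allclose(adjust_pvalues([0.03], "bonferroni"), [0.03])
        np.testing.assert_allclose(adjust_pvalues([0.6, 0.9], "bonferroni"), [1.0, 1.0])

    def test_bh_matches_step_up_enumeration(self):
        """BH equals min over j >= i of (m/j) p_(j), computed by brute force."""
        p = np.array([0.04, 0.01, 0.03, 0.02])
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for rank_i, idx in enumerate(order):
            candidates = [m / (rank_j + 1) * p[order[rank_j]] for rank_j in range(rank_i, m)]
            expected[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(adjust_pvalues(p, "bh"), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")
        with pytest.raises(ValueError):
            adjust_pvalues([-0.1], "bonferroni")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_bonferroni_dominates_bh(self, p):
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        assert np.all(bonf >= bh - 1e-12)
        assert np.all((bh >= np.asarray(p) - 1e-12) & (bh <= 1.0))


def test_variance_squeeze_pulls_toward_prior():
    rng = np.random.default_rng(1)
    s2 = stats.chi2.rvs(6, size=500, random_state=rng) / 6 * 0.25
    s2_tilde, d0, s0 = squeeze_variances(s2, df=6)
    assert s0 == pytest.approx(0.25, rel=0.2)
    # shrinkage: moderated variances are strictly less spread out
    assert np.var(np.log(s2_tilde)) < np.var(np.log(s2))
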