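import itertools

import numpy as np
import pandas as pd
import pytest

from senesig.datatypes import CellCountMatrix, ClusterLabels, LogNormMatrix
from senesig.sc_scoring import (
    cell_cycle_phase,
    lognormalize,
    module_score,
    qc_filter,
    score_clusters,
)

from conftest import signature


class TestQCFilter:
    def test_survivors_match_hand_enumeration(self, toy_counts):
        # c0: 5 features ex-mito (6 total) >= min_features=4, mito 1/51 ok -> keep
        # c1: 2 features -> drop; c2: mito 6/96 > 5% -> drop
        # c3: 4 features, 0% mito -> keep; c4: 6 features, 2/102 mito -> keep
        filtered, report = qc_filter(toy_counts, min_features=4, max_mito_frac=0.05)
        assert filtered.barcodes == ["c0", "c3", "c4"]
        assert report.n_low_features == 1
        assert report.n_high_mito == 1
        assert report.n_kept == 3

    def test_feature_boundary_is_inclusive(self):
        counts = np.zeros((2, 600), dtype=int)
        counts[0, :499] = 1
        counts[1, :500] = 1
        m = CellCountMatrix(
            barcodes=["low", "edge"], gene_ids=[f"g{i}" for i in range(600)], counts=counts
        )
        with pytest.warns(UserWarning, match="vacuously"):
            filtered, _ = qc_filter(m)
        assert filtered.barcodes == ["edge"]

    def test_mito_fraction_boundary(self):
        genes = ["MT-1"] + [f"g{i}" for i in range(9)]
        counts = np.ones((2, 10), dtype=int) * 100
        counts[0, 0] = 60   # 60/960 ~ 6.2% mito
        counts[1, 0] = 40   # 40/940 ~ 4.3% mito
        m = CellCountMatrix(barcodes=["hi", "lo"], gene_ids=genes, counts=counts)
        filtered, report = qc_filter(m, min_features=5)
        assert filtered.barcodes == ["lo"]
        assert report.n_high_mito == 1


class TestLognormalize:
    def test_closed_form(self):
        counts = np.array([[0, 3, 9997]])
        m = CellCountMatrix(barcodes=["c"], gene_ids=["a", "b", "c"], counts=counts)
        ln = lognormalize(m, scale_factor=1e4)  # total equals scale_factor
        assert ln.values[0, 0] == 0.0
        assert ln.values[0, 1] == pytest.approx(np.log(4.0))

    def test_monotone_within_cell(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(5, 50)) + 1
        m = CellCountMatrix(
            barcodes=[f"c{i}" for i in range(5)], gene_ids=[f"g{i}" for i in range(50)], counts=counts
        )
        ln = lognormalize(m)
        for i in range(5):
            order = np.argsort(counts[i])
            assert np.all(np.diff(ln.values[i][order]) >= 0)

    def test_zero_total_cell_rejected(self):
        m = CellCountMatrix(barcodes=["a", "b"], gene_ids=["g"], counts=np.array([[0], [2]]))
        with pytest.raises(ValueError, match="qc_filter"):
            lognormalize(m)


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        values = np.full((3, 30), 1.7)
        ln = LogNormMatrix(
            barcodes=["a", "b", "c"], gene_ids=[f"g{i}" for i in range(30)], values=values
        )
        for mode in ("uniform", "binned"):
            res = module_score(ln, signature("g0", "g1", "g2"), n_control=5, seed=9, ctrl_mode=mode)
            np.testing.assert_allclose(res.scores, 0.0, atol=1e-12)

    def test_cell_level_shift_invariance(self, toy_lognorm):
        sig = signature("g0", "g1", "g2")
        base = module_score(toy_lognorm, sig, n_control=6, seed=3)
        shifted = LogNormMatrix(
            barcodes=toy_lognorm.barcodes,
            gene_ids=toy_lognorm.gene_ids,
            values=toy_lognorm.values + np.array([[0.5], [0.0], [1.0], [0.0]]),
        )
        res = module_score(shifted, sig, n_control=6, seed=3)
        np.testing.assert_allclose(res.scores, base.scores, atol=1e-12)

    def test_hand_computed_scores_on_toy(self, toy_lognorm):
        """Scores equal plain-python mean differences using the reported control draw."""
        sig = signature("g1", "g4", "g7")
        res = module_score(toy_lognorm, sig, n_control=5, seed=11)
        assert len(res.control_genes_used) == 5
        assert set(res.control_genes_used).isdisjoint(sig.genes)
        gi = {g: j for j, g in enumerate(toy_lognorm.gene_ids)}
        for i, bc in enumerate(toy_lognorm.barcodes):
            sig_mean = sum(toy_lognorm.values[i, gi[g]] for g in sig.genes) / 3
            ctrl_mean = sum(toy_lognorm.values[i, gi[g]] for g in res.control_genes_used) / 5
            assert res.scores[bc] == pytest.approx(sig_mean - ctrl_mean, abs=1e-12)

    def test_same_seed_reproduces_draw(self, toy_lognorm):
        a = module_score(toy_lognorm, signature("g0"), n_control=4, seed=2)
        b = module_score(toy_lognorm, signature("g0"), n_control=4, seed=2)
        assert a.control_genes_used == b.control_genes_used
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_missing_genes_warn_and_all_missing_errors(self, toy_lognorm):
        with pytest.warns(UserWarning, match="absent"):
            res = module_score(toy_lognorm, signature("g0", "nope"), n_control=4, seed=0)
        assert res.dropped_signature_genes == ["nope"]
        with pytest.warns(UserWarning, match="absent"), pytest.raises(ValueError, match="no gene"):
            module_score(toy_lognorm, signature("none1", "none2"), n_control=4, seed=0)

    def test_control_pool_exhaustion_rejected(self, toy_lognorm):
        with pytest.raises(ValueError, match="n_control"):
            module_score(toy_lognorm, signature("g0"), n_control=50, seed=0)

    def test_binned_controls_match_signature_bins(self, toy_lognorm):
        sig = signature("g2", "g9")
        res = module_score(toy_lognorm, sig, n_control=2, seed=4, ctrl_mode="binned")
        assert res.ctrl_mode == "binned"
        assert len(res.control_genes_used) == 4  # 2 per signature gene
        assert set(res.control_genes_used).isdisjoint(sig.genes)


class TestScoreClusters:
    def make_scores(self, values, barcodes=None):
        barcodes = barcodes or [f"c{i}" for i in range(len(values))]
        from senesig.sc_scoring import ModuleScoreResult

        return ModuleScoreResult(
            signature_name="s",
            scores=pd.Series(values, index=barcodes),
            n_control=10,
            seed=0,
            ctrl_mode="uniform",
            control_genes_used=[],
        )

    def test_all_ties_give_p_one(self, two_cluster_labels):
        summ = score_clusters(self.make_scores([1.0] * 10), two_cluster_labels)
        assert (summ.table["p"] == 1.0).all()

    def test_relabeling_permutes_rows_not_values(self, two_cluster_labels):
        rng = np.random.default_rng(8)
        scores = self.make_scores(rng.normal(size=10))
        summ = score_clusters(scores, two_cluster_labels)
        swapped = ClusterLabels({b: {"A": "B", "B": "A"}[c] for b, c in two_cluster_labels.labels.items()})
        summ2 = score_clusters(scores, swapped)
        pd.testing.assert_frame_equal(
            summ.table.rename(index={"A": "B", "B": "A"}).sort_index(), summ2.table.sort_index()
        )

    def test_exact_rank_sum_against_enumeration(self, two_cluster_labels):
        """5v5 one-sided p equals brute-force enumeration over all C(10,5) splits."""
        from scipy.stats import rankdata

        vals = np.array([3.1, 2.9, 2.5, 1.8, 2.2, 1.0, 1.2, 0.8, 2.0, 0.9])
        summ = score_clusters(self.make_scores(list(vals)), two_cluster_labels)
        ranks = rankdata(vals)
        w_obs = ranks[:5].sum()
        hits = total = 0
        for combo in itertools.combinations(range(10), 5):
            total += 1
            if ranks[list(combo)].sum() >= w_obs - 1e-12:
                hits += 1
        assert summ.table.loc["A", "p"] == pytest.approx(hits / total, abs=1e-10)

    def test_small_cluster_gets_nan_p(self):
        labels = ClusterLabels({"c0": "tiny", "c1": "tiny", "c2": "big", "c3": "big", "c4": "big"})
        with pytest.warns(UserWarning, match="< 3"):
            summ = score_clusters(self.make_scores([1.0, 2.0, 0.5, 0.6, 0.4]), labels)
        assert np.isnan(summ.table.loc["tiny", "p"])
        assert np.isfinite(summ.table.loc["big", "q"])

    def test_subject_means_pivot(self, two_cluster_labels):
        scores = self.make_scores(list(np.arange(10.0)))
        summ = score_clusters(scores, two_cluster_labels, subject_ids=["s1", "s2"] * 5)
        assert summ.subject_means.shape == (2, 2)
        # subject s1 holds cells 0,2,4 in A and 6,8 in B
        assert summ.subject_means.loc["s1", "A"] == pytest.approx(np.mean([0.0, 2.0, 4.0]))


class TestCellCyclePhase:
    def make_lognorm(self, values, genes):
        return LogNormMatrix(
            barcodes=[f"c{i}" for i in range(values.shape[0])], gene_ids=genes, values=values
        )

    def test_silent_phase_genes_force_g1(self):
        genes = ["s1", "s2", "m1", "m2"] + [f"g{i}" for i in range(20)]
        values = np.hstack([np.zeros((3, 4)), np.full((3, 20), 2.0)])
        ln = self.make_lognorm(values, genes)
        calls = cell_cycle_phase(
            ln, signature("s1", "s2", name="S"), signature("m1", "m2", name="G2M"), n_control=10, seed=0
        )
        assert (calls.table["phase"] == "G1").all()
        assert (calls.table["s_score"] < 0).all()

    def test_duplicated_cells_get_identical_phase(self):
        rng = np.random.default_rng(2)
        genes = ["s1", "s2", "m1", "m2"] + [f"g{i}" for i in range(20)]
        row = rng.uniform(0, 2, size=(1, 24))
        ln = self.make_lognorm(np.vstack([row, row, row]), genes)
        calls = cell_cycle_phase(
            ln, signature("s1", "s2", name="S"), signature("m1", "m2", name="G2M"), n_control=10, seed=5
        )
        assert calls.table["phase"].nunique() == 1

    def test_entirely_absent_list_rejected(self, toy_lognorm):
        with pytest.raises(ValueError, match="G2M marker"):
            cell_cycle_phase(
                toy_lognorm, signature("g0", name="S"), signature("zz", name="G2M"), n_control=4, seed=0
            )
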