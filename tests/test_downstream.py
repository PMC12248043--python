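import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grnvae as gv
from grnvae.downstream import ranksum_p, rescaled_lfc
from grnvae.training import CellTypeGRNSet
from grnvae.ulm import TFActivityMatrix


def _acts(values, tf_ids=None):
    values = np.asarray(values, float)
    tf_ids = tf_ids or [f"T{i}" for i in range(values.shape[1])]
    return TFActivityMatrix(values, [f"c{i}" for i in range(values.shape[0])],
                            tf_ids, source="model")


class TestDifferentialActivity:
    def test_identical_groups_excluded(self):
        rng = np.random.default_rng(0)
        pattern = rng.normal(size=20)
        acts = _acts(np.concatenate([pattern, pattern])[:, None])
        labels = ["a"] * 20 + ["b"] * 20
        table = gv.differential_tf_activity(acts, labels, p_threshold=0.05)
        assert table.empty  # p ~ 1 for a TF identical across groups

    def test_perfect_separation_exact_p(self):
        # 10 vs 10 with no ties: minimal two-sided exact rank-sum p = 2/C(20,10)
        vals = np.concatenate([np.arange(10) + 100.0, np.arange(10)])
        acts = _acts(vals[:, None])
        labels = ["hi"] * 10 + ["lo"] * 10
        table = gv.differential_tf_activity(acts, labels, p_threshold=1.1)
        expected = 2.0 / math.comb(20, 10)
        got = table[table.cell_type == "hi"].iloc[0]["p"]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_lfc_arithmetic(self):
        assert rescaled_lfc(np.array([0.5]), np.array([0.25])) == pytest.approx(1.0)
        assert rescaled_lfc(np.array([0.25]), np.array([0.5])) == pytest.approx(-1.0)

    def test_sorted_by_lfc_within_type(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(60, 4))
        base[:30, 0] += 3
        base[:30, 1] += 1.5
        base[30:, 2] += 2
        acts = _acts(base)
        labels = ["x"] * 30 + ["y"] * 30
        table = gv.differential_tf_activity(acts, labels)
        for _, sub in table.groupby("cell_type"):
            lfcs = sub["lfc"].to_numpy()
            assert (np.diff(lfcs) <= 1e-12).all()

    def test_padj_ge_p(self):
        rng = np.random.default_rng(2)
        acts = _acts(rng.normal(size=(40, 6)) + np.array([2, 0, 0, 0, 0, 0]) *
                     np.array([1] * 20 + [0] * 20)[:, None])
        labels = ["a"] * 20 + ["b"] * 20
        table = gv.differential_tf_activity(acts, labels, p_threshold=1.1)
        assert (table["p_adj"] >= table["p"] - 1e-15).all()

    def test_small_group_warned(self):
        acts = _acts(np.random.default_rng(3).normal(size=(23, 2)))
        labels = ["a"] * 20 + ["b"] * 3 + []
        labels[-1] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            gv.differential_tf_activity(acts, labels, p_threshold=1.1)

    def test_permuted_labels_uniform_p(self):
        # KS check: with random labels, p-values should be ~ Uniform(0,1)
        rng = np.random.default_rng(4)
        acts = _acts(rng.normal(size=(200, 40)))
        labels = rng.permutation(["a"] * 100 + ["b"] * 100)
        table = gv.differential_tf_activity(acts, labels, p_threshold=1.1)
        from scipy import stats

        ks = stats.kstest(table[table.cell_type == "a"]["p"], "uniform")
        assert ks.pvalue > 0.01


class TestCosine:
    def test_identity(self):
        v = np.array([1.0, 2.0, -3.0])
        assert gv.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert gv.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert gv.cosine_similarity([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            gv.cosine_similarity([0, 0], [1, 1])

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8),
           st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_scale_invariant(self, v, c):
        v = np.asarray(v)
        if np.linalg.norm(v) == 0:
            return
        w = v[::-1].copy()
        if np.linalg.norm(w) == 0:
            return
        s = gv.cosine_similarity(v, w)
        assert -1.0 <= s <= 1.0
        assert gv.cosine_similarity(c * v, w) == pytest.approx(s, abs=1e-9)
        assert gv.cosine_similarity(w, v) == pytest.approx(s, abs=1e-12)


def _grnset(contexts, weights):
    grns = {ct: gv.WeightedGRN([f"T{i}" for i in range(w.shape[0])],
                               [f"g{j}" for j in range(w.shape[1])], w, ct)
            for ct, w in zip(contexts, weights)}
    return CellTypeGRNSet(grns, {})


def _da_table(rows):
    return pd.DataFrame(rows, columns=["tf", "cell_type", "lfc", "mean_diff",
                                       "p", "p_adj"])


class TestCoregulatoryNetwork:
    def setup_method(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(2, 10))
        self.grns = _grnset(["a", "b"], [w, w.copy()])  # duplicated GRN
        self.da = _da_table([("T0", "a", 2.0, 1.0, 1e-5, 1e-4),
                             ("T1", "a", 1.0, 0.5, 1e-4, 1e-3),
                             ("T0", "b", 2.0, 1.0, 1e-5, 1e-4),
                             ("T1", "b", 1.0, 0.5, 1e-4, 1e-3)])

    def test_unattainable_threshold_empty(self):
        edges = gv.coregulatory_network(self.grns, self.da, 5, 1.0 + 1e-9)
        assert edges.empty

    def test_duplicated_grn_self_similarity(self):
        edges = gv.coregulatory_network(self.grns, self.da, 5, 0.999)
        cross = edges[(edges.tf1 == edges.tf2)
                      & (edges.cell_type1 != edges.cell_type2)]
        assert len(cross) == 2  # T0 and T1 pair with themselves across types
        np.testing.assert_allclose(cross.similarity, 1.0)

    def test_each_unordered_pair_once(self):
        edges = gv.coregulatory_network(self.grns, self.da, 5, -1.0)
        keys = {frozenset([(r.tf1, r.cell_type1), (r.tf2, r.cell_type2)])
                for r in edges.itertuples()}
        assert len(keys) == len(edges)
        n_nodes = 4
        assert len(edges) == n_nodes * (n_nodes - 1) // 2

    def test_empty_da_rejected(self):
        with pytest.raises(ValueError):
            gv.coregulatory_network(self.grns, self.da.iloc[0:0], 5, 0.5)


class TestGRNCorrelationClustering:
    def test_self_correlation_diagonal(self):
        rng = np.random.default_rng(6)
        gs = _grnset(["a", "b"], [rng.normal(size=(3, 8)),
                                  rng.normal(size=(3, 8))])
        corr, _ = gv.grn_correlation_clustering(gs)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(7)
        w = rng.normal(size=(3, 8))
        gs = _grnset(["a", "b"], [w, 2.0 * w])
        corr, _ = gv.grn_correlation_clustering(gs)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_leaf_order_groups_shared_support(self):
        rng = np.random.default_rng(8)
        base = np.zeros((2, 20))
        base[:, :10] = np.abs(rng.normal(2.0, 0.1, size=(2, 10)))
        a = base + rng.normal(0, 0.05, base.shape)
        b = base + rng.normal(0, 0.05, base.shape)
        c = np.zeros((2, 20))
        c[:, 10:] = np.abs(rng.normal(2.0, 0.1, size=(2, 10)))
        corr, order = gv.grn_correlation_clustering(_grnset(["A", "B", "C"],
                                                            [a, b, c]))
        assert abs(order.index("A") - order.index("B")) == 1  # A,B adjacent

    def test_constant_grn_rejected(self):
        gs = _grnset(["a", "b"], [np.ones((2, 4)),
                                  np.random.default_rng(9).normal(size=(2, 4))])
        with pytest.raises(ValueError, match="'a'"):
            gv.grn_correlation_clustering(gs)


class TestEnrichment:
    def _grn(self, n_genes=400):
        rng = np.random.default_rng(10)
        w = rng.normal(size=(1, n_genes))
        return gv.WeightedGRN(["T0"], [f"g{j}" for j in range(n_genes)], w)

    def test_perfect_overlap_smallest_p(self):
        grn = self._grn()
        order = np.argsort(-grn.weights[0])
        top = [grn.gene_ids[j] for j in order[:4]]  # top 1% of 400
        table = gv.top_targets_enrichment(grn, "T0", {"hit": top, "miss":
                                                      [grn.gene_ids[j] for j in order[-4:]]})
        hit = table[table.gene_set == "hit"].iloc[0]
        from scipy import stats

        assert hit["p"] == pytest.approx(
            float(stats.hypergeom.sf(3, 400, 4, 4)), rel=1e-12)
        assert hit["p"] == table["p"].min()

    def test_zero_overlap_p_one(self):
        grn = self._grn()
        order = np.argsort(-grn.weights[0])
        bottom = [grn.gene_ids[j] for j in order[-10:]]
        table = gv.top_targets_enrichment(grn, "T0", {"none": bottom})
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_hand_enumeration_oracle(self):
        # universe 4 genes, top 2, set of 2 overlapping once:
        # P(X >= 1) = 1 - C(2,0)C(2,2)/C(4,2) = 1 - 1/6 = 5/6
        w = np.array([[4.0, 3.0, 2.0, 1.0]])
        grn = gv.WeightedGRN(["T0"], ["g0", "g1", "g2", "g3"], w)
        table = gv.top_targets_enrichment(grn, "T0", {"s": ["g0", "g2"]},
                                          top_fraction=0.5)
        assert table.iloc[0]["p"] == pytest.approx(5 / 6, rel=1e-12)

    def test_disjoint_set_skipped(self):
        grn = self._grn()
        with pytest.warns(UserWarning, match="alien"):
            table = gv.top_targets_enrichment(
                grn, "T0", {"alien": ["zz1", "zz2"],
                            "ok": [grn.gene_ids[0]]})
        assert "alien" not in set(table.gene_set)

    def test_unknown_tf(self):
        with pytest.raises(KeyError):
            gv.top_targets_enrichment(self._grn(), "NOPE", {"s": ["g0"]})

    def test_rank_by_abs_flag(self):
        w = np.array([[-10.0, 5.0, 1.0, 0.5]])
        grn = gv.WeightedGRN(["T0"], ["g0", "g1", "g2", "g3"], w)
        signed = gv.top_targets_enrichment(grn, "T0", {"s": ["g0"]},
                                           top_fraction=0.25)
        by_abs = gv.top_targets_enrichment(grn, "T0", {"s": ["g0"]},
                                           top_fraction=0.25, rank_by_abs=True)
        assert signed.iloc[0]["overlap"] == 0
        assert by_abs.iloc[0]["overlap"] == 1


def test_read_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\n")
    sets = gv.read_gmt(p)
    assert sets["setA"] == ["g1", "g2", "g3"]
    assert sets["setB"] == ["g4"]
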