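from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bcrforest as bf
from bcrforest.plm import AMINO_ACIDS
from oracles import loop_pseudolikelihood, spearman_manual


def _aligned_tree_with_scores(seed=1):
    """Simulated lineage + stand-in likelihoods keyed by node."""
    cfg = bf.SimulationConfig(seed=seed)
    _, truth = bf.simulate_lineage(cfg)
    ct = bf.observed_clonotype(truth)
    tree = bf.build_tree(ct)
    aln = {"germline": truth.tree.graph.nodes["germline"]["sequence_aa"]}
    for v in ct.variants:
        aln[v.variant_id] = v.sequence_aa
    scores = bf.standin_scorer(aln)
    return tree, aln, scores


class TestPseudolikelihood:
    def test_uniform_matrix(self):
        mat = np.full((7, 20), 1 / 20)
        assert bf.pseudolikelihood("ACDEFGH", mat) == pytest.approx(np.log(1 / 20))

    def test_one_hot_near_zero(self):
        seq = "ACD"
        mat = np.full((3, 20), 1e-12 / 19)
        for i, c in enumerate(seq):
            mat[i, AMINO_ACIDS.index(c)] = 1 - 1e-12
        assert bf.pseudolikelihood(seq, mat) == pytest.approx(0.0, abs=1e-10)

    def test_length_one(self):
        mat = np.zeros((1, 20))
        mat[0, 0] = 0.5
        mat[0, 1:] = 0.5 / 19
        assert bf.pseudolikelihood("A", mat) == pytest.approx(np.log(0.5))

    def test_duplication_invariance(self):
        rng = np.random.default_rng(3)
        mat = rng.dirichlet(np.ones(20), size=6)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=6))
        single = bf.pseudolikelihood(seq, mat)
        doubled = bf.pseudolikelihood(seq * 2, np.vstack([mat, mat]))
        assert doubled == pytest.approx(single, abs=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        mat = rng.dirichlet(np.ones(20), size=100)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=100))
        assert bf.pseudolikelihood(seq, mat) == \
            pytest.approx(loop_pseudolikelihood(seq, mat, AMINO_ACIDS), abs=1e-12)

    def test_alphabet_error(self):
        with pytest.raises(bf.AlphabetError):
            bf.pseudolikelihood("Z", np.full((1, 20), 1 / 20))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_always_nonpositive(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.dirichlet(np.ones(20), size=5)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=5))
        assert bf.pseudolikelihood(seq, mat) <= 0.0


class TestStandinScorer:
    def test_single_sequence_smoothing(self):
        out = bf.standin_scorer({"germline": "A"})
        row = out["germline"].matrix[0]
        assert row[AMINO_ACIDS.index("A")] == pytest.approx(2 / 21)
        assert row[AMINO_ACIDS.index("C")] == pytest.approx(1 / 21)

    def test_conserved_column_twenty_sequences(self):
        aln = {f"v{i}": "A" for i in range(20)}
        out = bf.standin_scorer(aln)
        assert out["v0"].matrix[0, AMINO_ACIDS.index("A")] == pytest.approx(21 / 40)

    def test_rows_sum_to_one(self, sim_truth):
        _, truth = sim_truth
        g = truth.tree.graph
        aln = {n: g.nodes[n]["sequence_aa"] for n in ["germline"] + truth.observed}
        out = bf.standin_scorer(aln)
        for rl in out.values():
            np.testing.assert_allclose(rl.matrix.sum(axis=1), 1.0, atol=1e-12)


class TestLoadLikelihoods:
    def test_roundtrip_and_attachment(self, tmp_path):
        tree, aln, scores = _aligned_tree_with_scores()
        for node, rl in scores.items():
            if node in tree.graph:
                bf.write_likelihood_csv(rl, tmp_path / f"{node}.csv")
        loaded = bf.load_likelihoods(tmp_path, tree)
        assert set(loaded) <= set(tree.graph.nodes)
        for node, rl in loaded.items():
            np.testing.assert_allclose(rl.matrix, scores[node].matrix, atol=1e-9)
            if scores[node].pseudolikelihood is not None:
                assert rl.pseudolikelihood == pytest.approx(scores[node].pseudolikelihood)

    def test_slightly_off_rows_renormalized(self, tmp_path, caplog):
        tree, _, scores = _aligned_tree_with_scores()
        node = next(n for n in scores if n in tree.graph and n != "germline")
        rl = scores[node]
        perturbed = bf.ResidueLikelihoods(node_id=node, matrix=rl.matrix * 1.0005)
        bf.write_likelihood_csv(perturbed, tmp_path / f"{node}.csv")
        with caplog.at_level("WARNING", logger="bcrforest"):
            loaded = bf.load_likelihoods({node: tmp_path / f"{node}.csv"}, tree)
        assert "renormalizing" in caplog.text
        assert loaded[node].row_sums_valid(tol=1e-9)

    def test_badly_off_rows_rejected(self, tmp_path):
        tree, _, scores = _aligned_tree_with_scores()
        node = next(n for n in scores if n in tree.graph)
        bad = bf.ResidueLikelihoods(node_id=node, matrix=scores[node].matrix * 1.5)
        bf.write_likelihood_csv(bad, tmp_path / f"{node}.csv")
        with pytest.raises(ValueError):
            bf.load_likelihoods({node: tmp_path / f"{node}.csv"}, tree)


class TestEdgeProfile:
    def test_identical_parent_child(self):
        seq = AMINO_ACIDS  # one of each residue, no ambiguity
        mat = np.full((len(seq), 20), 1 / 20)
        t = bf.LineageTree.empty("germline", tree_id="x")
        t.graph.nodes["germline"]["sequence_aa"] = seq
        t.add_node("v", kind=bf.SAMPLED, sequence_aa=seq)
        t.add_edge("germline", "v", 0)
        lk = {"germline": bf.ResidueLikelihoods(node_id="germline", matrix=mat),
              "v": bf.ResidueLikelihoods(node_id="v", matrix=mat)}
        df = bf.edge_substitution_profile(t, lk, ("germline", "v"))
        assert (df.klass == "conserved").sum() == len(seq)
        assert (df.klass == "mutated").sum() == 0

    def test_argmax_child_has_rank_one(self):
        L = 5
        rng = np.random.default_rng(6)
        mat = rng.dirichlet(np.ones(20), size=L)
        parent_seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        child_seq = list(parent_seq)
        child_seq[2] = AMINO_ACIDS[int(np.argmax(mat[2]))]
        if child_seq[2] == parent_seq[2]:
            mat[2, (AMINO_ACIDS.index(parent_seq[2]) + 1) % 20] = mat[2].max() + 1
            mat[2] /= mat[2].sum()
            child_seq[2] = AMINO_ACIDS[int(np.argmax(mat[2]))]
        child_seq = "".join(child_seq)
        t = bf.LineageTree.empty("germline")
        t.graph.nodes["germline"]["sequence_aa"] = parent_seq
        t.add_node("v", kind=bf.SAMPLED, sequence_aa=child_seq)
        t.add_edge("germline", "v", 1)
        lk = {"germline": bf.ResidueLikelihoods(node_id="germline", matrix=mat),
              "v": bf.ResidueLikelihoods(node_id="v", matrix=mat)}
        df = bf.edge_substitution_profile(t, lk, ("germline", "v"))
        mutated = df[df.klass == "mutated"]
        assert len(mutated) == 1
        assert int(mutated.iloc[0].child_rank_in_parent) == 1

    def test_simulated_edges_partition_positions(self):
        tree, aln, scores = _aligned_tree_with_scores()
        lk = {n: scores[n] for n in tree.graph.nodes if n in scores}
        L = len(aln["germline"])
        checked = 0
        for u, v, _ in tree.edges():
            if u in lk and v in lk:
                df = bf.edge_substitution_profile(tree, lk, (u, v))
                counts = df.klass.value_counts()
                assert counts.get("mutated", 0) + counts.get("conserved", 0) \
                    + counts.get("indel", 0) == L
                checked += 1
        assert checked >= 3


class TestLikelihoodVsEvolution:
    def _tree_with_linear_pll(self, slope):
        t = bf.LineageTree.empty("germline")
        lk = {}
        mat = np.full((4, 20), 1 / 20)
        for i in range(1, 6):
            t.add_node(f"v{i}", kind=bf.SAMPLED, sequence_aa="ACDE")
            t.add_edge("germline" if i == 1 else f"v{i-1}", f"v{i}", 1.0)
            rl = bf.ResidueLikelihoods(node_id=f"v{i}", matrix=mat)
            rl.pseudolikelihood = -1.0 + slope * i
            lk[f"v{i}"] = rl
        return t, {t.tree_id: lk}

    def test_linear_gives_perfect_correlation(self):
        t, lk = self._tree_with_linear_pll(slope=-0.1)
        df = bf.likelihood_vs_evolution([t], lk)
        row = df[df.tree_id == t.tree_id].iloc[0]
        assert row.pearson == pytest.approx(-1.0)
        assert row.spearman == pytest.approx(-1.0)

    def test_constant_reports_zero_variance(self):
        t, lk = self._tree_with_linear_pll(slope=0.0)
        df = bf.likelihood_vs_evolution([t], lk)
        row = df[df.tree_id == t.tree_id].iloc[0]
        assert np.isnan(row.spearman)
        assert row.reason == "zero variance"

    def test_too_few_points(self):
        t = bf.LineageTree.empty("germline")
        df = bf.likelihood_vs_evolution([t], {t.tree_id: {}})
        assert df.iloc[0].reason == "fewer than 3 points"

    def test_spearman_matches_rank_oracle(self):
        tree, aln, scores = _aligned_tree_with_scores(seed=2)
        lk = {n: scores[n] for n in tree.graph.nodes if n in scores}
        df = bf.likelihood_vs_evolution([tree], {tree.tree_id: lk})
        row = df[df.tree_id == tree.tree_id].iloc[0]
        x = [tree.path_weight(n) for n in sorted(lk) if tree.kind(n) != bf.INFERRED]
        y = [lk[n].pseudolikelihood for n in sorted(lk) if tree.kind(n) != bf.INFERRED]
        assert row.spearman == pytest.approx(spearman_manual(x, y), abs=1e-12)
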