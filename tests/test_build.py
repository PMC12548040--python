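from __future__ import annotations

import numpy as np
import pytest

import bcrforest as bf
from bcrforest.build import (
    _enumerate_unrooted_topologies, fitch_score, tree_log_likelihood, _encode_bits,
)
from conftest import random_distance_matrix
from oracles import fitch_brute_force, min_spanning_weight


def _clonotype(seqs: dict[str, str], germline: str, counts=None) -> bf.Clonotype:
    counts = counts or {}
    return bf.Clonotype(
        clonotype_id="c", germline_nt=germline,
        variants=[bf.Variant(variant_id=k, sequence_nt=s,
                             cell_count=counts.get(k, 1))
                  for k, s in seqs.items()])


class TestDistances:
    def test_hamming_basic_and_n_rule(self):
        assert bf.hamming("ACGT", "ACGA") == 1
        assert bf.hamming("ANGT", "ACGT") == 0
        assert bf.hamming("ANGT", "ACGT", n_counts_as_mismatch=True) == 1
        with pytest.raises(ValueError):
            bf.hamming("ACG", "ACGT")

    def test_matrix_shape_and_symmetry(self):
        ct = _clonotype({"v1": "ACGA", "v2": "ACTT"}, "ACGT")
        dm = bf.compute_distances(ct, "hamming")
        assert dm.labels[0] == "germline"
        assert dm.get("germline", "v1") == 1
        assert dm.get("v1", "v2") == dm.get("v2", "v1") == 2


class TestBuildDefault:
    def test_single_variant(self):
        ct = _clonotype({"v1": "ACAA"}, "ACGT")
        t = bf.build_default(bf.compute_distances(ct), ct)
        assert list(t.edges()) == [("germline", "v1", 2.0)]

    def test_chain_hand_trace(self):
        # D[G,A]=1, D[G,B]=3, D[A,B]=1: A first, then B under A
        dm = bf.DistanceMatrix(labels=["germline", "A", "B"],
                               values=np.array([[0, 1, 3], [1, 0, 1], [3, 1, 0]], float))
        t = bf.build_default(dm)
        assert set((u, v) for u, v, _ in t.edges()) == {("germline", "A"), ("A", "B")}
        assert t.edge_weight("A", "B") == 1.0

    def test_expansion_tiebreak(self):
        # v1, v2 join first without ties; v3 then ties between them and the
        # expanded parent (v2, 9 cells) must win
        vals = np.array([
            [0, 1, 2, 9],
            [1, 0, 4, 3],
            [2, 4, 0, 3],
            [9, 3, 3, 0]], float)
        dm = bf.DistanceMatrix(labels=["germline", "v1", "v2", "v3"], values=vals)
        ct = bf.Clonotype(clonotype_id="c", germline_nt="AAAA", variants=[
            bf.Variant(variant_id="v1", sequence_nt="AAAT", cell_count=1),
            bf.Variant(variant_id="v2", sequence_nt="AATA", cell_count=9),
            bf.Variant(variant_id="v3", sequence_nt="TTTT", cell_count=1)])
        t = bf.build_default(dm, ct, tie_break="expansion_max")
        assert t.parent("v3") == "v2"

    def test_random_tiebreak_seed_determinism(self):
        rng = np.random.default_rng(3)
        dm = random_distance_matrix(rng, 6, distinct=False)
        t1 = bf.build_default(dm, tie_break="random", seed=42)
        t2 = bf.build_default(dm, tie_break="random", seed=42)
        assert set(t1.edges()) == set(t2.edges())
        with pytest.raises(ValueError):
            bf.build_default(dm, tie_break="random")


class TestBuildMst:
    def test_three_node_enumeration(self):
        dm = bf.DistanceMatrix(labels=["germline", "A", "B"],
                               values=np.array([[0, 1, 5], [1, 0, 2], [5, 2, 0]], float))
        t = bf.build_mst(dm)
        assert set((u, v) for u, v, _ in t.edges()) == {("germline", "A"), ("A", "B")}
        assert t.total_weight() == 3.0

    def test_equal_distances_total(self):
        n, d = 5, 2.0
        vals = np.full((n, n), d)
        np.fill_diagonal(vals, 0.0)
        dm = bf.DistanceMatrix(labels=["germline"] + [f"v{i}" for i in range(1, n)],
                               values=vals)
        assert bf.build_mst(dm).total_weight() == (n - 1) * d

    def test_matches_cayley_enumeration(self):
        for seed in range(3):
            dm = random_distance_matrix(np.random.default_rng(seed), 6)
            assert bf.build_mst(dm).total_weight() == \
                pytest.approx(min_spanning_weight(dm.values), abs=1e-9)

    def test_default_never_beats_mst(self):
        for seed in range(5):
            dm = random_distance_matrix(np.random.default_rng(100 + seed), 7,
                                        distinct=False)
            assert bf.build_default(dm).total_weight() >= \
                bf.build_mst(dm).total_weight() - 1e-9


class TestBuildNj:
    def test_ultrametric_three_taxa_joins_closest(self):
        dm = bf.DistanceMatrix(labels=["germline", "A", "B"],
                               values=np.array([[0, 4, 4], [4, 0, 2], [4, 2, 0]], float))
        t = bf.build_nj(dm)
        # A and B joined first -> both children of the single inferred node
        inf = t.nodes(bf.INFERRED)
        assert len(inf) == 1
        assert sorted(t.children(inf[0])) == ["A", "B"]

    def test_additive_matrix_recovered_exactly(self):
        # build a known 4-taxon tree, derive its additive matrix, rerun NJ
        #      germline -2- x -1- y -3- A ;  x -2- B ; y -1- C  (x,y internal)
        true_paths = {
            ("germline", "B"): 4.0, ("germline", "A"): 6.0, ("germline", "C"): 4.0,
            ("A", "B"): 6.0, ("A", "C"): 4.0, ("B", "C"): 4.0,
        }
        labels = ["germline", "A", "B", "C"]
        vals = np.zeros((4, 4))
        for (a, b), d in true_paths.items():
            i, j = labels.index(a), labels.index(b)
            vals[i, j] = vals[j, i] = d
        t = bf.build_nj(bf.DistanceMatrix(labels=labels, values=vals))
        und = t.graph.to_undirected()
        import networkx as nx
        for (a, b), d in true_paths.items():
            assert nx.shortest_path_length(und, a, b, weight="weight") == \
                pytest.approx(d, abs=1e-9)

    def test_two_variants_fallback_star(self):
        dm = bf.DistanceMatrix(labels=["germline", "A"],
                               values=np.array([[0, 2], [2, 0]], float))
        t = bf.build_nj(dm)
        assert list(t.edges()) == [("germline", "A", 2.0)]

    def test_negative_lengths_clamped(self):
        for seed in range(5):
            dm = random_distance_matrix(np.random.default_rng(200 + seed), 6,
                                        distinct=False)
            t = bf.build_nj(dm)
            assert all(w >= 0 for _, _, w in t.edges())
            assert t.sampled_labels() == set(dm.labels[1:])


class TestParsimony:
    def test_single_variable_site(self):
        aln = {"germline": "A", "v1": "A", "v2": "A", "v3": "T"}
        _, score = bf.build_parsimony(aln)
        assert score == 1

    def test_two_sites_same_split(self):
        aln = {"germline": "AA", "v1": "AA", "v2": "TT", "v3": "TT"}
        tree, score = bf.build_parsimony(aln, bf.BuildConfig(method="mp",
                                                            search="exhaustive"))
        assert score == 2
        # the split {germline,v1} | {v2,v3} is recovered: v2,v3 share a parent
        assert tree.parent("v2") == tree.parent("v3")

    def test_fitch_matches_state_enumeration(self):
        # fixed quartet topology scored independently by brute force
        aln = {"L1": "ACGT", "L2": "ACGA", "L3": "TCGA", "L4": "TCTT"}
        edges = [("L1", "x"), ("L2", "x"), ("x", "y"), ("L3", "y"), ("L4", "y")]
        import networkx as nx
        topo = nx.Graph(edges)
        ours = fitch_score(topo, {k: _encode_bits(v) for k, v in aln.items()})
        brute = fitch_brute_force(edges, aln, ["x", "y"])
        assert ours == brute

    def test_nni_equals_exhaustive_on_simulated_alignments(self):
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            germ = "".join(rng.choice(list("ACGT"), size=30))
            aln = {"germline": germ}
            for i in range(1, 6):
                seq = list(germ)
                for pos in rng.choice(30, size=rng.integers(1, 5), replace=False):
                    seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
                aln[f"v{i}"] = "".join(seq)
            _, s_nni = bf.build_parsimony(aln, bf.BuildConfig(method="mp", search="nni"))
            _, s_ex = bf.build_parsimony(aln, bf.BuildConfig(method="mp",
                                                             search="exhaustive"))
            assert s_nni == s_ex

    def test_edge_weights_sum_to_score(self):
        rng = np.random.default_rng(9)
        germ = "".join(rng.choice(list("ACGT"), size=40))
        aln = {"germline": germ}
        for i in range(1, 5):
            seq = list(germ)
            for pos in rng.choice(40, size=3, replace=False):
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            aln[f"v{i}"] = "".join(seq)
        tree, score = bf.build_parsimony(aln)
        assert sum(w for _, _, w in tree.edges()) >= score  # traceback >= optimum
        assert tree.sampled_labels() == {f"v{i}" for i in range(1, 5)}


class TestMaxLikelihood:
    def test_two_sequence_jc69_closed_form(self):
        germ = "A" * 16
        var = "T" * 3 + "A" * 13            # p = 3/16
        tree, _ = bf.build_ml({"germline": germ, "v1": var})
        expected = -0.75 * np.log(1 - 4 * (3 / 16) / 3)
        assert tree.edge_weight("germline", "v1") == pytest.approx(expected, abs=1e-4)

    def test_identical_sequences_zero_branch(self):
        germ = "ACGTACGT"
        tree, ll = bf.build_ml({"germline": germ, "v1": germ})
        assert tree.edge_weight("germline", "v1") == pytest.approx(0.0, abs=1e-5)
        assert ll == pytest.approx(len(germ) * np.log(0.25), abs=1e-6)

    def test_k80_kappa1_equals_jc69_fixed_tree(self):
        import networkx as nx
        aln = {"germline": "ACGTACGTAC", "v1": "ACGAACGTAC",
               "v2": "TCGTACGTAA", "v3": "ACGTTCGTAC"}
        topo = nx.Graph([("germline", "x"), ("v1", "x"), ("x", "y"),
                         ("v2", "y"), ("v3", "y")])
        lengths = {frozenset(e): 0.07 for e in topo.edges()}
        ll_jc = tree_log_likelihood(topo, aln, lengths, model="JC69")
        ll_k80 = tree_log_likelihood(topo, aln, lengths, model="K80", kappa=1.0)
        assert ll_jc == pytest.approx(ll_k80, abs=1e-9)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            bf.BuildConfig(method="ml", substitution_model="GTR")

    def test_ml_tree_structure(self):
        rng = np.random.default_rng(17)
        germ = "".join(rng.choice(list("ACGT"), size=60))
        aln = {"germline": germ}
        for i in range(1, 5):
            seq = list(germ)
            for pos in rng.choice(60, size=4, replace=False):
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            aln[f"v{i}"] = "".join(seq)
        tree, ll = bf.build_ml(aln)
        assert np.isfinite(ll)
        assert tree.sampled_labels() == {f"v{i}" for i in range(1, 5)}
        assert all(w >= 0 for _, _, w in tree.edges())


class TestBuildTreeDispatch:
    @pytest.mark.parametrize("method", ["default", "mst", "nj", "mp", "ml"])
    def test_sampled_set_matches_variants(self, sim_clonotype, method):
        small = bf.Clonotype(clonotype_id="s", germline_nt=sim_clonotype.germline_nt,
                             variants=sim_clonotype.variants[:5])
        cfg = bf.BuildConfig(method=method)
        t = bf.build_tree(small, cfg)
        t.validate()
        assert t.sampled_labels() == {v.variant_id for v in small.variants}
        assert t.kind(t.root_id) == bf.GERMLINE
        if method in ("default", "mst"):
            assert not t.nodes(bf.INFERRED)
            assert t.n_nodes == len(small.variants) + 1
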