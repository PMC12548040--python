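"""Lineage tree construction from a clonotype.

Five construction routes, all returning a germline-rooted
:class:`~bcrforest.tree.LineageTree`:

``default``
    the iterative minimum-distance algorithm: start from the germline and
    repeatedly attach the out-of-tree variant with the globally smallest
    distance to any in-tree node. Ties are resolved by a configurable
    criterion (breadth/depth of the candidate parent, its mutational load,
    its clonal expansion, or a seeded random draw).
``mst``
    germline-rooted minimum spanning tree of the complete distance graph.
``nj``
    neighbor joining with inferred internal ancestors, negative branch
    lengths clamped to zero (deficit moved to the sibling branch), re-rooted
    on the germline leaf.
``mp``
    maximum parsimony: Fitch small parsimony scored on bit-encoded sites,
    topology optimized by NNI hill-climbing from the NJ start tree, or
    exhaustively for <= 7 leaves.
``ml``
    maximum likelihood under JC69 or K80 (equal base frequencies, no rate
    heterogeneity) by Felsenstein pruning; branch lengths fit one at a time
    by bounded 1-D search, topology by NNI from the NJ start tree.

Distances and alignments are nucleotide by default; the same machinery
applies to amino-acid input via the ``alphabet`` flag on distances.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar

from .io import Clonotype, DistanceMatrix
from .tree import GERMLINE, INFERRED, SAMPLED, LineageTree, TreeError, orient_from_root

TIE_BREAKS = ("breadth", "depth", "mutational_load_min", "mutational_load_max",
              "expansion_max", "expansion_min", "random")


@dataclass
class BuildConfig:
    method: str = "default"
    distance_metric: str = "hamming"
    tie_break: str = "breadth"
    seed: int | None = None
    substitution_model: str = "JC69"
    search: str = "nni"
    n_counts_as_mismatch: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("default", "mst", "nj", "mp", "ml"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.tie_break not in TIE_BREAKS:
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.tie_break == "random" and self.seed is None:
            raise ValueError("tie_break='random' requires a seed")
        if self.substitution_model not in ("JC69", "K80"):
            raise ValueError(f"unknown substitution model {self.substitution_model!r}")


# ---------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------

def hamming(a: str, b: str, n_counts_as_mismatch: bool = False) -> int:
    """Positionwise mismatch count. ``N`` matches any base unless configured
    otherwise (sequencing-uncertainty convention)."""
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths ({len(a)} vs {len(b)})")
    if n_counts_as_mismatch:
        return sum(x != y for x, y in zip(a, b))
    return sum(x != y and x != "N" and y != "N" for x, y in zip(a, b))


def levenshtein(a: str, b: str, n_counts_as_mismatch: bool = False) -> int:
    """Edit distance (edlib); ``N`` is treated as a wildcard by default."""
    if not a or not b:
        return max(len(a), len(b))
    eq = [] if n_counts_as_mismatch else [("N", c) for c in "ACGT"]
    return edlib.align(a, b, task="distance", additionalEqualities=eq)["editDistance"]


_METRICS: dict[str, Callable[..., int]] = {"hamming": hamming, "levenshtein": levenshtein}


def compute_distances(clonotype: Clonotype, metric: str = "hamming",
                      n_counts_as_mismatch: bool = False) -> DistanceMatrix:
    """Pairwise distance matrix over germline + variants (germline first)."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    fn = _METRICS[metric]
    labels = ["germline"] + clonotype.variant_ids()
    seqs = clonotype.sequences()
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = fn(seqs[labels[i]], seqs[labels[j]],
                                       n_counts_as_mismatch=n_counts_as_mismatch)
    return DistanceMatrix(labels=labels, values=mat)


# ---------------------------------------------------------------------
# Default iterative algorithm
# ---------------------------------------------------------------------

def build_default(distances: DistanceMatrix, clonotype: Clonotype | None = None,
                  tie_break: str = "breadth", seed: int | None = None) -> LineageTree:
    """Iteratively grow the tree from the germline.

    At each step the globally smallest distance between an in-tree node u
    and an out-of-tree variant v decides the attachment. When several
    (u, v) pairs tie at the minimum, candidates are first restricted by
    ``tie_break`` applied to the parent u; residual ties fall back to
    lexicographic (v, u) order, or a seeded uniform draw for
    ``tie_break='random'``.
    """
    if tie_break not in TIE_BREAKS:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    if tie_break == "random" and seed is None:
        raise ValueError("tie_break='random' requires a seed")
    rng = random.Random(seed)

    labels = distances.labels
    germ = labels[0]
    counts = {v.variant_id: v.cell_count for v in clonotype.variants} if clonotype else {}
    tree = LineageTree.empty(germ, sequence_nt=clonotype.germline_nt if clonotype else "",
                             tree_id=clonotype.clonotype_id if clonotype else "tree")
    in_tree = [germ]
    out = [l for l in labels[1:]]

    idx = {l: i for i, l in enumerate(labels)}
    D = distances.values

    while out:
        best = min(D[idx[u], idx[v]] for u in in_tree for v in out)
        cand = [(u, v) for u in in_tree for v in out
                if D[idx[u], idx[v]] <= best + 1e-12]
        if len(cand) > 1 and tie_break != "random":
            key = _tiebreak_key(tree, counts, tie_break)
            best_key = min(key(u) for u, _ in cand)
            cand = [(u, v) for u, v in cand if key(u) == best_key]
        if len(cand) > 1:
            if tie_break == "random":
                u, v = cand[rng.randrange(len(cand))]
            else:
                v, u = min((v, u) for u, v in cand)
        else:
            u, v = cand[0]
        tree.add_node(v, kind=SAMPLED, cell_count=counts.get(v, 0))
        tree.add_edge(u, v, D[idx[u], idx[v]])
        in_tree.append(v)
        out.remove(v)

    if clonotype is not None:
        annotate_from_clonotype(tree, clonotype)
    tree.annotations["method"] = "default"
    return tree


def _tiebreak_key(tree: LineageTree, counts: Mapping[str, int],
                  tie_break: str) -> Callable[[str], float]:
    # minimized keys: smaller is preferred
    if tie_break == "breadth":
        return lambda u: -len(tree.descendants(u))
    if tie_break == "depth":
        return lambda u: len(tree.descendants(u))
    if tie_break == "mutational_load_min":
        return lambda u: tree.path_weight(u)
    if tie_break == "mutational_load_max":
        return lambda u: -tree.path_weight(u)
    if tie_break == "expansion_max":
        return lambda u: -counts.get(u, tree.graph.nodes[u].get("cell_count", 0))
    if tie_break == "expansion_min":
        return lambda u: counts.get(u, tree.graph.nodes[u].get("cell_count", 0))
    raise ValueError(tie_break)


# ---------------------------------------------------------------------
# Minimum spanning tree
# ---------------------------------------------------------------------

def build_mst(distances: DistanceMatrix, clonotype: Clonotype | None = None) -> LineageTree:
    """Germline-rooted minimum spanning tree of the complete distance graph."""
    labels = distances.labels
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            g.add_edge(a, labels[j], weight=float(distances.values[i, j]))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    directed = orient_from_root(mst, labels[0])

    tree = LineageTree.empty(labels[0], tree_id=clonotype.clonotype_id if clonotype else "tree")
    for n in labels[1:]:
        tree.add_node(n, kind=SAMPLED)
    for u, v, w in directed.edges(data="weight"):
        tree.add_edge(u, v, w)
    if clonotype is not None:
        annotate_from_clonotype(tree, clonotype)
    tree.annotations["method"] = "mst"
    return tree


# ---------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------

def build_nj(distances: DistanceMatrix, clonotype: Clonotype | None = None) -> LineageTree:
    """Neighbor joining, re-rooted on the germline leaf.

    Standard agglomerative NJ (Saitou–Nei with the Studier–Keppler update).
    Negative branch lengths are clamped to zero and the deficit moved onto
    the sibling branch so the pair's summed length is preserved. With fewer
    than three taxa the result degenerates to direct germline attachment.
    """
    labels = list(distances.labels)
    germ = labels[0]
    if len(labels) < 3:
        tree = LineageTree.empty(germ)
        for i, l in enumerate(labels[1:], 1):
            tree.add_node(l, kind=SAMPLED)
            tree.add_edge(germ, l, float(distances.values[0, i]))
        if clonotype is not None:
            annotate_from_clonotype(tree, clonotype)
        tree.annotations["method"] = "nj"
        return tree

    d: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            d[frozenset((a, labels[j]))] = float(distances.values[i, j])

    und = nx.Graph()
    und.add_nodes_from(labels)
    active = list(labels)
    counter = itertools.count(1)

    while len(active) > 2:
        n = len(active)
        r = {t: sum(d[frozenset((t, o))] for o in active if o != t) for t in active}
        best_q, best_pair = None, None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (n - 2) * d[frozenset((a, b))] - r[a] - r[b]
            if best_q is None or q < best_q - 1e-12:
                best_q, best_pair = q, (a, b)
        a, b = best_pair
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        new = f"inferred_{next(counter)}"
        und.add_node(new)
        und.add_edge(new, a, weight=max(la, 0.0))
        und.add_edge(new, b, weight=max(lb, 0.0))
        for t in active:
            if t in (a, b):
                continue
            d[frozenset((new, t))] = 0.5 * (d[frozenset((a, t))] + d[frozenset((b, t))] - dab)
        active = [t for t in active if t not in (a, b)] + [new]

    a, b = active
    und.add_edge(a, b, weight=max(d[frozenset((a, b))], 0.0))

    tree = _rooted_from_unrooted(und, germ, length_attr="weight")
    if clonotype is not None:
        annotate_from_clonotype(tree, clonotype)
    tree.annotations["method"] = "nj"
    return tree


def _rooted_from_unrooted(und: nx.Graph, germ: str, length_attr: str = "weight") -> LineageTree:
    """Orient an unrooted tree away from the germline leaf."""
    directed = nx.DiGraph()
    for u, v in nx.bfs_edges(und, germ):
        directed.add_edge(u, v, weight=max(float(und.edges[u, v].get(length_attr, 0.0)), 0.0))
    tree = LineageTree.empty(germ)
    for n in und.nodes:
        if n == germ:
            continue
        kind = INFERRED if str(n).startswith("inferred_") else SAMPLED
        tree.add_node(n, kind=kind)
    for u, v, w in directed.edges(data="weight"):
        tree.add_edge(u, v, w)
    tree.validate()
    return tree


# ---------------------------------------------------------------------
# Shared alignment machinery (parsimony & likelihood)
# ---------------------------------------------------------------------

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 15}
_BIT_BASE = {1: "A", 2: "C", 4: "G", 8: "T"}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _check_alignment(alignment: Mapping[str, str]) -> None:
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment sequences must have equal length")
    if "germline" not in alignment:
        raise ValueError("alignment must include the germline")


def _encode_bits(seq: str) -> np.ndarray:
    return np.array([_BASE_BITS.get(c, 15) for c in seq], dtype=np.uint8)


def _enumerate_unrooted_topologies(leaves: Sequence[str]):
    """All (2n-5)!! unrooted binary topologies by stepwise addition."""
    leaves = list(leaves)
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")
    base = nx.Graph()
    core = "int_0"
    base.add_node(core)
    for l in leaves[:3]:
        base.add_edge(core, l)
    trees = [base]
    for k, leaf in enumerate(leaves[3:], 1):
        nxt = []
        for t in trees:
            for i, (u, v) in enumerate(sorted(t.edges())):
                g = t.copy()
                new = f"int_{k}_{i}"
                g.remove_edge(u, v)
                g.add_edge(u, new)
                g.add_edge(new, v)
                g.add_edge(new, leaf)
                nxt.append(g)
        trees = nxt
    return trees


def _nni_neighbors(topology: nx.Graph):
    """Both nearest-neighbor-interchange rearrangements of each internal edge."""
    internal_edges = [(u, v) for u, v in topology.edges()
                      if topology.degree(u) > 1 and topology.degree(v) > 1]
    for u, v in internal_edges:
        u_nbrs = sorted(n for n in topology.neighbors(u) if n != v)
        v_nbrs = sorted(n for n in topology.neighbors(v) if n != u)
        if len(u_nbrs) < 2 or len(v_nbrs) < 2:
            continue
        b = u_nbrs[1]
        for c in v_nbrs:
            g = topology.copy()
            g.remove_edge(u, b)
            g.remove_edge(v, c)
            g.add_edge(u, c)
            g.add_edge(v, b)
            yield g


def _nj_start_topology(alignment: Mapping[str, str]) -> nx.Graph:
    labels = sorted(alignment)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = hamming(alignment[labels[i]], alignment[labels[j]])
    labels = ["germline"] + [l for l in labels if l != "germline"]
    order = [sorted(alignment).index(l) for l in labels]
    mat = mat[np.ix_(order, order)]
    nj = build_nj(DistanceMatrix(labels=labels, values=mat))
    g = nx.Graph()
    for u, v, _ in nj.edges():
        g.add_edge(u, v)
    # suppress any degree-2 internal nodes so the topology is properly unrooted
    for node in [n_ for n_ in list(g.nodes) if str(n_).startswith("inferred_")]:
        if g.degree(node) == 2:
            a, b = list(g.neighbors(node))
            g.remove_node(node)
            g.add_edge(a, b)
    return g


# ---------------------------------------------------------------------
# Maximum parsimony
# ---------------------------------------------------------------------

def fitch_score(topology: nx.Graph, encoded: Mapping[str, np.ndarray]) -> int:
    """Fitch small-parsimony score of an unrooted topology (leaf-labelled)."""
    leaves = [n for n in topology.nodes if topology.degree(n) == 1]
    root = next(n for n in topology.nodes if topology.degree(n) > 1)
    order = list(nx.dfs_postorder_nodes(topology, root))
    parent = {c: p for p, c in nx.dfs_edges(topology, root)}
    L = len(next(iter(encoded.values())))
    states: dict = {}
    changes = np.zeros(L, dtype=np.int64)
    for node in order:
        if node in leaves:
            states[node] = encoded[node]
            continue
        kids = [c for c in topology.neighbors(node) if parent.get(c) == node]
        acc = states[kids[0]].copy()
        for k in kids[1:]:
            inter = acc & states[k]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | states[k], inter)
        states[node] = acc
    return int(changes.sum())


def build_parsimony(alignment: Mapping[str, str], config: BuildConfig | None = None
                    ) -> tuple[LineageTree, int]:
    """Maximum parsimony tree over an aligned clonotype (germline included).

    Returns the germline-rooted tree (internal nodes carry Fitch-reconstructed
    sequences; edge weights are the substitutions implied by a deterministic
    traceback that prefers retaining the parent state on ties) and the
    parsimony score.
    """
    config = config or BuildConfig(method="mp")
    _check_alignment(alignment)
    encoded = {k: _encode_bits(s) for k, s in alignment.items()}
    labels = sorted(alignment)

    if len(labels) == 2:
        other = next(l for l in labels if l != "germline")
        tree = LineageTree.empty("germline", sequence_nt=alignment["germline"])
        score = hamming(alignment["germline"], alignment[other])
        tree.add_node(other, kind=SAMPLED, sequence_nt=alignment[other])
        tree.add_edge("germline", other, score)
        return tree, score

    if config.search == "exhaustive":
        if len(labels) > 7:
            raise ValueError("exhaustive search limited to <= 7 leaves")
        candidates = _enumerate_unrooted_topologies(labels)
        scored = [(fitch_score(t, encoded), i, t) for i, t in enumerate(candidates)]
        best_score, _, topo = min(scored, key=lambda x: (x[0], x[1]))
    else:
        topo = _nj_start_topology(alignment)
        best_score = fitch_score(topo, encoded)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(topo):
                s = fitch_score(cand, encoded)
                if s < best_score:
                    best_score, topo, improved = s, cand, True
                    break

    tree = _parsimony_rooted(topo, alignment, encoded)
    tree.annotations["method"] = "mp"
    tree.annotations["parsimony_score"] = int(best_score)
    return tree, int(best_score)


def _parsimony_rooted(topology: nx.Graph, alignment: Mapping[str, str],
                      encoded: Mapping[str, np.ndarray]) -> LineageTree:
    """Root an unrooted MP topology at the germline leaf with Fitch traceback."""
    germ = "germline"
    parent = {c: p for p, c in nx.dfs_edges(topology, germ)}
    order = list(nx.dfs_postorder_nodes(topology, germ))
    sets: dict = {}
    for node in order:
        if node in alignment:
            sets[node] = encoded[node]
            continue
        kids = [c for c in topology.neighbors(node) if parent.get(c) == node]
        acc = sets[kids[0]].copy()
        for k in kids[1:]:
            inter = acc & sets[k]
            acc = np.where(inter == 0, acc | sets[k], inter)
        sets[node] = acc

    # top-down state assignment, preferring the parent state when possible
    assigned: dict[str, np.ndarray] = {germ: encoded[germ]}
    for p, c in nx.dfs_edges(topology, germ):
        pstate = assigned[p]
        cset = sets[c] if c not in alignment else encoded[c]
        keep = (cset & pstate) != 0
        ci = cset.astype(np.int32)
        lowest = (ci & -ci).astype(np.uint8)  # lowest set bit
        assigned[c] = np.where(keep, pstate, lowest).astype(np.uint8)

    def decode(bits: np.ndarray) -> str:
        return "".join(_BIT_BASE.get(int(b), "N") for b in bits)

    tree = LineageTree.empty(germ, sequence_nt=alignment[germ])
    for n in topology.nodes:
        if n == germ:
            continue
        if n in alignment:
            tree.add_node(n, kind=SAMPLED, sequence_nt=alignment[n])
        else:
            tree.add_node(str(n), kind=INFERRED, sequence_nt=decode(assigned[n]))
    for p, c in nx.dfs_edges(topology, germ):
        w = int(np.sum(assigned[p] != assigned[c]))
        tree.add_edge(str(p), str(c), w)
    tree.validate()
    return tree


# ---------------------------------------------------------------------
# Maximum likelihood (JC69 / K80)
# ---------------------------------------------------------------------

def _transition_matrix(d: float, model: str, kappa: float) -> np.ndarray:
    """4x4 substitution probability matrix at branch length d (subs/site).

    Base order A, C, G, T; equal base frequencies. K80 distinguishes
    transitions (A<->G, C<->T) from transversions.
    """
    d = max(float(d), 0.0)
    if model == "JC69":
        kappa = 1.0
    bt = d / (kappa + 2.0)          # beta * t
    e4b = math.exp(-4.0 * bt)
    e2ab = math.exp(-2.0 * (kappa + 1.0) * bt)
    p_same = 0.25 + 0.25 * e4b + 0.5 * e2ab
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = p_ts  # A<->G
    P[1, 3] = P[3, 1] = p_ts  # C<->T
    return P


def _leaf_partials(seq: str) -> np.ndarray:
    L = len(seq)
    out = np.zeros((L, 4))
    for i, c in enumerate(seq):
        if c in _BASE_IDX:
            out[i, _BASE_IDX[c]] = 1.0
        else:
            out[i, :] = 1.0  # N: any base
    return out


def tree_log_likelihood(topology: nx.Graph, alignment: Mapping[str, str],
                        lengths: Mapping[frozenset, float], model: str = "JC69",
                        kappa: float = 2.0) -> float:
    """Felsenstein pruning over an unrooted leaf-labelled tree."""
    if len(alignment) == 2:
        (a, sa), (b, sb) = sorted(alignment.items())
        d = lengths[frozenset((a, b))]
        P = _transition_matrix(d, model, kappa)
        pa, pb = _leaf_partials(sa), _leaf_partials(sb)
        site = np.einsum("ix,xy,iy->i", pa, P, pb) * 0.25
        return float(np.log(np.maximum(site, 1e-300)).sum())

    root = next(n for n in topology.nodes if topology.degree(n) > 1)
    parent = {c: p for p, c in nx.dfs_edges(topology, root)}
    order = list(nx.dfs_postorder_nodes(topology, root))
    partial: dict = {}
    for node in order:
        if node in alignment:
            partial[node] = _leaf_partials(alignment[node])
            continue
        kids = [c for c in topology.neighbors(node) if parent.get(c) == node]
        acc = None
        for k in kids:
            P = _transition_matrix(lengths[frozenset((node, k))], model, kappa)
            contrib = partial[k] @ P.T
            acc = contrib if acc is None else acc * contrib
        partial[node] = acc
    site = 0.25 * partial[root].sum(axis=1)
    return float(np.log(np.maximum(site, 1e-300)).sum())


def _optimize_lengths(topology: nx.Graph, alignment: Mapping[str, str],
                      lengths: dict, model: str, kappa: float,
                      tol: float = 1e-6, max_rounds: int = 20) -> float:
    edges = sorted(topology.edges(), key=str) if topology.number_of_edges() else []
    if len(alignment) == 2:
        edges = [tuple(sorted(alignment))]
    prev = tree_log_likelihood(topology, alignment, lengths, model, kappa)
    for _ in range(max_rounds):
        for u, v in edges:
            key = frozenset((u, v))

            def neg(d: float) -> float:
                trial = dict(lengths)
                trial[key] = d
                return -tree_log_likelihood(topology, alignment, trial, model, kappa)

            res = minimize_scalar(neg, bounds=(0.0, 10.0), method="bounded",
                                  options={"xatol": 1e-8})
            lengths[key] = float(res.x)
        cur = tree_log_likelihood(topology, alignment, lengths, model, kappa)
        if cur - prev < tol:
            return cur
        prev = cur
    return prev


def build_ml(alignment: Mapping[str, str], config: BuildConfig | None = None
             ) -> tuple[LineageTree, float]:
    """Maximum-likelihood tree (JC69/K80), germline-rooted.

    Topology search: NNI hill-climb from the NJ start tree; every accepted
    move strictly increases the log-likelihood. Branch lengths in expected
    substitutions per site.
    """
    config = config or BuildConfig(method="ml")
    _check_alignment(alignment)
    model = config.substitution_model
    kappa = 2.0 if model == "K80" else 1.0

    if len(alignment) == 2:
        topo = nx.Graph()
        a, b = sorted(alignment)
        topo.add_edge(a, b)
        lengths = {frozenset((a, b)): 0.1}
        ll = _optimize_lengths(topo, alignment, lengths, model, kappa)
        other = b if a == "germline" else a
        tree = LineageTree.empty("germline", sequence_nt=alignment["germline"])
        tree.add_node(other, kind=SAMPLED, sequence_nt=alignment[other])
        tree.add_edge("germline", other, lengths[frozenset((a, b))])
        tree.annotations.update(method="ml", log_likelihood=ll, model=model)
        return tree, ll

    topo = _nj_start_topology(alignment)
    lengths = {frozenset(e): 0.05 for e in topo.edges()}
    best_ll = _optimize_lengths(topo, alignment, lengths, model, kappa)

    if config.search == "nni":
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(topo):
                cl = {frozenset(e): lengths.get(frozenset(e), 0.05) for e in cand.edges()}
                ll = _optimize_lengths(cand, alignment, cl, model, kappa, max_rounds=5)
                if ll > best_ll + 1e-9:
                    topo, lengths, best_ll, improved = cand, cl, ll, True
                    break
        best_ll = _optimize_lengths(topo, alignment, lengths, model, kappa)

    tree = LineageTree.empty("germline", sequence_nt=alignment["germline"])
    for n in topo.nodes:
        if n == "germline":
            continue
        if n in alignment:
            tree.add_node(str(n), kind=SAMPLED, sequence_nt=alignment[n])
        else:
            tree.add_node(str(n), kind=INFERRED)
    for p, c in nx.dfs_edges(topo, "germline"):
        tree.add_edge(str(p), str(c), max(lengths[frozenset((p, c))], 0.0))
    tree.validate()
    tree.annotations.update(method="ml", log_likelihood=best_ll, model=model)
    return tree, best_ll


# ---------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------

def annotate_from_clonotype(tree: LineageTree, clonotype: Clonotype) -> LineageTree:
    """Copy sequences, cell counts and metadata fractions onto tree nodes."""
    by_id = {v.variant_id: v for v in clonotype.variants}
    g = tree.graph
    g.nodes[tree.root_id].update(sequence_nt=clonotype.germline_nt, cell_count=0)
    germ_aa = clonotype.annotations.get("germline_aa")
    if germ_aa:
        g.nodes[tree.root_id]["sequence_aa"] = germ_aa
    for n in g.nodes:
        v = by_id.get(n)
        if v is not None:
            g.nodes[n].update(sequence_nt=v.sequence_nt, sequence_aa=v.sequence_aa,
                              cell_count=v.cell_count,
                              metadata_fractions=dict(v.metadata_fractions),
                              cell_ids=list(v.cell_ids))
    tree.tree_id = clonotype.clonotype_id
    return tree


def build_tree(clonotype: Clonotype, config: BuildConfig | None = None) -> LineageTree:
    """Build a lineage tree for one clonotype with the configured method."""
    config = config or BuildConfig()
    if config.method in ("default", "mst", "nj"):
        dm = compute_distances(clonotype, config.distance_metric,
                               n_counts_as_mismatch=config.n_counts_as_mismatch)
        if config.method == "default":
            tree = build_default(dm, clonotype, config.tie_break, config.seed)
        elif config.method == "mst":
            tree = build_mst(dm, clonotype)
        else:
            tree = build_nj(dm, clonotype)
    else:
        alignment = clonotype.sequences()
        if config.method == "mp":
            tree, _ = build_parsimony(alignment, config)
        else:
            tree, _ = build_ml(alignment, config)
        annotate_from_clonotype(tree, clonotype)
    tree.tree_id = clonotype.clonotype_id
    return tree
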