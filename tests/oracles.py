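"""Independent oracles used by the test suite.

Each function here recomputes a quantity by a route deliberately different
from the package implementation (dynamic programming, brute-force
enumeration, closed forms, quaternion algebra) so agreement is evidence,
not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook O(nm) dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def all_spanning_trees(n: int):
    """Every labeled spanning tree of K_n as an edge list, via Prüfer sequences."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        edges = []
        seq_list = list(seq)
        leaves = sorted(v for v in range(n) if degree[v] == 1)
        for v in seq_list:
            leaf = leaves.pop(0)
            edges.append((leaf, v))
            degree[v] -= 1
            if degree[v] == 1:
                import bisect
                bisect.insort(leaves, v)
        edges.append((leaves[0], leaves[1]))
        yield edges


def min_spanning_weight(dist: np.ndarray) -> float:
    """Exhaustive minimum over all n^(n-2) spanning trees of K_n."""
    n = dist.shape[0]
    return min(sum(dist[u, v] for u, v in edges) for edges in all_spanning_trees(n))


def quaternion_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Optimal superposition RMSD by Horn's quaternion method."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    S = xc.T @ yc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    n = len(x)
    msd = (np.sum(xc ** 2) + np.sum(yc ** 2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def spearman_manual(x, y) -> float:
    """Spearman correlation via hand-computed average ranks + Pearson formula."""
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))


def loop_pseudolikelihood(seq: str, matrix: np.ndarray, alphabet: str,
                          floor: float = 1e-12) -> float:
    """Per-position python-loop mean log probability."""
    total = 0.0
    for i, c in enumerate(seq):
        total += np.log(max(matrix[i][alphabet.index(c)], floor))
    return total / len(seq)


def fitch_brute_force(topology_edges, leaf_states: dict, internal: list) -> int:
    """Minimum substitutions on a fixed topology by enumerating every
    assignment of nucleotide states to internal nodes (tiny cases only)."""
    bases = "ACGT"
    L = len(next(iter(leaf_states.values())))
    total = 0
    for site in range(L):
        best = None
        for combo in itertools.product(bases, repeat=len(internal)):
            state = {n: s for n, s in zip(internal, combo)}
            state.update({k: v[site] for k, v in leaf_states.items()})
            cost = sum(state[u] != state[v] for u, v in topology_edges)
            best = cost if best is None else min(best, cost)
        total += best
    return total


def path_distance_matrix(edges, nodes):
    """All-pairs path weights of a tree by repeated Dijkstra-free BFS
    (tree paths are unique, so a DFS accumulation suffices)."""
    adj: dict = {n: [] for n in nodes}
    for u, v, w in edges:
        adj[u].append((v, w))
        adj[v].append((u, w))
    idx = {n: i for i, n in enumerate(nodes)}
    mat = np.zeros((len(nodes), len(nodes)))
    for src in nodes:
        stack = [(src, 0.0)]
        seen = {src}
        while stack:
            node, d = stack.pop()
            mat[idx[src], idx[node]] = d
            for nb, w in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, d + w))
    return mat
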