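from __future__ import annotations

import numpy as np
import pytest

import bcrforest as bf


@pytest.fixture(scope="session")
def sim_truth():
    """One fully-observed simulated lineage shared across read-only tests."""
    cfg = bf.SimulationConfig(seed=1)
    records, truth = bf.simulate_lineage(cfg)
    return records, truth


@pytest.fixture(scope="session")
def sim_clonotype(sim_truth):
    _, truth = sim_truth
    return bf.observed_clonotype(truth)


def random_lineage_tree(rng: np.random.Generator, n_nodes: int = 8,
                        prefix: str = "v", integer_weights: bool = False) -> bf.LineageTree:
    """Random germline-rooted tree by sequential random attachment."""
    tree = bf.LineageTree.empty("germline")
    names = [f"{prefix}{i}" for i in range(1, n_nodes)]
    placed = ["germline"]
    for name in names:
        parent = placed[int(rng.integers(0, len(placed)))]
        w = int(rng.integers(1, 10)) if integer_weights else float(rng.uniform(0.1, 5.0))
        tree.add_node(name, kind=bf.SAMPLED, cell_count=int(rng.integers(1, 5)))
        tree.add_edge(parent, name, w)
        placed.append(name)
    return tree


def random_distance_matrix(rng: np.random.Generator, n: int,
                           distinct: bool = True) -> bf.DistanceMatrix:
    """Random symmetric distance matrix with (optionally) all-distinct entries."""
    m = n * (n - 1) // 2
    if distinct:
        vals = rng.permutation(np.arange(1, m + 1)).astype(float)
        vals += rng.uniform(0, 0.5, size=m)  # break any residual structure
    else:
        vals = rng.uniform(1, 10, size=m)
    mat = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mat[iu] = vals
    mat = mat + mat.T
    labels = ["germline"] + [f"v{i}" for i in range(1, n)]
    return bf.DistanceMatrix(labels=labels, values=mat)
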