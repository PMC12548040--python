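"""Comparing lineage trees within and across repertoires.

The generalized branch length distance (GBLD) compares two germline-rooted
trees over (possibly different) sets of sampled sequences. After
normalizing each tree's branch lengths to sum to 1:

    GBLD = P + W
    P = 1 − |L_a ∩ L_b| / |L_a ∪ L_b|          (sampled-label Jaccard penalty)
    W = mean over shared labels v of |d_a(v) − d_b(v)|

with d(v) the normalized path weight from the germline to v. Inferred
nodes never match by label but do contribute to path weights. GBLD is
symmetric, zero on identical trees, invariant to uniform branch-length
scaling, and at most 2. Over an empty shared label set W is defined as 0
(P already saturates at 1).

Repertoire-level comparison works on the topology-metric matrix:
hierarchical clustering (average linkage, Euclidean, z-scored columns) plus
a 2-D principal-component embedding identifies topologically similar
lineages, whose cluster labels can then be related to isotype, expansion or
any custom metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .build import BuildConfig, build_tree
from .io import Clonotype
from .tree import GERMLINE, LineageTree, TreeError


def _normalized_depths(tree: LineageTree) -> dict[str, float]:
    total = tree.total_weight()
    if total <= 0:
        return {n: 0.0 for n in tree.sampled_labels()}
    return {n: tree.path_weight(n) / total for n in tree.sampled_labels()}


def gbld(tree_a: LineageTree, tree_b: LineageTree) -> float:
    """Generalized branch length distance between two lineage trees."""
    for t in (tree_a, tree_b):
        if t.kind(t.root_id) != GERMLINE:
            raise TreeError("gbld requires germline-rooted trees")
    la, lb = tree_a.sampled_labels(), tree_b.sampled_labels()
    union = la | lb
    if not union:
        return 0.0
    shared = la & lb
    P = 1.0 - len(shared) / len(union)
    if shared:
        da, db = _normalized_depths(tree_a), _normalized_depths(tree_b)
        W = float(np.mean([abs(da[v] - db[v]) for v in sorted(shared)]))
    else:
        W = 0.0
    return P + W


@dataclass
class RobustnessReport:
    methods: list[str]
    matrix: pd.DataFrame       # method x method GBLD
    robustness_score: float    # mean off-diagonal GBLD; 0 = perfectly stable
    removal_mode: str | None


def robustness_report(clonotype: Clonotype, methods: Sequence[str],
                      config: BuildConfig | None = None,
                      removal_mode: str | None = None,
                      allow_mixed: bool = False) -> RobustnessReport:
    """How stable is one clonotype's tree across construction methods?

    Builds the clonotype with every requested method, applies a single
    internal-node-removal mode to all of them (required whenever any method
    can produce inferred nodes, unless ``allow_mixed``), and reports the
    pairwise GBLD matrix plus its mean off-diagonal value as the
    robustness score.
    """
    from .transform import remove_internal_nodes

    if len(methods) < 2:
        raise ValueError("robustness needs >= 2 construction methods")
    base = config or BuildConfig()
    trees = []
    for m in methods:
        cfg = BuildConfig(method=m, distance_metric=base.distance_metric,
                          tie_break=base.tie_break, seed=base.seed,
                          substitution_model=base.substitution_model,
                          search=base.search)
        t = build_tree(clonotype, cfg)
        if removal_mode is not None:
            t = remove_internal_nodes(t, removal_mode)
        trees.append(t)

    modes = {t.annotations.get("internal_node_removal") for t in trees
             if t.nodes("inferred") or t.annotations.get("internal_node_removal")}
    if len(modes) > 1 and not allow_mixed:
        raise ValueError("mixed internal-node-removal modes; pass allow_mixed=True "
                         "or a single removal_mode")

    n = len(methods)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = gbld(trees[i], trees[j])
    off = mat[~np.eye(n, dtype=bool)]
    return RobustnessReport(methods=list(methods),
                            matrix=pd.DataFrame(mat, index=methods, columns=methods),
                            robustness_score=float(off.mean()),
                            removal_mode=removal_mode)


@dataclass
class ComparisonResult:
    labels: pd.Series          # tree_id -> cluster label
    embedding: pd.DataFrame    # tree_id x (PC1, PC2)
    linkage_matrix: np.ndarray
    dropped_columns: list[str]


def compare_across(metrics: pd.DataFrame, method: str = "k",
                   k_or_height: float = 2) -> ComparisonResult:
    """Cluster trees by topology metrics and embed them in 2-D.

    ``metrics`` is the trees x metrics matrix (tree_id index). Columns are
    z-scored; constant or all-missing columns are dropped; remaining
    missing values are imputed with the column mean. ``method`` selects the
    dendrogram cut: ``"k"`` for a fixed cluster count, ``"height"`` for a
    distance threshold.
    """
    if len(metrics) < 2:
        raise ValueError("need >= 2 trees to compare")
    if method == "k":
        k = int(k_or_height)
        if k > len(metrics):
            raise ValueError(f"k={k} exceeds number of trees ({len(metrics)})")
    X = metrics.apply(pd.to_numeric, errors="coerce")
    dropped = [c for c in X.columns
               if X[c].isna().all() or np.nanstd(X[c].to_numpy(dtype=float)) < 1e-12]
    X = X.drop(columns=dropped)
    if X.empty:
        raise ValueError("no informative metric columns left after dropping constants")
    X = X.fillna(X.mean())
    Z = (X - X.mean()) / X.std(ddof=0)

    link = linkage(Z.to_numpy(), method="average", metric="euclidean")
    if method == "k":
        labels = fcluster(link, t=int(k_or_height), criterion="maxclust")
    elif method == "height":
        labels = fcluster(link, t=float(k_or_height), criterion="distance")
    else:
        raise ValueError(f"unknown cut method {method!r}")

    n_comp = min(2, Z.shape[1], Z.shape[0])
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(Z.to_numpy())
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    return ComparisonResult(
        labels=pd.Series(labels, index=metrics.index, name="cluster"),
        embedding=pd.DataFrame(coords[:, :2], index=metrics.index, columns=["PC1", "PC2"]),
        linkage_matrix=link,
        dropped_columns=dropped,
    )


@dataclass
class EdgeAgreement:
    shared_edges: set[tuple[str, str]]
    edge_agreement: float      # |shared| / max(|E_a|, |E_b|)
    edge_jaccard: float        # |shared| / |union|
    parent_agreement: pd.Series  # node -> parent identical in both trees


def compare_identical_sequences(tree_a: LineageTree, tree_b: LineageTree) -> EdgeAgreement:
    """Edge-level agreement of two trees over the same sampled sequences.

    Requires identical sampled label sets (use :func:`gbld` otherwise).
    Reports the shared directed parent→child pairs, the agreement fraction
    (shared edges over the larger edge set), the strict Jaccard of the
    directed edge sets, and a per-node indicator of parent agreement.
    """
    if tree_a.sampled_labels() != tree_b.sampled_labels():
        raise TreeError("sampled label sets differ; use gbld for such pairs")
    ea = {(u, v) for u, v, _ in tree_a.edges()}
    eb = {(u, v) for u, v, _ in tree_b.edges()}
    shared = ea & eb
    union = ea | eb
    nodes = sorted(tree_a.sampled_labels())
    parents = pd.Series(
        {n: tree_a.parent(n) == tree_b.parent(n) for n in nodes}, name="parent_agrees")
    return EdgeAgreement(
        shared_edges=shared,
        edge_agreement=len(shared) / max(len(ea), len(eb)) if union else 1.0,
        edge_jaccard=len(shared) / len(union) if union else 1.0,
        parent_agreement=parents,
    )
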