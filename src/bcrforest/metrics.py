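"""Per-tree topology descriptors.

Two families of metrics summarize a lineage tree:

* plain graph statistics — node/leaf/internal counts, depths in edge count
  and in cumulative edge weight, out-degrees, and the Sackin imbalance
  index (sum of leaf depths in edges; large values flag caterpillar-like
  trees, a signature of sustained selective pressure on one sub-lineage);
* the spectral density of a modified graph Laplacian built from patristic
  (path-weight) distances between all node pairs. Its largest eigenvalue
  tracks lineage richness, the skewness of the log-eigenvalue distribution
  separates deep from shallow branching, and its excess kurtosis tracks
  imbalance.

The Laplacian is M = Diag(row sums) − P with P the all-pairs patristic
distance matrix (root and inferred nodes included). Eigenvalues of M are
real and non-negative and the smallest is exactly 0. The density is a
Gaussian KDE over the natural log of the positive eigenvalues with
Silverman's bandwidth; skewness/kurtosis are computed on the log-eigenvalue
sample itself so they do not depend on grid resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import INFERRED, LineageTree, pairwise_path_weights


class MetricError(ValueError):
    """Metric undefined for this tree (e.g. spectral density of one node)."""


@dataclass
class SpectralDensity:
    eigenvalues: np.ndarray          # descending
    principal_eigenvalue: float
    asymmetry: float                 # skewness of ln-eigenvalues
    peakedness: float                # excess kurtosis of ln-eigenvalues
    density_grid: tuple[np.ndarray, np.ndarray]
    meta: dict = field(default_factory=dict)


@dataclass
class TreeMetrics:
    tree_id: str
    n_nodes: int
    n_leaves: int
    n_internal: int
    max_depth_edges: int
    mean_depth_edges: float
    max_depth_weighted: float
    mean_depth_weighted: float
    root_outdegree: int
    mean_outdegree: float
    sackin: int
    spectral: SpectralDensity | None = None

    FIELDS = ("n_nodes", "n_leaves", "n_internal", "max_depth_edges",
              "mean_depth_edges", "max_depth_weighted", "mean_depth_weighted",
              "root_outdegree", "mean_outdegree", "sackin",
              "spectral_principal_eigenvalue", "spectral_asymmetry",
              "spectral_peakedness")

    def to_row(self) -> dict:
        row = {f: getattr(self, f) for f in self.FIELDS if not f.startswith("spectral_")}
        if self.spectral is not None:
            row["spectral_principal_eigenvalue"] = self.spectral.principal_eigenvalue
            row["spectral_asymmetry"] = self.spectral.asymmetry
            row["spectral_peakedness"] = self.spectral.peakedness
        else:
            row.update({"spectral_principal_eigenvalue": np.nan,
                        "spectral_asymmetry": np.nan, "spectral_peakedness": np.nan})
        return row


def sackin_index(tree: LineageTree) -> int:
    """Sum of leaf depths in edge counts (classical Sackin index)."""
    return sum(tree.depth_edges(l) for l in tree.leaves())


def compute_tree_metrics(tree: LineageTree, with_spectral: bool = True) -> TreeMetrics:
    nodes = list(tree.graph.nodes)
    leaves = tree.leaves()
    internal = [n for n in nodes if n != tree.root_id and n not in leaves]
    depths_e = {n: tree.depth_edges(n) for n in nodes}
    depths_w = {n: tree.path_weight(n) for n in nodes}
    non_root = [n for n in nodes if n != tree.root_id] or [tree.root_id]
    spectral = None
    if with_spectral and len(nodes) >= 2:
        try:
            spectral = spectral_density(tree)
        except MetricError:
            spectral = None
    return TreeMetrics(
        tree_id=tree.tree_id,
        n_nodes=len(nodes),
        n_leaves=len(leaves),
        n_internal=len(internal),
        max_depth_edges=max(depths_e.values()),
        mean_depth_edges=float(np.mean([depths_e[n] for n in non_root])),
        max_depth_weighted=max(depths_w.values()),
        mean_depth_weighted=float(np.mean([depths_w[n] for n in non_root])),
        root_outdegree=tree.graph.out_degree(tree.root_id),
        mean_outdegree=float(np.mean([tree.graph.out_degree(n) for n in nodes])),
        sackin=sackin_index(tree),
        spectral=spectral,
    )


def modified_laplacian(tree: LineageTree) -> tuple[list[str], np.ndarray]:
    """M = Diag(row sums) − P over all-pairs patristic distances."""
    labels, P = pairwise_path_weights(tree, min_weight=1e-9)
    M = np.diag(P.sum(axis=1)) - P
    return labels, M


def spectral_density(tree: LineageTree, bandwidth_rule: str = "silverman",
                     grid_points: int = 256) -> SpectralDensity:
    """Laplacian spectral density of a lineage tree.

    Raises :class:`MetricError` on single-node trees, where the spectrum is
    degenerate.
    """
    if tree.n_nodes < 2:
        raise MetricError("spectral density undefined for a single-node tree")
    _, M = modified_laplacian(tree)
    eig = np.linalg.eigvalsh(M)
    eig = np.sort(eig)[::-1]
    positive = eig[eig > 1e-8]
    ln_eig = np.log(positive)

    if positive.size >= 2 and np.ptp(ln_eig) > 1e-12:
        kde = stats.gaussian_kde(ln_eig, bw_method=bandwidth_rule)
        lo, hi = ln_eig.min(), ln_eig.max()
        pad = 3.0 * kde.factor * max(ln_eig.std(ddof=1), 1e-6)
        x = np.linspace(lo - pad, hi + pad, grid_points)
        f = kde(x)
        f = f / np.trapezoid(f, x)  # exact unit mass on the reported grid
        grid = (x, f)
    else:
        grid = (np.array([]), np.array([]))

    if ln_eig.size >= 3 and np.ptp(ln_eig) > 1e-12:
        asym = float(stats.skew(ln_eig))
        peak = float(stats.kurtosis(ln_eig))  # excess (Fisher)
    else:
        asym = peak = float("nan")

    return SpectralDensity(
        eigenvalues=eig,
        principal_eigenvalue=float(eig[0]),
        asymmetry=asym,
        peakedness=peak,
        density_grid=grid,
        meta={"bandwidth_rule": bandwidth_rule, "transform": "ln",
              "statistic_basis": "ln-eigenvalue sample"},
    )


def metrics_matrix(forest: Sequence[LineageTree]) -> pd.DataFrame:
    """One row of topology metrics per tree (fixed column order, CSV-ready).

    Metrics that are undefined for a tree (spectral summaries of 1-node
    trees) are left empty.
    """
    if not forest:
        raise ValueError("metrics_matrix requires at least one tree")
    rows = []
    for tree in forest:
        m = compute_tree_metrics(tree)
        row = {"tree_id": tree.tree_id}
        row.update(m.to_row())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["tree_id", *TreeMetrics.FIELDS])
    return df.set_index("tree_id")
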