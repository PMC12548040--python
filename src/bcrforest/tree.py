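"""Germline-rooted lineage tree container.

A B-cell clonal lineage is represented as a rooted, edge-weighted directed
graph. The root is the unmutated germline reference; every other node is
either a *sampled* antibody variant (observed in the repertoire, carrying a
cell count) or an *inferred* ancestor introduced by a phylogenetic
algorithm (cell count 0). Multifurcations are allowed, and sampled
sequences may sit at internal positions — both depart from the classical
strictly-bifurcating phylogeny and reflect how somatic hypermutation
lineages are actually observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Mapping

import networkx as nx

GERMLINE = "germline"
SAMPLED = "sampled"
INFERRED = "inferred"

_KINDS = {GERMLINE, SAMPLED, INFERRED}


class TreeError(ValueError):
    """Structural problem with a lineage tree."""


@dataclass
class LineageTree:
    """Rooted, edge-weighted, multifurcation-capable lineage tree.

    Thin wrapper around a :class:`networkx.DiGraph` whose edges point away
    from the germline root. Node attributes: ``kind`` (germline / sampled /
    inferred), ``sequence_nt``, ``sequence_aa``, ``cell_count``,
    ``metadata_fractions`` (mapping label-column -> {label: fraction}),
    ``cell_ids`` and free-form ``annotations``. Edge attribute: ``weight``
    (non-negative; for distance-built trees the sequence distance, for
    parsimony trees the implied substitution count).
    """

    graph: nx.DiGraph
    root_id: str
    tree_id: str = "tree"
    annotations: dict[str, Any] = field(default_factory=dict)

    # -- construction -------------------------------------------------

    @classmethod
    def empty(cls, root_id: str, sequence_nt: str = "", tree_id: str = "tree",
              **root_attrs: Any) -> "LineageTree":
        g = nx.DiGraph()
        g.add_node(root_id, kind=GERMLINE, sequence_nt=sequence_nt,
                   cell_count=0, metadata_fractions={}, **root_attrs)
        return cls(graph=g, root_id=root_id, tree_id=tree_id)

    def add_node(self, node_id: str, *, kind: str = SAMPLED,
                 sequence_nt: str = "", cell_count: int = 0,
                 **attrs: Any) -> None:
        if kind not in _KINDS:
            raise TreeError(f"unknown node kind {kind!r}")
        self.graph.add_node(node_id, kind=kind, sequence_nt=sequence_nt,
                            cell_count=cell_count,
                            metadata_fractions=attrs.pop("metadata_fractions", {}),
                            **attrs)

    def add_edge(self, parent: str, child: str, weight: float) -> None:
        if weight < 0:
            raise TreeError(f"negative edge weight {weight} on {parent}->{child}")
        self.graph.add_edge(parent, child, weight=float(weight))

    # -- accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def nodes(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.graph.nodes)
        return [n for n, k in self.graph.nodes(data="kind") if k == kind]

    def sampled_labels(self) -> set[str]:
        """Sampled (non-germline, non-inferred) node ids."""
        return set(self.nodes(SAMPLED))

    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    def parent(self, node: str) -> str | None:
        preds = list(self.graph.predecessors(node))
        if not preds:
            return None
        if len(preds) > 1:
            raise TreeError(f"node {node} has {len(preds)} parents")
        return preds[0]

    def children(self, node: str) -> list[str]:
        return list(self.graph.successors(node))

    def leaves(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, w in self.graph.edges(data="weight"):
            yield u, v, float(w)

    def edge_weight(self, parent: str, child: str) -> float:
        return float(self.graph.edges[parent, child]["weight"])

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges()))

    def depth_edges(self, node: str) -> int:
        d = 0
        while (p := self.parent(node)) is not None:
            node = p
            d += 1
        return d

    def path_weight(self, node: str) -> float:
        """Cumulative edge weight from the germline root to ``node``."""
        w = 0.0
        while (p := self.parent(node)) is not None:
            w += self.edge_weight(p, node)
            node = p
        return w

    def descendants(self, node: str) -> set[str]:
        return nx.descendants(self.graph, node)

    def postorder(self) -> list[str]:
        return list(nx.dfs_postorder_nodes(self.graph, self.root_id))

    def copy(self) -> "LineageTree":
        return LineageTree(graph=self.graph.copy(), root_id=self.root_id,
                           tree_id=self.tree_id, annotations=dict(self.annotations))

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        g = self.graph
        if self.root_id not in g:
            raise TreeError("root missing from graph")
        if g.nodes[self.root_id]["kind"] != GERMLINE:
            raise TreeError("root is not the germline")
        if not nx.is_weakly_connected(g) or not nx.is_directed_acyclic_graph(g):
            raise TreeError("graph is not a connected DAG")
        for n in g.nodes:
            indeg = g.in_degree(n)
            if n == self.root_id:
                if indeg != 0:
                    raise TreeError("root has a parent")
            elif indeg != 1:
                raise TreeError(f"node {n} has in-degree {indeg}")
            if g.nodes[n]["kind"] == INFERRED and g.nodes[n].get("cell_count", 0):
                raise TreeError(f"inferred node {n} has nonzero cell count")
        for u, v, w in self.edges():
            if not math.isfinite(w) or w < 0:
                raise TreeError(f"bad edge weight {w} on {u}->{v}")

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        data = nx.node_link_data(self.graph, edges="links")
        return {"tree_id": self.tree_id, "root_id": self.root_id,
                "annotations": self.annotations, "graph": data}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "LineageTree":
        g = nx.node_link_graph(d["graph"], directed=True, edges="links")
        return cls(graph=g, root_id=d["root_id"], tree_id=d.get("tree_id", "tree"),
                   annotations=dict(d.get("annotations", {})))


def orient_from_root(undirected: nx.Graph, root: str) -> nx.DiGraph:
    """Orient an undirected weighted tree away from ``root``."""
    if root not in undirected:
        raise TreeError(f"root {root!r} not in graph")
    directed = nx.DiGraph()
    for n, attrs in undirected.nodes(data=True):
        directed.add_node(n, **attrs)
    for u, v in nx.bfs_edges(undirected, root):
        directed.add_edge(u, v, weight=float(undirected.edges[u, v].get("weight", 1.0)))
    return directed


def pairwise_path_weights(tree: LineageTree,
                          nodes: Iterable[str] | None = None,
                          min_weight: float = 0.0):
    """Patristic (summed edge weight) distances between tree nodes.

    Returns ``(labels, matrix)``. Zero or near-zero edge weights are raised
    to ``min_weight`` so downstream spectral constructions stay
    non-degenerate.
    """
    import numpy as np

    labels = list(nodes) if nodes is not None else list(tree.graph.nodes)
    und = nx.Graph()
    und.add_nodes_from(tree.graph.nodes)
    for u, v, w in tree.edges():
        und.add_edge(u, v, weight=max(float(w), min_weight))
    idx = {n: i for i, n in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)))
    for src, dists in nx.all_pairs_dijkstra_path_length(und, weight="weight"):
        if src not in idx:
            continue
        i = idx[src]
        for dst, d in dists.items():
            if dst in idx:
                mat[i, idx[dst]] = d
    return labels, mat
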