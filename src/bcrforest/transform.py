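"""Tree post-processing: internal-node removal, bulk integration, annotation.

Phylogenetic algorithms (NJ/MP/ML) introduce inferred internal ancestors.
In B-cell repertoires these ancestors are often themselves sampled (zero
branch length to a sequenced variant) or represent cells absent at sampling
time. To turn a bifurcating phylogeny into the multifurcating lineage
network the repertoire actually supports, inferred nodes can be removed in
three ways; downstream tree comparisons should use one removal mode
consistently, since the choice changes the apparent evolutionary
trajectory. The mode used is stamped into the tree's annotations.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .build import annotate_from_clonotype, compute_distances, hamming, levenshtein
from .io import BULK, Clonotype, SequenceRecord, Variant, _fractions, group_clonotypes
from .tree import GERMLINE, INFERRED, SAMPLED, LineageTree, TreeError

logger = logging.getLogger("bcrforest")

ZERO_TOL = 1e-9

REMOVAL_MODES = ("zero_length_only", "replace_by_closest_descendant", "link_to_parent")


def remove_internal_nodes(tree: LineageTree, mode: str = "zero_length_only") -> LineageTree:
    """Remove (or absorb) inferred internal nodes.

    ``zero_length_only``
        an inferred node with a zero-weight edge (<= 1e-9) to a sampled
        terminal child is merged with that terminal: the terminal takes the
        inferred node's place and inherits its remaining children. This
        preserves mutational ordering; inferred nodes without such a
        terminal are kept.
    ``replace_by_closest_descendant``
        every inferred node is replaced by its nearest sampled descendant
        (smallest path weight; ties broken by larger cell count, then id),
        repaired recursively bottom-up; displaced siblings re-attach at
        their original patristic distance from the promoted node. Favors
        depth.
    ``link_to_parent``
        every inferred node is deleted and its children re-attach to their
        closest sampled ancestor with edge weight equal to the connecting
        path weight, preserving germline path weights. Favors breadth.
    """
    if mode not in REMOVAL_MODES:
        raise ValueError(f"unknown removal mode {mode!r}")
    out = tree.copy()
    if mode == "zero_length_only":
        _merge_zero_length(out)
    elif mode == "replace_by_closest_descendant":
        _replace_closest_descendant(out)
    else:
        _link_to_parent(out)
    out.annotations["internal_node_removal"] = mode
    out.validate()
    return out


def _cell_count(tree: LineageTree, n: str) -> int:
    return int(tree.graph.nodes[n].get("cell_count", 0) or 0)


def _merge_zero_length(tree: LineageTree) -> None:
    g = tree.graph
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            if node not in g or g.nodes[node]["kind"] != INFERRED:
                continue
            candidates = [c for c in g.successors(node)
                          if g.nodes[c]["kind"] == SAMPLED
                          and g.out_degree(c) == 0
                          and g.edges[node, c]["weight"] <= ZERO_TOL]
            if not candidates:
                continue
            if len(candidates) > 1:
                logger.info("zero-length tie at %s among %s; merging by cell count",
                            node, candidates)
            winner = max(candidates, key=lambda c: (_cell_count(tree, c), c))
            parent = tree.parent(node)
            for child in list(g.successors(node)):
                if child != winner:
                    g.add_edge(winner, child, weight=g.edges[node, child]["weight"])
            if parent is not None:
                g.add_edge(parent, winner, weight=g.edges[parent, node]["weight"])
            g.remove_node(node)
            changed = True


def _replace_closest_descendant(tree: LineageTree) -> None:
    g = tree.graph
    # bottom-up: after processing, every subtree below is inferred-free
    for node in tree.postorder():
        if node not in g or g.nodes[node]["kind"] != INFERRED:
            continue
        kids = list(g.successors(node))
        if not kids:  # dangling inferred leaf: drop it
            g.remove_node(node)
            continue
        winner = min(kids, key=lambda c: (g.edges[node, c]["weight"],
                                          -_cell_count(tree, c), c))
        parent = tree.parent(node)
        w_up = g.edges[node, winner]["weight"]
        for child in kids:
            if child != winner:
                g.add_edge(winner, child,
                           weight=g.edges[node, child]["weight"] + w_up)
        if parent is not None:
            g.add_edge(parent, winner, weight=g.edges[parent, node]["weight"] + w_up)
        g.remove_node(node)


def _link_to_parent(tree: LineageTree) -> None:
    g = tree.graph
    inferred = [n for n in g.nodes if g.nodes[n]["kind"] == INFERRED]
    sampled_parent: dict[str, tuple[str, float]] = {}
    for node in g.nodes:
        if g.nodes[node]["kind"] == INFERRED:
            continue
        p, w = tree.parent(node), 0.0
        if p is None:
            continue
        w = tree.edge_weight(p, node)
        while p is not None and g.nodes[p]["kind"] == INFERRED:
            gp = tree.parent(p)
            if gp is None:
                break
            w += tree.edge_weight(gp, p)
            p = gp
        if p is not None:
            sampled_parent[node] = (p, w)
    for node, (p, w) in sampled_parent.items():
        old = tree.parent(node)
        if old != p:
            g.remove_edge(old, node)
            g.add_edge(p, node, weight=w)
    for n in inferred:
        if g.in_degree(n) == 0 and g.out_degree(n) == 0:
            g.remove_node(n)
        elif g.out_degree(n) == 0:
            g.remove_node(n)
        else:  # inferred root-side remnant should not happen (root is germline)
            g.remove_node(n)


# ---------------------------------------------------------------------
# Bulk integration
# ---------------------------------------------------------------------

def integrate_bulk(target: Clonotype | LineageTree, bulk_records: Sequence[SequenceRecord],
                   strategy: str = "use_clone_id", metric: str = "hamming",
                   ) -> tuple[Clonotype | LineageTree, list[SequenceRecord]]:
    """Fold bulk-sequencing reads into a clonotype or an existing tree.

    Bulk reads matching an existing variant raise its cell count by their
    duplicate count; novel sequences become new variants (clonotype input)
    or new leaves attached by the minimum-distance rule without touching
    existing edges (tree input). Non-matching records are returned
    unassigned.
    """
    if isinstance(target, Clonotype):
        return _bulk_into_clonotype(target, bulk_records, strategy)
    return _bulk_into_tree(target, bulk_records, strategy, metric)


def _matches(clonotype_id: str, rec: SequenceRecord, strategy: str,
             germline: str = "") -> bool:
    if strategy == "use_clone_id":
        return rec.clone_id == clonotype_id
    # vjl fallback: same germline alignment marks the same recombination event
    return bool(germline) and rec.germline_alignment_nt == germline


def _bulk_into_clonotype(clonotype: Clonotype, records: Sequence[SequenceRecord],
                         strategy: str) -> tuple[Clonotype, list[SequenceRecord]]:
    unassigned = []
    import copy
    out = Clonotype(clonotype_id=clonotype.clonotype_id, germline_nt=clonotype.germline_nt,
                    variants=copy.deepcopy(clonotype.variants),
                    chain_scope=clonotype.chain_scope,
                    annotations=dict(clonotype.annotations))
    by_seq = {v.sequence_nt: v for v in out.variants}
    fresh = 0
    for rec in records:
        if rec.source != BULK or not _matches(clonotype.clonotype_id, rec, strategy,
                                              clonotype.germline_nt):
            unassigned.append(rec)
            continue
        v = by_seq.get(rec.sequence_nt)
        if v is None:
            fresh += 1
            v = Variant(variant_id=f"bulk_{fresh}", sequence_nt=rec.sequence_nt,
                        cell_count=0, junction_nt=rec.junction_nt)
            out.variants.append(v)
            by_seq[rec.sequence_nt] = v
        v.cell_count += rec.duplicate_count
        v.cell_labels[rec.sequence_id] = {"source": BULK}
        v.metadata_fractions = _fractions(v.cell_labels)
    return out, unassigned


def _bulk_into_tree(tree: LineageTree, records: Sequence[SequenceRecord],
                    strategy: str, metric: str) -> tuple[LineageTree, list[SequenceRecord]]:
    fn = hamming if metric == "hamming" else levenshtein
    out = tree.copy()
    g = out.graph
    unassigned = []
    fresh = 0
    germ_seq = g.nodes[out.root_id].get("sequence_nt", "")
    for rec in records:
        if rec.source != BULK or not _matches(out.tree_id, rec, strategy, germ_seq):
            unassigned.append(rec)
            continue
        hit = next((n for n, s in g.nodes(data="sequence_nt")
                    if s == rec.sequence_nt and g.nodes[n]["kind"] != INFERRED), None)
        if hit is not None:
            g.nodes[hit]["cell_count"] = _cell_count(out, hit) + rec.duplicate_count
            continue
        scored = sorted(
            (fn(g.nodes[n]["sequence_nt"], rec.sequence_nt), n)
            for n in g.nodes if g.nodes[n].get("sequence_nt"))
        d, parent = scored[0]
        fresh += 1
        new = f"bulk_{fresh}"
        out.add_node(new, kind=SAMPLED, sequence_nt=rec.sequence_nt,
                     cell_count=rec.duplicate_count,
                     metadata_fractions={"source": {BULK: 1.0}})
        out.add_edge(parent, new, d)
    return out, unassigned


# ---------------------------------------------------------------------
# Node annotation
# ---------------------------------------------------------------------

def annotate_nodes(tree: LineageTree,
                   records_or_table: Sequence[SequenceRecord] | Mapping[str, Mapping[str, str]],
                   label_column: str) -> LineageTree:
    """Attach per-label cell fractions to sampled nodes.

    ``records_or_table`` is either a sequence of records (labels pulled from
    ``c_call`` for ``label_column='isotype'`` or from ``extras``) or a
    mapping cell_id -> {column: label}. Each sampled node's
    ``metadata_fractions[label_column]`` becomes the label distribution over
    its cells; nodes without cells (germline, inferred) get empty fractions.
    """
    cell_labels: dict[str, str] = {}
    if isinstance(records_or_table, Mapping):
        for cell, row in records_or_table.items():
            if label_column in row:
                cell_labels[cell] = row[label_column]
    else:
        for rec in records_or_table:
            val = rec.c_call if label_column == "isotype" else rec.extras.get(label_column, "")
            if val:
                cell_labels[rec.cell_id or rec.sequence_id] = val
    if not cell_labels:
        raise ValueError(f"label column {label_column!r} yields no labels")

    out = tree.copy()
    for n, attrs in out.graph.nodes(data=True):
        cells = attrs.get("cell_ids", [])
        labels = [cell_labels[c] for c in cells if c in cell_labels]
        fr = attrs.setdefault("metadata_fractions", {})
        if labels:
            fr[label_column] = {lab: labels.count(lab) / len(labels)
                                for lab in sorted(set(labels))}
        else:
            fr.setdefault(label_column, {})
    return out
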