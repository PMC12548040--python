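"""Reading, writing and clonotype assembly for repertoire data.

Consumes AIRR Rearrangement TSV (the community-standard tab-separated
schema for adaptive immune receptor sequences), plain FASTA, Newick trees
produced by external phylogenetics tools, and GraphML / CSV for export.
Raw sequence records are grouped into clonotypes — sets of B cells that
arose from one V(D)J recombination event and diversified by somatic
hypermutation from a shared germline.

All sequence coordinates are 0-based, half-open.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Phylo

from .tree import GERMLINE, INFERRED, SAMPLED, LineageTree, TreeError, orient_from_root

logger = logging.getLogger("bcrforest")

SINGLE_CELL = "single_cell"
BULK = "bulk"

#: default junction-identity threshold for V/J/length clonotyping
DEFAULT_JUNCTION_IDENTITY = 0.85


class FormatError(ValueError):
    """Unparseable or schema-violating input file."""


# ---------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One sequenced BCR chain with its germline call and cell metadata."""

    sequence_id: str
    sequence_nt: str
    cell_id: str = ""
    sequence_aa: str = ""
    v_call: str = ""
    j_call: str = ""
    junction_nt: str = ""
    c_call: str = ""
    duplicate_count: int = 1
    clone_id: str = ""
    germline_alignment_nt: str = ""
    source: str = SINGLE_CELL
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence_nt:
            raise ValueError("sequence_nt must be non-empty")
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")
        if self.source == SINGLE_CELL and not self.cell_id:
            raise ValueError("single-cell records require a cell_id")


@dataclass
class Variant:
    """A unique sequence within a clonotype, with its supporting cells."""

    variant_id: str
    sequence_nt: str
    sequence_aa: str = ""
    cell_count: int = 0
    metadata_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    cell_ids: list[str] = field(default_factory=list)
    cell_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    junction_nt: str = ""


@dataclass
class Clonotype:
    """Germline reference plus the unique variants derived from it."""

    clonotype_id: str
    germline_nt: str
    variants: list[Variant] = field(default_factory=list)
    chain_scope: str = "heavy"
    annotations: dict[str, Any] = field(default_factory=dict)

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def sequences(self, include_germline: bool = True) -> dict[str, str]:
        seqs = {"germline": self.germline_nt} if include_germline else {}
        for v in self.variants:
            seqs[v.variant_id] = v.sequence_nt
        return seqs

    def validate(self) -> None:
        seqs = [v.sequence_nt for v in self.variants]
        if len(set(seqs)) != len(seqs):
            raise ValueError("variant sequences must be unique within a clonotype")
        for v in self.variants:
            for fr in v.metadata_fractions.values():
                if fr and abs(sum(fr.values()) - 1.0) > 1e-9:
                    raise ValueError(f"fractions of {v.variant_id} do not sum to 1")


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix over germline + variants.

    ``labels[0]`` is the germline by convention.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------
# AIRR Rearrangement TSV
# ---------------------------------------------------------------------

_AIRR_FIELDS = {
    "sequence_id": "sequence_id",
    "sequence": "sequence_nt",
    "sequence_aa": "sequence_aa",
    "cell_id": "cell_id",
    "v_call": "v_call",
    "j_call": "j_call",
    "junction": "junction_nt",
    "c_call": "c_call",
    "duplicate_count": "duplicate_count",
    "clone_id": "clone_id",
    "germline_alignment": "germline_alignment_nt",
}


def read_airr(path: str | Path, column_map: Mapping[str, str] | None = None,
              source: str = SINGLE_CELL) -> list[SequenceRecord]:
    """Read an AIRR Rearrangement TSV into sequence records.

    ``column_map`` maps AIRR standard column names to the file's actual
    headers for dialects with nonstandard naming. Rows lacking a
    sequence_id or sequence are skipped; the skip count is logged.
    Unrecognized columns are carried in ``record.extras``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = dict(column_map or {})
    resolved = {std: colmap.get(std, std) for std in _AIRR_FIELDS}
    for required in ("sequence_id", "sequence"):
        if resolved[required] not in df.columns:
            raise FormatError(f"required column {resolved[required]!r} absent from {path}")

    known_cols = set(resolved.values())
    records: list[SequenceRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        seq = row.get(resolved["sequence"], "")
        sid = row.get(resolved["sequence_id"], "")
        if not seq or not sid:
            skipped += 1
            continue
        dup = row.get(resolved["duplicate_count"], "") or "1"
        extras = {c: row[c] for c in df.columns if c not in known_cols}
        records.append(SequenceRecord(
            sequence_id=sid,
            sequence_nt=seq.upper(),
            sequence_aa=row.get(resolved["sequence_aa"], ""),
            cell_id=row.get(resolved["cell_id"], ""),
            v_call=row.get(resolved["v_call"], ""),
            j_call=row.get(resolved["j_call"], ""),
            junction_nt=row.get(resolved["junction"], "").upper(),
            c_call=row.get(resolved["c_call"], ""),
            duplicate_count=int(float(dup)),
            clone_id=row.get(resolved["clone_id"], ""),
            germline_alignment_nt=row.get(resolved["germline_alignment"], "").upper(),
            source=source,
            extras=extras,
        ))
    if skipped:
        logger.warning("read_airr: skipped %d rows lacking sequence_id/sequence", skipped)
    return records


def write_airr(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records back to AIRR Rearrangement TSV (standard columns)."""
    rows = []
    for r in records:
        row = {airr: getattr(r, attr) for airr, attr in _AIRR_FIELDS.items()}
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------
# Clonotype assembly
# ---------------------------------------------------------------------

def junction_identity(a: str, b: str) -> float:
    """Alignment-free per-position identity of two equal-length junctions."""
    if len(a) != len(b):
        return 0.0
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _gene(call: str) -> str:
    """Strip the allele suffix from a V/J call (IGHV1-1*01 -> IGHV1-1)."""
    return call.split("*")[0].split(",")[0].strip()


def group_clonotypes(records: Sequence[SequenceRecord], strategy: str = "use_clone_id",
                     identity_threshold: float = DEFAULT_JUNCTION_IDENTITY,
                     ) -> tuple[list[Clonotype], list[SequenceRecord]]:
    """Partition records into clonotypes.

    Strategies:

    ``use_clone_id``
        trust the caller-provided ``clone_id`` column.
    ``vjl``
        same V gene, same J gene, equal junction length, and junction
        nucleotide identity >= ``identity_threshold`` (single-linkage).

    Records without a germline alignment (or without the keys the strategy
    needs) land in the returned ``unassigned`` list. Within a clonotype,
    identical sequences collapse into one variant whose cell count is the
    number of distinct cells (single-cell) or the summed duplicate counts
    (bulk); per-cell labels (isotype from ``c_call``) become metadata
    fractions.
    """
    if strategy not in ("use_clone_id", "vjl"):
        raise ValueError(f"unknown clonotyping strategy {strategy!r}")

    unassigned: list[SequenceRecord] = []
    groups: dict[str, list[SequenceRecord]] = {}

    if strategy == "use_clone_id":
        for r in records:
            if not r.clone_id or not r.germline_alignment_nt:
                unassigned.append(r)
            else:
                groups.setdefault(r.clone_id, []).append(r)
    else:
        buckets: dict[tuple, list[SequenceRecord]] = {}
        for r in records:
            if not r.v_call or not r.j_call or not r.junction_nt or not r.germline_alignment_nt:
                unassigned.append(r)
                continue
            key = (_gene(r.v_call), _gene(r.j_call), len(r.junction_nt))
            buckets.setdefault(key, []).append(r)
        gid = 0
        for key in sorted(buckets, key=str):
            members = buckets[key]
            # single-linkage clustering on junction identity
            parent = list(range(len(members)))

            def find(i: int) -> int:
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if junction_identity(members[i].junction_nt,
                                         members[j].junction_nt) >= identity_threshold:
                        parent[find(i)] = find(j)
            comps: dict[int, list[SequenceRecord]] = {}
            for i, r in enumerate(members):
                comps.setdefault(find(i), []).append(r)
            for root in sorted(comps):
                gid += 1
                groups[f"clonotype_{gid}"] = comps[root]

    clonotypes = [_assemble_clonotype(cid, recs) for cid, recs in groups.items()]
    total = sum(sum(len(v.cell_ids) or 1 for v in c.variants) for c in clonotypes)
    logger.info("group_clonotypes: %d clonotypes, %d unassigned of %d records",
                len(clonotypes), len(unassigned), len(records))
    del total
    return clonotypes, unassigned


def _assemble_clonotype(clonotype_id: str, recs: list[SequenceRecord]) -> Clonotype:
    germlines = [r.germline_alignment_nt for r in recs if r.germline_alignment_nt]
    germline = max(set(germlines), key=germlines.count) if germlines else ""
    by_seq: dict[str, list[SequenceRecord]] = {}
    for r in recs:
        by_seq.setdefault(r.sequence_nt, []).append(r)
    variants = []
    for i, (seq, members) in enumerate(sorted(by_seq.items(),
                                              key=lambda kv: kv[1][0].sequence_id), 1):
        cells: dict[str, dict[str, str]] = {}
        count = 0
        for m in members:
            if m.source == BULK:
                count += m.duplicate_count
            else:
                if m.cell_id not in cells:
                    count += 1
            labels = {}
            if m.c_call:
                labels["isotype"] = m.c_call
            labels["source"] = m.source
            cells[m.cell_id or m.sequence_id] = labels
        variants.append(Variant(
            variant_id=f"variant_{i}",
            sequence_nt=seq,
            sequence_aa=members[0].sequence_aa,
            cell_count=count,
            cell_ids=sorted(cells),
            cell_labels=cells,
            metadata_fractions=_fractions(cells),
            junction_nt=members[0].junction_nt,
        ))
    return Clonotype(clonotype_id=clonotype_id, germline_nt=germline, variants=variants)


def _fractions(cells: Mapping[str, Mapping[str, str]]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    columns = {col for labels in cells.values() for col in labels}
    for col in columns:
        vals = [labels[col] for labels in cells.values() if col in labels]
        if not vals:
            continue
        out[col] = {lab: vals.count(lab) / len(vals) for lab in sorted(set(vals))}
    return out


def restrict_region(clonotype: Clonotype,
                    region_spec: Sequence[tuple[int, int]] | str) -> Clonotype:
    """Restrict a clonotype to sub-regions of its sequences.

    ``region_spec`` is either a list of 0-based half-open intervals applied
    to germline and every variant (concatenated in the given order), or the
    name of an annotated region (currently ``"junction"``, which substitutes
    each variant's junction; the germline junction is taken from the
    clonotype's ``junction_interval`` annotation). Variants that become
    identical after restriction are merged with summed cell counts.
    """
    if isinstance(region_spec, str):
        if region_spec != "junction":
            raise ValueError(f"unknown named region {region_spec!r}")
        interval = clonotype.annotations.get("junction_interval")
        if interval is None:
            raise ValueError("junction restriction requires a 'junction_interval' annotation")
        new_germ = _slice(clonotype.germline_nt, [tuple(interval)])
        new_seqs = {v.variant_id: (v.junction_nt or _slice(v.sequence_nt, [tuple(interval)]))
                    for v in clonotype.variants}
    else:
        intervals = [(int(a), int(b)) for a, b in region_spec]
        new_germ = _slice(clonotype.germline_nt, intervals)
        new_seqs = {v.variant_id: _slice(v.sequence_nt, intervals)
                    for v in clonotype.variants}

    merged: dict[str, Variant] = {}
    for v in clonotype.variants:
        seq = new_seqs[v.variant_id]
        if seq in {m.sequence_nt for m in merged.values()}:
            target = next(m for m in merged.values() if m.sequence_nt == seq)
            target.cell_count += v.cell_count
            target.cell_ids = sorted(set(target.cell_ids) | set(v.cell_ids))
            target.cell_labels.update(v.cell_labels)
            target.metadata_fractions = _fractions(target.cell_labels)
        else:
            merged[v.variant_id] = Variant(
                variant_id=v.variant_id, sequence_nt=seq, sequence_aa="",
                cell_count=v.cell_count, cell_ids=list(v.cell_ids),
                cell_labels=dict(v.cell_labels),
                metadata_fractions=dict(v.metadata_fractions),
                junction_nt=v.junction_nt)
    return Clonotype(clonotype_id=clonotype.clonotype_id, germline_nt=new_germ,
                     variants=list(merged.values()), chain_scope="region-restricted",
                     annotations=dict(clonotype.annotations))


def _slice(seq: str, intervals: Sequence[tuple[int, int]]) -> str:
    parts = []
    for a, b in intervals:
        if a < 0 or b > len(seq) or a > b:
            raise IndexError(f"interval [{a}, {b}) out of bounds for length {len(seq)}")
        parts.append(seq[a:b])
    return "".join(parts)


# ---------------------------------------------------------------------
# Newick import/export
# ---------------------------------------------------------------------

def read_newick(path_or_handle, germline_label: str = "germline") -> LineageTree:
    """Read a Newick tree and root it on the germline.

    The tree may be multifurcating, carry named internal nodes and branch
    lengths. Unnamed internal nodes are labeled ``inferred_1``,
    ``inferred_2``, ... in parse order and typed as inferred; named nodes
    are sampled. If the germline is a leaf the tree is re-rooted on it and
    its pendant edge becomes the root edge.
    """
    if isinstance(path_or_handle, (str, Path)):
        phylo = Phylo.read(str(path_or_handle), "newick")
    else:
        phylo = Phylo.read(path_or_handle, "newick")

    und = nx.Graph()
    counter = [0]
    names: dict[int, str] = {}

    def label(clade) -> str:
        key = id(clade)
        if key not in names:
            if clade.name:
                names[key] = clade.name
            else:
                counter[0] += 1
                names[key] = f"inferred_{counter[0]}"
        return names[key]

    def walk(clade) -> None:
        lab = label(clade)
        und.add_node(lab, inferred=clade.name is None)
        for child in clade.clades:
            clab = label(child)
            und.add_node(clab, inferred=child.name is None)
            und.add_edge(lab, clab, weight=float(child.branch_length or 0.0))
            walk(child)

    walk(phylo.root)
    if germline_label not in und:
        raise TreeError(f"germline label {germline_label!r} not found in Newick tree")

    # drop a nameless degree-2 original root (artifact of the rooted format)
    old_root = label(phylo.root)
    if (phylo.root.name is None and und.degree(old_root) == 2
            and old_root != germline_label):
        a, b = list(und.neighbors(old_root))
        w = und.edges[old_root, a]["weight"] + und.edges[old_root, b]["weight"]
        und.remove_node(old_root)
        und.add_edge(a, b, weight=w)

    directed = orient_from_root(und, germline_label)

    # renumber inferred nodes in traversal order from the germline so labels
    # do not depend on where the file's arbitrary root sat
    relabel: dict[str, str] = {}
    k = 0
    for n in nx.bfs_tree(directed, germline_label):
        if und.nodes[n].get("inferred"):
            k += 1
            relabel[n] = f"inferred_{k}"
    if relabel:
        directed = nx.relabel_nodes(directed, relabel)
        und = nx.relabel_nodes(und, relabel)

    tree = LineageTree(graph=nx.DiGraph(), root_id=germline_label)
    tree.graph.add_node(germline_label, kind=GERMLINE, sequence_nt="",
                        cell_count=0, metadata_fractions={})
    for n in directed.nodes:
        if n == germline_label:
            continue
        kind = INFERRED if und.nodes[n].get("inferred") else SAMPLED
        tree.graph.add_node(n, kind=kind, sequence_nt="", cell_count=0,
                            metadata_fractions={})
    for u, v, w in directed.edges(data="weight"):
        tree.graph.add_edge(u, v, weight=float(w))
    tree.validate()
    return tree


def write_newick(tree: LineageTree, path_or_handle) -> None:
    """Serialize a lineage tree to Newick (germline as the outermost label)."""
    from Bio.Phylo.Newick import Clade, Tree

    def build(node: str) -> Clade:
        clade = Clade(name=node)
        for child in sorted(tree.children(node)):
            c = build(child)
            c.branch_length = tree.edge_weight(node, child)
            clade.clades.append(c)
        return clade

    phylo = Tree(root=build(tree.root_id), rooted=True)
    if isinstance(path_or_handle, (str, Path)):
        Phylo.write(phylo, str(path_or_handle), "newick", format_branch_length="%.17g")
    else:
        Phylo.write(phylo, path_or_handle, "newick", format_branch_length="%.17g")


def newick_string(tree: LineageTree) -> str:
    buf = _io.StringIO()
    write_newick(tree, buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------
# GraphML / JSON export
# ---------------------------------------------------------------------

_DICT_ATTRS = ("metadata_fractions", "annotations", "cell_ids", "cell_labels")


def write_graphml(tree: LineageTree, path: str | Path) -> None:
    """Export a lineage tree with all node/edge attributes to GraphML.

    Mapping-valued attributes are JSON-encoded (GraphML values are scalar).
    """
    g = nx.DiGraph()
    g.graph["root_id"] = tree.root_id
    g.graph["tree_id"] = tree.tree_id
    g.graph["tree_annotations"] = json.dumps(tree.annotations)
    for n, attrs in tree.graph.nodes(data=True):
        flat = {}
        for k, v in attrs.items():
            flat[k] = json.dumps(v) if isinstance(v, (dict, list)) else v
        g.add_node(n, **flat)
    for u, v, w in tree.edges():
        g.add_edge(u, v, weight=w)
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> LineageTree:
    g = nx.read_graphml(str(path))
    tree = LineageTree(graph=nx.DiGraph(), root_id=g.graph["root_id"],
                       tree_id=g.graph.get("tree_id", "tree"),
                       annotations=json.loads(g.graph.get("tree_annotations", "{}")))
    for n, attrs in g.nodes(data=True):
        parsed = {}
        for k, v in attrs.items():
            if k in _DICT_ATTRS and isinstance(v, str):
                parsed[k] = json.loads(v)
            else:
                parsed[k] = v
        parsed.setdefault("metadata_fractions", {})
        tree.graph.add_node(n, **parsed)
    for u, v, data in g.edges(data=True):
        tree.graph.add_edge(u, v, weight=float(data["weight"]))
    tree.validate()
    return tree


def clonotypes_to_json(clonotypes: Sequence[Clonotype], path: str | Path) -> None:
    payload = [asdict(c) for c in clonotypes]
    Path(path).write_text(json.dumps(payload, indent=1))


def clonotypes_from_json(path: str | Path) -> list[Clonotype]:
    payload = json.loads(Path(path).read_text())
    out = []
    for c in payload:
        variants = [Variant(**v) for v in c.pop("variants")]
        out.append(Clonotype(variants=variants, **c))
    return out


def forest_to_json(trees: Sequence[LineageTree], path: str | Path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in trees], indent=1))


def forest_from_json(path: str | Path) -> list[LineageTree]:
    return [LineageTree.from_dict(d) for d in json.loads(Path(path).read_text())]
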