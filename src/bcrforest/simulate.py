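"""Synthetic clonal lineages with known ground truth.

A seeded branching process emulates somatic hypermutation diversifying a
clonotype from its unmutated germline: each node in generation g spawns a
Poisson(λ) number of children, each child substitutes Binomial(L, μ)
distinct positions of its parent's sequence to a uniformly chosen different
base, nodes are observed with probability ρ (the germline is always kept as
the reference but never as an observed cell), each observed node carries a
geometric number of cells, and isotypes switch one-way along
IgM → IgG → IgA. Substitution-only (no indels), so Hamming distances,
alignments and per-residue likelihood matrices all stay coordinate-
compatible across the whole pipeline. One pseudorandom stream, seeded once,
drives every draw; runs are byte-reproducible.

The matching structure generator lays the germline amino-acid sequence on
an ideal α-helical CA trace and displaces one CA per inherited mutation by
a fixed magnitude in a seeded random direction, so structural divergence
grows monotonically with mutation count by construction — real predicted
structures are obviously not this well behaved, which is exactly what makes
the generator a controllable oracle for the structure module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import SequenceRecord, write_airr, write_fasta
from .structure import Residue, StructureModel, write_pdb, _ONE_TO_THREE
from .tree import GERMLINE, SAMPLED, LineageTree

BASES = "ACGT"
ISOTYPE_CHAIN = ("IgM", "IgG", "IgA")

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt: str) -> str:
    """Translate a nucleotide sequence; stops and partial codons become X."""
    aa = []
    for i in range(0, len(nt) - 2, 3):
        c = CODON_TABLE.get(nt[i:i + 3], "X")
        aa.append("X" if c == "*" else c)
    return "".join(aa)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated clonal lineage.

    Defaults describe a modestly expanded clonotype: a 300-nt V(D)J region,
    mean 1.5 offspring per node over 4 generations, per-site substitution
    probability 0.01 per generation (so ~3 mutations per edge, in the range
    typical of hypermutated memory sequences), 80% sampling, geometric cell
    counts with mean 3, and a 0.2 per-generation isotype switch chance.
    """

    seed: int
    germline_length: int = 300
    branching_rate: float = 1.5
    mutation_rate: float = 0.01
    generations: int = 4
    sampling_fraction: float = 0.8
    cell_count_mean: float = 3.0
    isotype_switch_prob: float = 0.2
    clonotype_id: str = "sim_clonotype"
    max_nodes: int = 400
    junction_interval: tuple[int, int] = (135, 180)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in (0,1)")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0,1]")
        if self.branching_rate < 0:
            raise ValueError("branching_rate must be >= 0")
        j0, j1 = self.junction_interval
        if not (0 <= j0 <= j1 <= self.germline_length):
            raise ValueError("junction_interval out of bounds")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated lineage."""

    config: SimulationConfig
    tree: LineageTree                       # all generated nodes
    observed: list[str]
    edge_mutations: dict[str, list[int]]    # "parent>child" -> positions
    cells: dict[str, list[tuple[str, str]]]  # node -> [(cell_id, isotype)]

    def parent_of(self) -> dict[str, str]:
        return {c: p for p, c, _ in self.tree.edges()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "tree": self.tree.to_dict(),
            "observed": self.observed,
            "edge_mutations": self.edge_mutations,
            "cells": self.cells,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        cfg = d["config"]
        cfg["junction_interval"] = tuple(cfg["junction_interval"])
        return cls(config=SimulationConfig(**cfg),
                   tree=LineageTree.from_dict(d["tree"]),
                   observed=d["observed"],
                   edge_mutations={k: list(v) for k, v in d["edge_mutations"].items()},
                   cells={k: [tuple(c) for c in v] for k, v in d["cells"].items()})


def simulate_lineage(config: SimulationConfig
                     ) -> tuple[list[SequenceRecord], SimulationTruth]:
    """Run the branching-process SHM simulation.

    Returns the AIRR-style records (one per observed cell) and the full
    ground truth. Draw order per run: germline bases, then per generation
    and per parent (in id order): offspring count, then per child its
    mutation count, positions, substituted bases and isotype switch; then
    the observation mask, then per-node cell counts and per-cell isotype
    switches.
    """
    rng = np.random.default_rng(config.seed)
    L = config.germline_length
    # productive rearrangement: an open reading frame without stop codons
    sense = sorted(c for c, a in CODON_TABLE.items() if a != "*")
    codons = [sense[i] for i in rng.integers(0, len(sense), size=L // 3)]
    tail = "".join(BASES[i] for i in rng.integers(0, 4, size=L % 3))
    germline = "".join(codons) + tail

    tree = LineageTree.empty("germline", sequence_nt=germline,
                             tree_id=config.clonotype_id)
    tree.graph.nodes["germline"]["sequence_aa"] = translate(germline)
    seqs = {"germline": germline}
    isotype = {"germline": "IgM"}
    edge_mut: dict[str, list[int]] = {}
    current = ["germline"]
    node_no = 0
    capped = False
    for _ in range(config.generations):
        nxt = []
        for parent in current:
            if tree.n_nodes >= config.max_nodes:
                capped = True
                break
            n_children = int(rng.poisson(config.branching_rate))
            for _ in range(n_children):
                if tree.n_nodes >= config.max_nodes:
                    capped = True
                    break
                node_no += 1
                child = f"node_{node_no}"
                k = int(rng.binomial(L, config.mutation_rate))
                positions = sorted(rng.choice(L, size=k, replace=False)) if k else []
                seq = list(seqs[parent])
                for pos in positions:
                    # substitutions never introduce a stop codon, so every
                    # node stays translatable (a sense alternative always
                    # exists: at most 2 of 3 single-base changes can stop)
                    alternatives = [b for b in BASES if b != seq[pos]]
                    if pos < 3 * (L // 3):
                        c0 = 3 * (pos // 3)
                        codon = seq[c0:c0 + 3]
                        off = pos - c0
                        alternatives = [
                            b for b in alternatives
                            if CODON_TABLE["".join(codon[:off] + [b] + codon[off + 1:])] != "*"
                        ] or alternatives
                    seq[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
                seqs[child] = "".join(seq)
                iso = isotype[parent]
                if (iso != ISOTYPE_CHAIN[-1]
                        and rng.random() < config.isotype_switch_prob):
                    iso = ISOTYPE_CHAIN[ISOTYPE_CHAIN.index(iso) + 1]
                isotype[child] = iso
                tree.add_node(child, kind=SAMPLED, sequence_nt=seqs[child],
                              sequence_aa=translate(seqs[child]))
                tree.add_edge(parent, child, len(positions))
                edge_mut[f"{parent}>{child}"] = [int(p) for p in positions]
                nxt.append(child)
        current = nxt
    if capped:
        import logging
        logging.getLogger("bcrforest").warning(
            "simulate_lineage: node cap %d reached", config.max_nodes)

    non_germ = [n for n in tree.graph.nodes if n != "germline"]
    mask = rng.random(len(non_germ)) < config.sampling_fraction
    observed = [n for n, keep in zip(non_germ, mask) if keep]

    j0, j1 = config.junction_interval
    cells: dict[str, list[tuple[str, str]]] = {}
    records: list[SequenceRecord] = []
    p_geom = 1.0 / config.cell_count_mean
    for node in observed:
        n_cells = int(rng.geometric(p_geom))
        node_cells = []
        for c in range(1, n_cells + 1):
            iso = isotype[node]
            if (iso != ISOTYPE_CHAIN[-1]
                    and rng.random() < config.isotype_switch_prob):
                iso = ISOTYPE_CHAIN[ISOTYPE_CHAIN.index(iso) + 1]
            cell_id = f"{node}_cell{c}"
            node_cells.append((cell_id, iso))
            records.append(SequenceRecord(
                sequence_id=f"{cell_id}_seq",
                cell_id=cell_id,
                sequence_nt=seqs[node],
                sequence_aa=translate(seqs[node]),
                v_call="IGHV1-1*01",
                j_call="IGHJ4*01",
                junction_nt=seqs[node][j0:j1],
                c_call=iso,
                duplicate_count=1,
                clone_id=config.clonotype_id,
                germline_alignment_nt=germline,
            ))
        cells[node] = node_cells
        tree.graph.nodes[node]["cell_count"] = n_cells

    truth = SimulationTruth(config=config, tree=tree, observed=observed,
                            edge_mutations=edge_mut, cells=cells)
    return records, truth


def observed_clonotype(truth: SimulationTruth):
    """Ground-truth clonotype over the observed nodes (bypasses AIRR I/O)."""
    from .io import Clonotype, Variant

    variants = []
    g = truth.tree.graph
    for node in truth.observed:
        cell_list = truth.cells.get(node, [])
        labels = {cid: {"isotype": iso, "source": "single_cell"}
                  for cid, iso in cell_list}
        from .io import _fractions
        variants.append(Variant(
            variant_id=node,
            sequence_nt=g.nodes[node]["sequence_nt"],
            sequence_aa=g.nodes[node].get("sequence_aa", ""),
            cell_count=len(cell_list),
            cell_ids=sorted(labels),
            cell_labels=labels,
            metadata_fractions=_fractions(labels),
        ))
    j0, j1 = truth.config.junction_interval
    return Clonotype(clonotype_id=truth.config.clonotype_id,
                     germline_nt=g.nodes["germline"]["sequence_nt"],
                     variants=variants,
                     annotations={"junction_interval": [j0, j1],
                                  "germline_aa": g.nodes["germline"].get("sequence_aa", "")})


def parent_recovery(truth: SimulationTruth, built: LineageTree) -> float:
    """Fraction of observed nodes whose built parent is their true parent.

    The true parent of an observed node is its nearest *observed* ancestor
    in the ground-truth tree (unsampled intermediates are invisible to any
    reconstruction), falling back to the germline.
    """
    parent = truth.parent_of()
    observed = set(truth.observed)

    def true_parent(node: str) -> str:
        p = parent.get(node, "germline")
        while p != "germline" and p not in observed:
            p = parent.get(p, "germline")
        return p

    hits = total = 0
    for node in truth.observed:
        if node not in built.graph:
            continue
        total += 1
        if built.parent(node) == true_parent(node):
            hits += 1
    return hits / total if total else float("nan")


def simulate_repertoire(seed: int, n_clonotypes: int = 10,
                        **config_overrides) -> list[SimulationTruth]:
    """Independent lineages with per-clonotype seeds derived from ``seed``."""
    truths = []
    for i in range(n_clonotypes):
        cfg = SimulationConfig(seed=(seed * 10_000 + i) % (2**31 - 1),
                               clonotype_id=f"clonotype_{i + 1}",
                               **config_overrides)
        _, truth = simulate_lineage(cfg)
        truths.append(truth)
    return truths


# ---------------------------------------------------------------------
# Structure generator
# ---------------------------------------------------------------------

def _helix_trace(n_residues: int) -> np.ndarray:
    """Ideal α-helix CA trace: 2.3 Å radius, 1.5 Å rise, 100° per residue."""
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def inherited_mutations(truth: SimulationTruth, node: str) -> list[int]:
    """Nucleotide positions mutated anywhere on the germline→node path."""
    parent = truth.parent_of()
    positions: set[int] = set()
    while node in parent:
        p = parent[node]
        positions.update(truth.edge_mutations.get(f"{p}>{node}", []))
        node = p
    return sorted(positions)


def simulate_structures(truth: SimulationTruth, displacement_per_mutation: float = 1.0,
                        out_dir: str | Path | None = None
                        ) -> dict[str, StructureModel]:
    """Synthetic CA-only structures for the germline and observed nodes.

    Each node's trace displaces one CA per inherited nucleotide mutation
    (mapped to its codon's residue) by ``displacement_per_mutation`` Å in a
    seeded random direction; pLDDT values are seeded uniforms in [60, 95].
    Optionally writes one PDB per node.
    """
    if displacement_per_mutation < 0:
        raise ValueError("displacement must be >= 0")
    rng = np.random.default_rng(truth.config.seed + 777)
    g = truth.tree.graph
    n_res = len(g.nodes["germline"].get("sequence_aa")
                or translate(g.nodes["germline"]["sequence_nt"]))
    base = _helix_trace(n_res)

    models: dict[str, StructureModel] = {}
    for node in ["germline"] + list(truth.observed):
        seq_aa = g.nodes[node].get("sequence_aa") or translate(g.nodes[node]["sequence_nt"])
        coords = base.copy()
        for nt_pos in inherited_mutations(truth, node) if node != "germline" else []:
            res_pos = nt_pos // 3
            if res_pos >= n_res:
                continue
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[res_pos] = coords[res_pos] + displacement_per_mutation * direction
        plddt = rng.uniform(60.0, 95.0, size=n_res)
        residues = [Residue(name=_ONE_TO_THREE.get(c, "GLY"), code=c,
                            ca=coords[i], plddt=float(plddt[i]), resid=str(i + 1))
                    for i, c in enumerate(seq_aa)]
        models[node] = StructureModel(node_id=node, chains={"H": residues},
                                      roles={"H": "antibody"})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for node, mdl in models.items():
            write_pdb(mdl, out_dir / f"{node}.pdb")
    return models


def write_outputs(truth: SimulationTruth, records, out_dir: str | Path) -> None:
    """AIRR TSV + truth JSON + FASTA for one simulated lineage."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_airr(records, out_dir / "repertoire.tsv")
    truth.to_json(out_dir / "truth.json")
    seqs = {n: truth.tree.graph.nodes[n]["sequence_nt"]
            for n in ["germline"] + truth.observed}
    write_fasta(seqs, out_dir / "sequences.fasta")
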