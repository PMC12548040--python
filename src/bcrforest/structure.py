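"""Structural evolution across a lineage.

Works on alpha-carbon geometry of predicted antibody structures (PDB
format, with per-residue pLDDT confidence in the temperature-factor column,
as AlphaFold-style predictors emit). Per lineage it quantifies:

* RMSD to the germline structure and along tree edges after optimal
  least-squares superposition (rotation + translation, no reflection),
  and its correlation with mutation counts;
* coarse biophysical properties — mean Kyte–Doolittle hydropathy and
  integer net charge at neutral pH ((K + R) − (D + E), His neutral);
* prediction confidence (mean pLDDT);
* antibody–antigen interface composition under a CA–CA distance cutoff
  (default 5.0 Å) and how it changes relative to the germline.

Residue correspondence is by aligned sequence position, not author
numbering, since predicted models number arbitrarily.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from Bio.PDB import PDBParser, PDBIO, StructureBuilder
from Bio.PDB.Polypeptide import protein_letters_3to1
from Bio.SVDSuperimposer import SVDSuperimposer

from .tree import LineageTree

logger = logging.getLogger("bcrforest")

DEFAULT_INTERFACE_CUTOFF = 5.0

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

_ONE_TO_THREE = {v: k for k, v in protein_letters_3to1.items()}


class StructureError(ValueError):
    """Missing or malformed structural input."""


@dataclass
class Residue:
    name: str            # 3-letter
    code: str            # 1-letter
    ca: np.ndarray       # (3,) Å
    plddt: float
    resid: str           # author number + insertion code


@dataclass
class StructureModel:
    node_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)  # chain -> antibody/antigen/unassigned

    def coords(self, chain_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = chain_ids if chain_ids is not None else sorted(self.chains)
        pts = [r.ca for c in ids for r in self.chains[c]]
        return np.array(pts, dtype=float)

    def sequence(self, chain_id: str) -> str:
        return "".join(r.code for r in self.chains[chain_id])

    def mean_plddt(self, chain_ids: Sequence[str] | None = None) -> float:
        ids = chain_ids if chain_ids is not None else sorted(self.chains)
        vals = [r.plddt for c in ids for r in self.chains[c]]
        return float(np.mean(vals)) if vals else float("nan")

    def chains_with_role(self, role: str) -> list[str]:
        return sorted(c for c, r in self.roles.items() if r == role)


# ---------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------

def read_pdb(path: str | Path, chain_roles: Mapping[str, str] | None = None,
             node_id: str | None = None) -> StructureModel:
    """Read alpha carbons, pLDDT and chain roles from a PDB file.

    Alternate locations resolve to the highest-occupancy conformer (first
    on ties, which Biopython applies); insertion codes are preserved in
    residue ids. Files without any ATOM record are rejected.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    model = StructureModel(node_id=node_id or path.stem)
    if not list(structure.get_models()):
        raise StructureError(f"no ATOM records in {path}")
    n_atoms = 0
    for chain in structure[0]:
        residues = []
        for res in chain:
            if "CA" not in res:
                continue
            ca = res["CA"]
            n_atoms += 1
            het, num, icode = res.id
            code = protein_letters_3to1.get(res.get_resname(), "X")
            residues.append(Residue(
                name=res.get_resname(), code=code,
                ca=np.array(ca.get_coord(), dtype=float),
                plddt=float(ca.get_bfactor()),
                resid=f"{num}{icode.strip()}"))
        if residues:
            model.chains[chain.id] = residues
            model.roles[chain.id] = (chain_roles or {}).get(chain.id, "unassigned")
    if n_atoms == 0:
        raise StructureError(f"no ATOM records with alpha carbons in {path}")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a CA-only model back to PDB (pLDDT into the B-factor column)."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure(model.node_id)
    builder.init_model(0)
    for chain_id in sorted(model.chains):
        builder.init_chain(chain_id)
        builder.init_seg("    ")
        for i, res in enumerate(model.chains[chain_id], 1):
            builder.init_residue(res.name, " ", i, " ")
            builder.init_atom("CA", np.asarray(res.ca, dtype=float), res.plddt,
                              1.0, " ", " CA ", i, "C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------
# Superposition RMSD
# ---------------------------------------------------------------------

def superpose_rmsd(model_a: StructureModel | np.ndarray,
                   model_b: StructureModel | np.ndarray,
                   residue_map: Sequence[tuple[int, int]] | None = None) -> float:
    """RMSD after optimal rigid superposition (Kabsch, reflection excluded).

    Inputs are structure models (CA coordinates of all chains in sorted
    chain order) or raw (N, 3) coordinate arrays. ``residue_map`` pairs
    positions of a with positions of b; by default positions map 1:1 over
    the shared length. At least 3 pairs are required.
    """
    xa = model_a.coords() if isinstance(model_a, StructureModel) else np.asarray(model_a, float)
    xb = model_b.coords() if isinstance(model_b, StructureModel) else np.asarray(model_b, float)
    if residue_map is None:
        n = min(len(xa), len(xb))
        residue_map = [(i, i) for i in range(n)]
    if len(residue_map) < 3:
        raise StructureError("superposition needs at least 3 residue pairs")
    ia = [i for i, _ in residue_map]
    ib = [j for _, j in residue_map]
    sup = SVDSuperimposer()
    sup.set(xa[ia], xb[ib])
    sup.run()
    return float(sup.get_rms())


# ---------------------------------------------------------------------
# Biophysics
# ---------------------------------------------------------------------

def biophysics(sequence_aa: str) -> tuple[float, int]:
    """(mean Kyte–Doolittle hydropathy, integer net charge) of a sequence.

    ``X`` is permitted and excluded from the hydropathy mean. Net charge
    counts (K + R) − (D + E) with histidine neutral.
    """
    if not sequence_aa:
        raise ValueError("empty sequence")
    vals = [KYTE_DOOLITTLE[c] for c in sequence_aa if c in KYTE_DOOLITTLE]
    hydro = float(np.mean(vals)) if vals else float("nan")
    charge = (sequence_aa.count("K") + sequence_aa.count("R")
              - sequence_aa.count("D") - sequence_aa.count("E"))
    return hydro, charge


# ---------------------------------------------------------------------
# Lineage-level report
# ---------------------------------------------------------------------

@dataclass
class LineageStructureReport:
    nodes: pd.DataFrame          # per-node RMSD to germline, pLDDT, biophysics
    edges: pd.DataFrame          # per-edge RMSD and edge weight
    correlations: dict[str, float | str]
    skipped: list[str]


def lineage_structure_report(tree: LineageTree,
                             structures: Mapping[str, StructureModel]
                             ) -> LineageStructureReport:
    """Structural divergence across one lineage tree.

    Per node: CA RMSD to the germline structure, mean pLDDT, mean
    hydropathy and net charge of the node's amino-acid sequence (falling
    back to the structure's chain sequence). Per edge: RMSD between the
    connected structures and the edge weight (mutation count). Correlations
    (Spearman): edge RMSD vs edge weight, and node RMSD-to-germline vs
    weighted germline distance; zero-variance cases are reported as such.
    Nodes without structures are skipped and listed.
    """
    if tree.root_id not in structures:
        raise StructureError("germline structure is required")
    germ = structures[tree.root_id]
    skipped = [n for n in tree.graph.nodes if n not in structures]

    node_rows = []
    for n in tree.graph.nodes:
        if n not in structures:
            continue
        mdl = structures[n]
        seq = tree.graph.nodes[n].get("sequence_aa") or "".join(
            mdl.sequence(c) for c in sorted(mdl.chains))
        hydro, charge = biophysics(seq) if seq else (float("nan"), 0)
        node_rows.append({
            "node_id": n,
            "rmsd_to_germline": superpose_rmsd(germ, mdl),
            "mean_plddt": mdl.mean_plddt(),
            "mean_hydrophobicity": hydro,
            "net_charge": charge,
            "germline_distance": tree.path_weight(n),
        })
    nodes = pd.DataFrame(node_rows).set_index("node_id")

    edge_rows = []
    for u, v, w in tree.edges():
        if u in structures and v in structures:
            edge_rows.append({"parent": u, "child": v, "weight": w,
                              "rmsd": superpose_rmsd(structures[u], structures[v])})
    edges = pd.DataFrame(edge_rows)

    corr: dict[str, float | str] = {}
    corr.update(_spearman_or_reason("edge_rmsd_vs_weight",
                                    edges["weight"].tolist() if len(edges) else [],
                                    edges["rmsd"].tolist() if len(edges) else []))
    nn = nodes[nodes.index != tree.root_id]
    corr.update(_spearman_or_reason("node_rmsd_vs_germline_distance",
                                    nn["germline_distance"].tolist(),
                                    nn["rmsd_to_germline"].tolist()))
    return LineageStructureReport(nodes=nodes, edges=edges, correlations=corr,
                                  skipped=sorted(skipped))


def _spearman_or_reason(name: str, x: list, y: list) -> dict:
    if len(x) < 3:
        return {name: "fewer than 3 points"}
    if np.std(x) == 0 or np.std(y) == 0:
        return {name: "zero variance"}
    return {name: float(stats.spearmanr(x, y).statistic)}


# ---------------------------------------------------------------------
# Antibody-antigen interface
# ---------------------------------------------------------------------

@dataclass
class InterfaceReport:
    antibody_residues: set[tuple[str, str]]   # (chain, resid)
    antigen_residues: set[tuple[str, str]]
    size: int
    mean_plddt: float
    mean_hydrophobicity: float
    net_charge: int


def interface_residues(complex_model: StructureModel,
                       cutoff_angstrom: float = DEFAULT_INTERFACE_CUTOFF) -> InterfaceReport:
    """Interface residues of an antibody-antigen complex.

    A residue is at the interface when its CA lies within the cutoff of any
    CA on the opposite side. Summary statistics (size, pLDDT, hydropathy,
    charge) cover the antibody side.
    """
    ab_chains = complex_model.chains_with_role("antibody")
    ag_chains = complex_model.chains_with_role("antigen")
    if not ab_chains or not ag_chains:
        raise StructureError("complex needs >= 1 antibody and >= 1 antigen chain")

    ab = [(c, r) for c in ab_chains for r in complex_model.chains[c]]
    ag = [(c, r) for c in ag_chains for r in complex_model.chains[c]]
    D = cdist(np.array([r.ca for _, r in ab]), np.array([r.ca for _, r in ag]))
    ab_hit = D.min(axis=1) <= cutoff_angstrom
    ag_hit = D.min(axis=0) <= cutoff_angstrom

    ab_res = [r for (c, r), h in zip(ab, ab_hit) if h]
    seq = "".join(r.code for r in ab_res)
    hydro, charge = biophysics(seq) if seq else (float("nan"), 0)
    return InterfaceReport(
        antibody_residues={(c, r.resid) for (c, r), h in zip(ab, ab_hit) if h},
        antigen_residues={(c, r.resid) for (c, r), h in zip(ag, ag_hit) if h},
        size=int(ab_hit.sum()),
        mean_plddt=float(np.mean([r.plddt for r in ab_res])) if ab_res else float("nan"),
        mean_hydrophobicity=hydro,
        net_charge=charge,
    )


def interface_change_vs_germline(germline: StructureModel, variant: StructureModel,
                                 cutoff_angstrom: float = DEFAULT_INTERFACE_CUTOFF) -> dict:
    """Gained and lost antibody interface residues relative to the germline."""
    gi = interface_residues(germline, cutoff_angstrom).antibody_residues
    vi = interface_residues(variant, cutoff_angstrom).antibody_residues
    return {"gained": sorted(vi - gi), "lost": sorted(gi - vi),
            "retained": sorted(gi & vi)}
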