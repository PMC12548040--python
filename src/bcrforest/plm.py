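"""Protein-language-model likelihoods along a lineage.

A PLM scores every residue of an antibody sequence with a probability over
the 20 amino acids. This module consumes such per-residue likelihood
matrices exported by *any* model (ESM-style general models, antibody
models, custom fine-tunes — there are no model-specific code paths),
attaches them to tree nodes, and relates them to the tree:

* the **pseudolikelihood** of a sequence is the mean natural-log
  probability of the observed residue per position — a mean rather than a
  sum so values stay comparable across variants of different lengths;
* along an edge, positions are classed as mutated or conserved and the
  parent's and child's probabilities of the relevant residues (plus the
  child residue's rank in the parent row) quantify which substitutions the
  model considered likely;
* across a tree, pseudolikelihood is correlated with weighted distance
  from the germline to ask whether somatic hypermutation moves sequences
  toward or away from what the model deems plausible.

Probabilities are floored at 1e-12 before taking logs (PLM exports can
contain exact zeros).

A stand-in scorer (additive-smoothed column frequencies of the lineage
alignment) generates valid matrices for testing and pipeline dry runs; it
is a synthetic substrate, not a model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import INFERRED, LineageTree

logger = logging.getLogger("bcrforest")

#: fixed alphabet order for likelihood CSV columns
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROB_FLOOR = 1e-12


class AlphabetError(ValueError):
    """Residue outside the 20-letter amino-acid alphabet."""


@dataclass
class ResidueLikelihoods:
    node_id: str
    matrix: np.ndarray                 # positions x 20, rows sum to 1
    alphabet: str = AMINO_ACIDS
    pseudolikelihood: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.alphabet):
            raise ValueError("matrix must be positions x alphabet")

    def row_sums_valid(self, tol: float = 1e-6) -> bool:
        return bool(np.all(np.abs(self.matrix.sum(axis=1) - 1.0) <= tol))


def pseudolikelihood(sequence_aa: str, matrix: np.ndarray,
                     alphabet: str = AMINO_ACIDS) -> float:
    """Mean ln-probability of the observed residue per position."""
    matrix = np.asarray(matrix, dtype=float)
    if len(sequence_aa) != matrix.shape[0]:
        raise ValueError(f"sequence length {len(sequence_aa)} != matrix rows {matrix.shape[0]}")
    idx = []
    for c in sequence_aa:
        j = alphabet.find(c)
        if j < 0:
            raise AlphabetError(f"residue {c!r} outside alphabet")
        idx.append(j)
    probs = np.maximum(matrix[np.arange(len(idx)), idx], PROB_FLOOR)
    return float(np.mean(np.log(probs)))


def load_likelihoods(source: str | Path | Mapping[str, str | Path],
                     tree: LineageTree) -> dict[str, ResidueLikelihoods]:
    """Load per-node likelihood CSVs and attach pseudolikelihoods.

    ``source`` is a directory containing ``<node_id>.csv`` files or an
    explicit mapping node_id -> path. Each CSV has the 20 amino-acid
    letters as header and one row per position. Rows off unit mass by up to
    1e-3 are renormalized with a warning; beyond that the file is rejected.
    Nodes whose matrix length mismatches their sequence are reported and
    skipped.
    """
    if isinstance(source, (str, Path)):
        paths = {p.stem: p for p in sorted(Path(source).glob("*.csv"))}
    else:
        paths = {k: Path(v) for k, v in source.items()}

    out: dict[str, ResidueLikelihoods] = {}
    for node_id, path in paths.items():
        if node_id not in tree.graph.nodes:
            logger.warning("load_likelihoods: %s has no matching tree node", node_id)
            continue
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c in AMINO_ACIDS]
        if sorted(cols) != sorted(AMINO_ACIDS):
            raise ValueError(f"{path}: header must be the 20 amino-acid letters")
        mat = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
        sums = mat.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-3
        if bad.any():
            raise ValueError(f"{path}: {int(bad.sum())} rows deviate from unit mass by >1e-3")
        if np.any(np.abs(sums - 1.0) > 1e-6):
            logger.warning("load_likelihoods: renormalizing %s rows of %s",
                           int(np.sum(np.abs(sums - 1.0) > 1e-6)), path.name)
            mat = mat / sums[:, None]
        rl = ResidueLikelihoods(node_id=node_id, matrix=mat)
        seq = tree.graph.nodes[node_id].get("sequence_aa", "")
        if seq:
            if len(seq) != mat.shape[0]:
                logger.warning("load_likelihoods: %s matrix has %d rows but sequence "
                               "has %d residues; skipped", node_id, mat.shape[0], len(seq))
                continue
            try:
                rl.pseudolikelihood = pseudolikelihood(seq, mat)
            except AlphabetError:
                logger.warning("load_likelihoods: %s contains residues outside the "
                               "alphabet; pseudolikelihood omitted", node_id)
                rl.pseudolikelihood = None
        out[node_id] = rl
    return out


# ---------------------------------------------------------------------
# Edge-level substitution analysis
# ---------------------------------------------------------------------

def edge_substitution_profile(tree: LineageTree,
                              likelihoods: Mapping[str, ResidueLikelihoods],
                              edge: tuple[str, str]) -> pd.DataFrame:
    """Per-position likelihood report along one parent→child edge.

    Both sequences must be aligned (equal length). Gap characters in
    either sequence are classed ``indel`` and excluded from the
    mutated/conserved classes (PLM rows do not cover gaps). For each
    position the report carries the parent's probability of its own and of
    the child's residue, the child's probability of its residue, and the
    rank of the child residue within the parent's row (1 = most likely).
    """
    parent, child = edge
    pseq = tree.graph.nodes[parent].get("sequence_aa", "")
    cseq = tree.graph.nodes[child].get("sequence_aa", "")
    if len(pseq) != len(cseq):
        raise ValueError("edge profile requires aligned (equal-length) sequences")
    pl, cl = likelihoods[parent], likelihoods[child]

    rows = []
    for i, (pa, ca) in enumerate(zip(pseq, cseq)):
        if pa not in AMINO_ACIDS or ca not in AMINO_ACIDS:
            rows.append({"position": i, "parent_res": pa, "child_res": ca,
                         "klass": "indel", "p_parent_parent": np.nan,
                         "p_parent_child": np.nan, "p_child_child": np.nan,
                         "child_rank_in_parent": np.nan})
            continue
        prow = pl.matrix[i]
        ranks = stats.rankdata(-prow, method="min")
        rows.append({
            "position": i, "parent_res": pa, "child_res": ca,
            "klass": "mutated" if pa != ca else "conserved",
            "p_parent_parent": float(prow[AMINO_ACIDS.index(pa)]),
            "p_parent_child": float(prow[AMINO_ACIDS.index(ca)]),
            "p_child_child": float(cl.matrix[i][AMINO_ACIDS.index(ca)]),
            "child_rank_in_parent": int(ranks[AMINO_ACIDS.index(ca)]),
        })
    df = pd.DataFrame(rows)
    df.attrs["aggregates"] = (
        df[df.klass != "indel"]
        .groupby("klass")[["p_parent_parent", "p_parent_child", "p_child_child",
                           "child_rank_in_parent"]]
        .mean().to_dict("index"))
    return df


# ---------------------------------------------------------------------
# Likelihood vs evolutionary distance
# ---------------------------------------------------------------------

def likelihood_vs_evolution(forest: Sequence[LineageTree],
                            likelihoods: Mapping[str, Mapping[str, ResidueLikelihoods]]
                            ) -> pd.DataFrame:
    """Correlate node pseudolikelihood with weighted distance from germline.

    ``likelihoods`` maps tree_id -> node_id -> ResidueLikelihoods. Per tree
    (and pooled) the report carries Spearman and Pearson correlations with
    the sample size; trees with fewer than 3 scored nodes, or with zero
    variance in either variable, get empty correlations and a reason.
    """
    rows = []
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    for tree in forest:
        ldict = likelihoods.get(tree.tree_id, {})
        pts = [(tree.path_weight(n), rl.pseudolikelihood)
               for n, rl in sorted(ldict.items())
               if rl.pseudolikelihood is not None and tree.kind(n) != INFERRED]
        x = [p[0] for p in pts]
        y = [p[1] for p in pts]
        pooled_x += x
        pooled_y += y
        rows.append(_corr_row(tree.tree_id, x, y))
    rows.append(_corr_row("pooled", pooled_x, pooled_y))
    return pd.DataFrame(rows)


def _corr_row(label: str, x: list[float], y: list[float]) -> dict:
    row = {"tree_id": label, "n": len(x), "spearman": np.nan, "pearson": np.nan,
           "reason": ""}
    if len(x) < 3:
        row["reason"] = "fewer than 3 points"
        return row
    if np.std(x) == 0 or np.std(y) == 0:
        row["reason"] = "zero variance"
        return row
    row["spearman"] = float(stats.spearmanr(x, y).statistic)
    row["pearson"] = float(stats.pearsonr(x, y).statistic)
    return row


# ---------------------------------------------------------------------
# Stand-in scorer (synthetic test substrate)
# ---------------------------------------------------------------------

def standin_scorer(clonotype_alignment: Mapping[str, str]) -> dict[str, ResidueLikelihoods]:
    """Synthetic per-residue scorer: smoothed lineage column frequencies.

    For each alignment column the probability of residue a is
    ``(count(a) + 1) / (n_sequences + 20)`` (add-one smoothing over the
    20-letter alphabet); every node receives the same matrix. This stands
    in for an external PLM in tests and examples only.
    """
    seqs = {k: v for k, v in clonotype_alignment.items()}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("stand-in scorer requires an aligned clonotype")
    L = lengths.pop()
    n = len(seqs)
    mat = np.ones((L, len(AMINO_ACIDS)))  # pseudo-count 1
    for s in seqs.values():
        for i, c in enumerate(s):
            j = AMINO_ACIDS.find(c)
            if j >= 0:
                mat[i, j] += 1
    mat = mat / mat.sum(axis=1, keepdims=True)
    out = {}
    for node_id, seq in seqs.items():
        rl = ResidueLikelihoods(node_id=node_id, matrix=mat.copy())
        try:
            rl.pseudolikelihood = pseudolikelihood(seq, mat)
        except AlphabetError:
            rl.pseudolikelihood = None
        out[node_id] = rl
    return out


def write_likelihood_csv(rl: ResidueLikelihoods, path: str | Path) -> None:
    pd.DataFrame(rl.matrix, columns=list(AMINO_ACIDS)).to_csv(path, index=False)
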