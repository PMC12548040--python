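# bcrforest

Germline-rooted B-cell lineage trees from immune-repertoire sequencing:
reconstruction, topology metrics, tree comparison, protein-language-model
likelihoods and structural evolution.

## The problem

During an immune response, B cells descending from one V(D)J recombination
event diversify by somatic hypermutation (SHM) into a *clonotype*: a cloud
of antibody variants around an unmutated germline reference. The
evolutionary history of a clonotype is naturally a **germline-rooted
lineage tree** whose nodes are unique antibody sequences (observed variants
may be internal, not only leaves, and multifurcations are common) and whose
edge weights measure mutational separation. Repertoire-scale questions —
which lineages show signatures of selection, whether two repertoires evolve
similarly, how SHM moves sequences relative to what a protein language
model (PLM) deems plausible, and how predicted structures diverge as
mutations accumulate — all reduce to building, describing and comparing
collections ("forests") of such trees. `bcrforest` is a library + CLI for
exactly that, aimed at computational immunologists working with AIRR-format
single-cell or bulk BCR data.

## What it computes

**Tree construction** (per clonotype, all germline-rooted):

- *default*: iteratively attach the out-of-tree variant with the globally
  smallest distance to any in-tree node; ties resolved by breadth, depth,
  mutational load, clonal expansion, or a seeded random draw;
- *mst*: minimum spanning tree of the complete distance graph;
- *nj*: neighbor joining (negative branch lengths clamped, deficit moved to
  the sibling), re-rooted on the germline;
- *mp*: maximum parsimony (Fitch score, NNI search or exhaustive for ≤ 7
  leaves);
- *ml*: maximum likelihood under JC69/K80 by Felsenstein pruning;
- or import trees from any external tool via Newick.

Bifurcating phylogenies are converted to multifurcating lineage networks by
three inferred-node removal modes (`zero_length_only`,
`replace_by_closest_descendant`, `link_to_parent`).

**Topology metrics**: graph statistics, the Sackin imbalance index
`S = Σ_leaves depth(leaf)`, and the spectral density of the modified graph
Laplacian `M = Diag(row sums) − P` (P = all-pairs patristic distances),
summarized by the principal eigenvalue λ\*, the skewness (asymmetry) and
excess kurtosis (peakedness) of the ln-eigenvalue distribution.

**Tree comparison**: the generalized branch length distance

```
GBLD(T_a, T_b) = P + W,   P = 1 − |L_a ∩ L_b| / |L_a ∪ L_b|,
W = mean_{v ∈ shared} | d_a(v) − d_b(v) |
```

over branch-length-normalized germline-to-node path weights d(v); method
robustness reports; hierarchical clustering + PCA embedding of the
trees × metrics matrix; directed-edge agreement for trees on identical
sequence sets.

**PLM likelihoods**: attach per-residue probability matrices exported by
any model, compute per-sequence pseudolikelihoods (mean ln-probability of
the observed residue), profile mutated vs conserved positions along edges,
and correlate likelihood with evolutionary distance from the germline.

**Structure**: CA-only RMSD to germline and along edges (Kabsch
superposition), Kyte–Doolittle hydropathy, integer net charge, pLDDT
summaries, and antibody–antigen interface composition under a CA–CA
cutoff.

**Simulator**: a seeded SHM branching process with full ground truth
(topology, per-edge mutations, cell counts, isotypes, optional synthetic
structures), so the whole pipeline is testable without external data.

## Worked example

```python
import bcrforest as bf

cfg = bf.SimulationConfig(seed=1)                      # one SHM lineage
records, truth = bf.simulate_lineage(cfg)
clonotype = bf.observed_clonotype(truth)
tree = bf.build_tree(clonotype, bf.BuildConfig(method="default",
                                               distance_metric="hamming"))
m = bf.compute_tree_metrics(tree)
print(f"observed variants: {len(clonotype.variants)}  cells: {len(records)}")
print(f"tree: {m.n_nodes} nodes, {m.n_leaves} leaves, Sackin index {m.sackin}")
print(f"principal eigenvalue: {m.spectral.principal_eigenvalue:.2f}  "
      f"asymmetry: {m.spectral.asymmetry:.3f}  peakedness: {m.spectral.peakedness:.3f}")
rep = bf.robustness_report(clonotype, ["default", "mst", "nj"],
                           removal_mode="link_to_parent")
print(f"robustness (mean GBLD across default/mst/nj): {rep.robustness_score:.4f}")
print(f"parent recovery vs truth: {bf.parent_recovery(truth, tree):.2%}")
```

prints

```
observed variants: 13  cells: 33
tree: 14 nodes, 8 leaves, Sackin index 21
principal eigenvalue: 221.57  asymmetry: 0.311  peakedness: -0.956
robustness (mean GBLD across default/mst/nj): 0.0679
parent recovery vs truth: 84.62%
```

The simulated clonotype has 13 observed variants carried by 33 cells; the
iterative builder reconstructs a 14-node tree whose Sackin index and
spectral summaries describe its imbalance and branching pattern. The mean
pairwise GBLD of 0.07 across three construction methods says the topology
is nearly method-independent for this lineage, and 84.6 % of the inferred
parent assignments match the (partially unobservable) simulated truth.

The same pipeline runs from the shell:

```sh
forest simulate --seed 1 --out simdir/
forest io --airr simdir/repertoire.tsv --out clonotypes.json
forest build --clonotypes clonotypes.json --method nj --out forests.json
forest transform --in forests.json --remove-internal link_to_parent --out lineages.json
forest metrics --in lineages.json --out metrics.csv
forest compare --in metrics.csv --cluster k=2 --out-prefix compared
```

All sequence coordinates are 0-based, half-open.

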