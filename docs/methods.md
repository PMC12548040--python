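# Methods

## Lineage model

A clonotype is modeled as a rooted, edge-weighted, multifurcation-capable
directed tree. The root is always the unmutated germline reference; it is a
reference sequence, never an observed cell. Every other node is either a
*sampled* variant (a unique observed sequence, carrying the number of
supporting cells and per-label cell fractions) or an *inferred* ancestor
introduced by a phylogenetic algorithm (cell count 0). Sampled sequences
may occupy internal positions — in hypermutating lineages, ancestors are
routinely re-sequenced alongside their descendants — which is the main
reason the container is a general rooted tree rather than a leaf-labelled
phylogeny.

## Distances

Hamming distance requires pre-aligned (equal-length) sequences; Levenshtein
(via edlib) accepts any lengths. The ambiguity code `N` matches every base
by default, so sequencing uncertainty does not inflate distances; a flag
switches it to count as a mismatch. Distances are computed on nucleotides
by default. The iterative default builder compares **raw** (not
length-normalized) distances; with equal-length input the two are
equivalent, and raw values keep edge weights interpretable as mutation
counts.

## Construction algorithms

**Iterative default.** Starting from the germline, repeatedly find the
global minimum D[u, v] over in-tree u and out-of-tree v and attach v under
u with edge weight D[u, v]. This is Prim's algorithm on the complete
distance graph, so its output is *a* minimum spanning tree; the value of
the tie-break lies in choosing *which* MST when distances tie. Ties are
resolved in two stages: first the configured criterion applied to the
candidate parent u — breadth (most current descendants), depth (fewest),
mutational load (smallest/largest path weight from the germline), clonal
expansion (largest/smallest cell count) — then lexicographic (v, u) order,
or a seeded uniform draw when `tie_break="random"`. The ordering
(criterion on the parent first, deterministic fallback second) is a design
choice made for reproducibility; only the list of criteria is fixed by the
method's definition.

**MST** uses networkx's Kruskal implementation on the complete graph and
orients edges away from the germline. When all pairwise distances are
distinct the MST is unique and `default` and `mst` provably coincide.

**Neighbor joining** is the standard Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion. Negative branch lengths are clamped to zero
with the deficit transferred to the sibling branch, preserving the joined
pair's summed length and keeping all edge weights valid for downstream
metrics. The unrooted result is re-rooted on the germline leaf (its pendant
edge becomes the root edge). Fewer than three taxa degenerate to direct
germline attachment.

**Maximum parsimony** scores topologies with Fitch's algorithm on
bit-encoded sites (`N` = any base). The search is NNI hill-climbing from
the NJ start topology, first-improvement order, or exhaustive enumeration
of all (2n−5)!! topologies for ≤ 7 leaves. Per-edge weights come from one
deterministic Fitch traceback that prefers retaining the parent state on
ties; tracebacks are not unique, so edge weights are one optimal mutation
assignment among possibly several (their sum can exceed the site-wise
optimum when a state change is forced onto a different edge than the
counting pass assumed).

**Maximum likelihood** supports JC69 and K80 (equal base frequencies, no
rate heterogeneity; κ defaults to 2.0 for K80 and K80 with κ = 1 reduces
exactly to JC69). Likelihoods are computed by Felsenstein pruning; branch
lengths are optimized coordinate-wise by bounded scalar search
(xatol 1e-8) until the log-likelihood gain falls below 1e-6, capped at 20
rounds; topology search is NNI from the NJ start tree, accepting only
strict improvements, so the log-likelihood is monotone across accepted
moves. Richer substitution models are expected to arrive via Newick import
from dedicated phylogenetics tools rather than re-implementation.

## Internal-node removal

`zero_length_only` merges an inferred node with a sampled terminal child at
edge weight ≤ 1e-9 (floating-point Newick tolerance); the terminal inherits
the inferred node's other children. When two terminals tie at zero length
the higher-cell-count one wins and the event is logged.
`replace_by_closest_descendant` promotes each inferred node's nearest
sampled descendant (ties: larger cell count, then id), bottom-up; displaced
siblings re-attach at their original patristic distance from the promoted
node — path weights below the repair are therefore not preserved, which is
inherent to promotion-style repair. `link_to_parent` re-attaches every
sampled node to its closest sampled ancestor at the connecting path weight,
which preserves all germline path weights exactly. Branch lengths are never
re-optimized after removal. Because the mode changes the apparent
trajectory, it is stamped into tree annotations and cross-method
comparisons refuse mixed modes unless explicitly allowed.

## Topology metrics

Sackin's index is the classical unweighted sum of leaf depths (in edges);
weighted depths are reported separately rather than folded in, since the
two answer different questions. The spectral summary builds
M = Diag(row sums) − P from the all-pairs patristic distance matrix P over
*all* nodes (root and inferred included; zero-weight edges nudged to 1e-9).
M is symmetric and its smallest eigenvalue is exactly 0. The density is a
Gaussian KDE with Silverman's bandwidth over the natural log of the
positive eigenvalues, renormalized to unit mass on its reported grid;
asymmetry (skewness) and peakedness (excess kurtosis) are computed on the
ln-eigenvalue *sample*, not the KDE grid, so they are independent of grid
resolution. Trees with fewer than three positive eigenvalues report NaN
summaries, and the spectral block is empty for single-node trees.

## GBLD

The generalized branch length distance is operationalized as P + W over
branch-length-normalized trees: P is one minus the Jaccard overlap of the
sampled label sets (germline excluded — it is present in both trees by
construction), and W is the mean absolute difference of normalized
germline-to-node path weights over shared labels, defined as 0 over an
empty shared set (P already saturates at 1). Inferred nodes never match by
label but contribute to path weights. The measure is symmetric, zero on
identical trees, invariant to uniform branch scaling, and bounded by 2.
Whether the original formulation weights the two components or compares
per-edge rather than root-path lengths is ambiguous in secondary
descriptions; this definition is frozen by the test suite and would be
versioned behind a flag if revised.

## Cross-repertoire comparison

Clustering operates on the trees × metrics matrix: columns are z-scored,
constant or all-missing columns dropped, remaining gaps mean-imputed;
average-linkage hierarchical clustering with Euclidean distance, cut by
cluster count or height; 2-D embedding by exact PCA. Everything is
deterministic. Count-like topology metrics are heavy-tailed across
branching regimes, so callers comparing lineages of very different sizes
should variance-stabilize first (e.g. `np.arcsinh` on the matrix) —
the regime-recovery test and the acceptance script do exactly that.

For trees on identical sequence sets, the edge-agreement report gives the
shared directed parent→child pairs, an agreement fraction (shared edges
over the larger edge set — for two trees on n common nodes this is
shared/(n−1)), the strict Jaccard of the directed edge sets, and per-node
parent agreement.

## PLM likelihoods

Pseudolikelihood is the **mean** (not sum) ln-probability of the observed
residue per position, making values comparable across variants of
different lengths; probabilities are floored at 1e-12 because real PLM
exports contain zeros. The module is model-agnostic: identical CSVs from
any model give identical results. Edge profiles class each aligned position
as mutated, conserved, or indel (gap or non-standard residue in either
sequence; excluded from the two main classes because PLM rows do not cover
them) and report the child residue's probability under both the parent's
and the child's rows — which of the two is "correct" is a modeling choice
the data cannot settle, so both are reported. Germline-bias caveats of
antibody-specific models are a documentation concern only; no
model-specific code paths exist.

The stand-in scorer (add-one-smoothed column frequencies of the lineage
alignment, one shared matrix for all nodes) is a synthetic test substrate.
It produces valid, lineage-correlated matrices, but nothing it does
resembles a trained model's inductive bias; tests passing with it validate
the plumbing and the statistics, not any claim about real PLM behavior.

## Structure

Geometry is alpha-carbon only: robust to predictor side-chain noise and
sufficient for coarse divergence trends; all-atom analysis is out of
scope. Residue correspondence is by aligned sequence position, not author
numbering. Superposition uses least-squares rotation + translation with
reflections disallowed. Hydropathy is the Kyte–Doolittle mean (X excluded);
net charge is integer counting at neutral pH, (K + R) − (D + E) with
histidine neutral — pKa-based models require external tools. The
antibody–antigen interface is defined by a 5.0 Å CA–CA cutoff
(configurable), a deliberately coarse contact definition consistent with
CA-only geometry.

## Simulator

The generator emulates SHM as a seeded branching process: germline drawn
as an open reading frame (sense codons only, so the reference translates
cleanly), Poisson(λ = 1.5) offspring per node over G = 4 generations,
Binomial(L = 300, μ = 0.01) distinct substituted positions per child
(≈ 3 mutations per edge, typical of affinity-maturing lineages),
independent observation with probability ρ = 0.8, geometric cell counts
with mean 3, and one-way IgM→IgG→IgA isotype switching at 0.2 per
generation (per node, then again per cell, giving mixed per-node isotype
fractions). Substitutions are re-drawn to avoid creating stop codons so
every node stays translatable and nucleotide, amino-acid and likelihood
coordinates remain aligned pipeline-wide; substitution-only (no indels) is
a v1 design decision for the same reason. A soft cap of 400 nodes guards
against runaway growth at high λ. One `numpy` Generator seeded once drives
every draw in documented order, so runs are byte-reproducible.

The structure generator places the germline on an ideal α-helix trace
(2.3 Å radius, 1.5 Å rise, 100°/residue) and displaces one CA per
inherited mutation in a seeded random direction; pLDDT is uniform on
[60, 95]. Structural divergence is monotone in mutation count *by
construction* — the generator is an oracle for the structure module's
bookkeeping and statistics, not a model of real conformational change.

What passing tests show, and do not: the simulator has no AID hot-spot
motifs, no selection, no indels, and no realistic isotype biology, so
green tests demonstrate algorithmic correctness on a controlled substrate,
not performance on real repertoires.

## Numerical and scale choices

- Zero-length tolerance 1e-9 on branch lengths throughout.
- Distance-matrix validation: symmetry to `allclose`, zero diagonal to
  1e-12, finite non-negative entries.
- Parent-recovery truth accounts for unobserved intermediates: the true
  parent of an observed node is its nearest *observed* ancestor.
- Test and acceptance problem sizes (6-node matrices against exhaustive
  spanning-tree enumeration, ≤ 7-leaf exhaustive parsimony, 10–20 seeded
  replicates, 10-clonotype repertoires) were chosen as the smallest scales
  at which each property is non-trivially exercised; the whole suite runs
  in well under a minute on one core.

## Known limitations

- Paired heavy/light chains are handled by concatenation with a recorded
  breakpoint; per-chain distance weighting is not supported.
- No bootstrap support, no GTR/codon/antibody-specific substitution models
  (import such trees via Newick instead).
- `replace_by_closest_descendant` does not preserve path weights below the
  repaired node (see above).
- The junction-identity clonotyping threshold (0.85 on equal-length
  nucleotide junctions) follows common repertoire-analysis practice and is
  configurable; no germline reconstruction from V/J references is
  attempted.
- mmCIF input, 3Di alphabets, free-energy and pKa computations are out of
  scope.
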