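# Methods

This note documents the models, conventions and numerical choices behind
`pagamap`, in the order of the pipeline. It states what each default is
and why; every empirical claim below is recomputed by the test suite or
by `scripts/acceptance.py`, never asserted from memory.

## Graph construction

Cells are embedded by PCA (deterministic full SVD; component signs fixed
by the largest-magnitude loading) and connected to their k nearest
neighbors under Euclidean distance. Neighbor search is exact for the
problem sizes this package targets (up to tens of thousands of cells);
distance ties break to the lower cell index so results are reproducible.
The directed kNN relation is symmetrized by union, keeping the larger
weight when both directions exist.

Edge weights come from one of three kernels:

- `exponential` (default): the smooth-kNN weighting of the UMAP family.
  Per cell, w = exp(−(d − ρ)/σ) with ρ the distance to the nearest
  neighbor (local connectivity 1) and σ solved by bisection so the
  weights sum to log2(k). The nearest neighbor always gets weight 1.
- `adaptive_gaussian`: diffusion-map convention,
  w = exp(−d² / (σ_i σ_j)) with σ_i the distance to the ⌈k/2⌉-th
  neighbor. This is the canonical kernel for diffusion pseudotime and
  is the one the pseudotime-recovery experiments use.
- `unit`: weight 1 on every edge (pure topology).

All kernels keep weights in (0, 1]. Defaults: k = 15, PCA to 10
components — enough to span the simulated manifolds with headroom and
the common desk-scale choice for real data.

## The connectivity statistic

For a partitioning into groups of sizes n_i, the abstraction weighs the
group pair (i, j) by θ_ij = min(1, e_ij / ê_ij), with e_ij the observed
inter-edge count (unweighted by default; weighted counting is a flag).
The null model is pluggable; three are built in:

- `knn` (default): ê_ij = k · n_i · n_j / (n_c − 1). Each of the k·n_i
  edge stubs of group i lands on any given other node of its connected
  component (n_c cells) with probability 1/(n_c − 1). Conditioning on
  the component is deliberate: edges can only ever form inside a
  component, so cells of unrelated disconnected parts carry no
  information about the pair. It makes the statistic *exactly*
  invariant to adding or removing detached clusters — the property that
  distinguishes this approach from tree-fitting methods that force
  disconnected clusters into a trajectory. On a connected graph
  n_c = n and the null reduces to the global form.
- `knn_global`: the same with n_c replaced by the total cell count.
  Kept for sensitivity analysis; the invariance above fails under it.
- `degrees`: ê_ij = (d_i n_j + d_j n_i) / (2(n − 1)) with d_i the
  realized summed degree of group i; conditions on degrees rather than
  on k.

θ = 0 whenever e = 0; a degenerate null (ê = 0 with e > 0) yields θ = 1
with a warning. The cap at 1 makes θ read as a confidence. Edges with
θ below a threshold (default 0.01, a CLI parameter — the right value
depends on the noise level and is meant to be swept) are discarded; the
minimum spanning forest under weight 1/θ (Kruskal, ties broken by
lexicographic pair order) extracts the tree skeleton used for path
tracing.

Directed velocity graphs are abstracted by the net-flow ratio
t_ij = (f_ij − f_ji)/(f_ij + f_ji) over arrow counts f; t orients the
undirected edges (sign = direction, magnitude = confidence) and never
creates or removes them.

## Extended diffusion pseudotime

The walk kernel is the graph kernel plus self-similarity K(x,x) = 1,
density-corrected by dividing by the product of endpoint degrees
(diffusion-maps α = 1), then row-normalized. Working with the symmetric
conjugate S = Z^{−1/2} K Z^{−1/2}, the accumulated transition operator
is M = Σ_{λ<1} λ/(1−λ) φ φᵀ over eigenpairs outside the unit eigenspace,
and d(x, y) = ‖M(x,·) − M(y,·)‖₂. On a graph with c connected
components S has a c-dimensional eigenvalue-1 subspace; removing the
whole subspace (tolerance 1e−10; eigenvalues within 1e−6 of 1 are
flagged in a warning as weakly connected structure) makes d well defined
within each component, and cells outside the root's component are
assigned an explicit infinite distance (CSV output writes `inf`).

Including the kernel self-similarity is a deliberate choice: the bare
loop-free walk has eigenvalues near −1 on path-like graphs, and the
resulting parity oscillation makes pseudotime non-monotone at the ends
of a 1-D manifold (reproducible against a dense full-spectrum oracle).
The self-loop shifts the spectrum positive and restores monotonicity;
`include_self=False` exposes the bare walk.

Default spectrum truncation: 10 eigenpairs beyond the unit eigenspace
(dense solve below 1500 cells, Lanczos above). Truncation changes d
only at small scales; the dense-oracle tests run with the full spectrum.

Path tracing orders the cells of consecutive connected groups by d and
reports per-gene expression plus a sliding-window mean of width
max(5, n_cells/50) — a display convention, configurable.

## Embeddings

The coarse abstraction is laid out by a minimal deterministic
Fruchterman–Reingold engine (dense repulsion, attraction proportional to
θ, linear temperature decay, 200 iterations for the small group-level
graphs); connected components are laid out independently and tiled on a
grid. Fine nodes are then seeded uniformly inside axis-aligned squares
centered on their group's coarse position, with the square's edge length
equal to half the Euclidean distance to the nearest coarse neighbor
(half-edge = distance/4). This guarantees disjoint rectangles for any
configuration, since the Chebyshev distance of two centers is at least
their Euclidean distance over √2, which exceeds the sum of half-edges.
A single coarse node gets half-edge 1.0 (warned). The reverse map
places coarse nodes at the coordinate-wise median of their members.

Refinement runs the same engine on the single-cell graph (default 50
iterations, the conventional FR budget; `n_iter=0` returns the
initialization unchanged). `umap_like` uses a sharper 1/d² repulsion
profile of the same engine; adapters to external engines (ForceAtlas2,
UMAP) take any coordinate matrix through `Layout`. Layouts are 2-D.

## Evaluation metrics

**Geodesic KL divergence.** Shortest-path distances between a uniform
sample of cells (default 500) are computed on the high-dimensional kNN
graph and on a kNN graph built in the embedding, with edge length
−log(w) clipped below at 1e−12 (hop-count lengths are available for
unweighted graphs). Both distance sets, restricted to pairs finite in
both spaces, are normalized to distributions and compared with
D_KL(P‖Q). The normalization makes the measure scale-invariant —
proportional distance matrices give exactly 0. A Gaussian-kernel
transform of the distances (bandwidth = median distance) and a
symmetrized divergence are available behind flags; the plain identity
transform is the default because it is parameter-free.

**Topology path score.** Two abstracted graphs are compared through
their path sets. Inferred groups are related to reference nodes by
cell overlap; for every pair of reference leaves (degree ≤ 1, or all
nodes when fewer than two leaves exist) the shortest path between the
best-matching inferred groups is computed and mapped back. Each visited
group contributes the *set* of reference nodes holding at least 5% of
its cells; the pair is consistent when the reference path appears in
order along those sets, and no group lying cleanly inside a single
reference node is visited off the path. With clean one-to-one
associations this reduces to demanding the identical reference-node
sequence. The set-valued form exists because groups at a branch point
genuinely mix the adjacent segments — a hard majority label there is
arbitrary, and under the strict rule a correctly recovered topology can
score 0. Paths are read along the spanning forest of the thresholded
abstraction (the same inverse-connectivity tree used for lineage
skeletons), since branch-point triangles in the raw thresholded graph
legitimately short-cut the trunk group. Disconnection is compared
strictly: a pair connected in one graph and not the other is always
inconsistent.

## The simulator

Ground-truth datasets are piecewise-linear trees in gene space: each
segment of a user-given segment graph is a unit-length straight line in
a random direction (children start where the parent ends, so the
manifold is continuous at branch points; disconnected components are
offset far apart). Cells are sampled along segments — uniformly by
default, or with a Beta density to emulate variable sampling — and
perturbed by isotropic Gaussian noise. `noise_sd` is the magnitude of
the noise *displacement* relative to the segment length (per-gene
sd = noise_sd/√n_genes): a per-gene sd of 0.3 in 50 dimensions would
displace cells by twice the segment length and leave no manifold to
recover. Defaults: 50 genes, 200 cells per segment, noise_sd 0.3 —
at these settings Louvain at resolution 1.0 yields several groups per
segment, so the abstraction is exercised nontrivially.

Extras: `add_disconnected_cluster` appends an isotropic blob at 10×
the manifold diameter (no kNN edge can form across the gap for any
reasonable k); `simulate_arrows` orients every kNN edge from lower to
higher true time and flips each independently with a given probability,
emulating a velocity graph with controllable noise. Expression is
real-valued (post-preprocessing scale) by default; a Poisson emission
mode exercises the count-preprocessing path.

What the simulator does *not* emulate: library-size variation, dropout,
batch effects, curved manifolds (a spline option is not implemented),
or realistic gene-gene correlation structure. Tests passing on this
generator therefore demonstrate the correctness and robustness of the
graph-abstraction machinery, not performance on any particular
experimental protocol.

## Problem sizes and determinism

The test suite and the acceptance script run on simulated datasets of
600–1100 cells, 20-seed repetitions for recovery rates, a 5×4
resolution/seed sweep for the robustness experiment, and 10 paired
seeds for the embedding comparison — sizes chosen so the full suite
completes in a few minutes on one core while leaving the measured
rates' binomial noise visibly below the margins they are compared at.
Every stochastic step (PCA solver, Louvain, layouts, sampling) takes an
explicit seed, and rerunning any pipeline with the same configuration
reproduces byte-identical outputs.

## Known limitations

- The connectivity null assumes the kNN stub count k·n_i approximates
  the group's edge-endpoint budget; heavily weighted counting with the
  `knn` null mixes scales (use the `degrees` null there).
- Louvain determinism relies on seeding Python's global `random` state
  around the igraph call; partitions from other tools should be loaded
  through `load_partition` for full reproducibility.
- The force-directed engine is O(n²) per iteration; beyond ~10⁴ cells
  an external engine (via `Layout`) is the practical route.
- Groups spanning several connected components (possible only with
  external partitions) make the component-conditioned null use the
  union of their components' cells for the pair.
- `select_root` picks the extremal cell of the first diffusion
  component within an annotated group; with no annotation the root is
  a user responsibility, as in any pseudotime method.
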