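# Methods

## Model and assumptions

`nflink` predicts missing links in an undirected simple graph G(V, E) under
the similarity assumption: linked nodes tend to have similar neighbourhoods,
so observed links between *dissimilar* nodes are treated as noise in the
observation rather than as signal.

Each node's feature vector is its row of X = A + I, where A is the 0/1
adjacency matrix. The identity term ensures that two *linked* nodes with
identical neighbourhoods receive identical features (with rows of A alone,
node i's i-th entry is 0 while its twin's is 1). Feature k of node i then
reads "node i is within distance 1 of node k".

For a feature column x, the dissimilarity carried across links is the
quadratic form of the normalized Laplacian L̃ = I − D^(−1/2) A D^(−1/2):

    D(x) = xᵀ L̃ x = Σ_{i~j} (x_i/√d_i − x_j/√d_j)².

The degree normalization weights every node equally; the unnormalized
Laplacian (also provided, `graph.laplacian`) counts each node's feature
d_i times and is dominated by hubs. By Courant–Fischer, the eigenvectors of
L̃ ordered by ascending eigenvalue are the unit directions of minimal
dissimilarity, orthogonal to their predecessors — a graph analogue of
frequency. Noise filtering is low-pass projection: with V_t the first t
eigenvectors,

    Ŝ = V_t V_tᵀ (A + I),    S* = (Ŝ + Ŝᵀ)/2,

and S*'s entries over unlinked pairs are the similarity scores. The
symmetrization is needed because V_t V_tᵀ X is not symmetric in general.
Scores are always computed from the training graph only: held-out links are
unknown at prediction time, so its Laplacian, spectrum and features all come
from E^T.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| t | retained low-frequency eigenvectors, 1 ≤ t ≤ n | CV-selected | see below |
| grid | CV candidates for t | 1 … min(125, n−1) | high cutoffs approach the unfiltered identity; capping keeps the search cheap and the filter meaningful |
| K, repeats | CV folds and repetitions | 10, 5 | keeps CV noise below typical AUC gaps between adjacent t on the synthetic suite |
| ε (LP) | weight of length-3 paths | 10⁻³ | standard quasi-local damping; ε = 0 reduces LP to CN |
| β (Katz) | path-length damping | 0.5/λ_max(A) | halfway to the divergence point β = 1/λ_max; closed form requires β < 1/λ_max |
| n_samples | sampled-AUC comparisons | 10⁵ | standard error ≤ 0.0016; exact mode available whenever the rank bookkeeping fits memory |
| L | precision cutoff | \|E^P\| | the conventional choice; precisions at different f are not comparable because L changes |

Once t is selected it is held fixed across runs and training fractions (the
CV optimum is empirically stable in f), and `run_benchmark` resolves all
method parameters once before its runs rather than re-optimizing per split.
When t is not supplied to a benchmark, CV runs once on the full observed
network; its links are exactly the information available before splitting.

## Numerical choices

- **Degenerate cutoffs.** Real graphs have repeated Laplacian eigenvalues
  (the five-node example already does). If the gap at the cutoff is below
  10⁻⁹ the cutoff is enlarged to absorb the whole tied eigenspace, making
  the projector basis-independent and runs reproducible across linear-algebra
  backends. Score tables record both the requested and effective t and the
  eigen-gap at the cut.
- **Full basis short-circuit.** When the (enlarged) cutoff reaches n the
  projector is the identity, so S* = A + I is returned exactly and every
  unlinked pair scores exactly 0 — no rounding residue.
- **Sign convention.** Each eigenvector's first component of magnitude
  > 10⁻¹² is made positive. With the degeneracy rule this makes the whole
  pipeline deterministic.
- **Isolated nodes.** L̃ rows/columns of degree-0 nodes are identically zero
  (the node contributes no dissimilarity and no frequency content), keeping
  D(x) finite and the spectrum in [0, 2]. Pairs involving nodes isolated in
  the training graph are scored like any other pair: their feature rows are
  unit vectors.
- **Eigensolver.** Dense `eigh` up to n = 5,000; beyond that only the
  needed smallest eigenpairs are computed (`eigsh`), sufficient because the
  cutoff grid is capped at 125.
- **AUC ties** count one half, the only reading under which iid scores give
  AUC = 0.5. Exact mode computes the tallies by binary search over the
  sorted non-existent scores; sampled mode draws pairs with replacement.
- **Precision ties** straddling rank L receive fractional expected credit
  (hypergeometric mean over random tie orders), so precision is
  deterministic given scores. Verified against exhaustive enumeration of
  tie orders on small cases.
- **Benchmark sd** uses ddof = 0, so a single run reports sd = 0; cells are
  formatted `0.6994(162)` with the sd in units of 10⁻⁴.
- **Splits** take |E^T| = round(f·|E|) edges uniformly without replacement
  and keep the full node universe. Training-graph connectivity is *not*
  enforced; splits may isolate probe endpoints, as plain random division
  implies.

## The synthetic generators

The generator suite stands in for real benchmark corpora:

- `erdos_renyi(n, p)` — unstructured null case;
- `pref_attachment(n, m)` — heavy-tailed degrees, grown from a complete
  seed core on m+1 nodes (so |E| = C(m+1,2) + (n−m−1)·m exactly);
- `planted_partition(n, blocks, p_in, p_out)` — the structured fixture: its
  leading non-trivial Laplacian eigenvectors align with the blocks, so a
  low-pass filter has a predictable regularity to recover (defaults used in
  tests: n = 100, 4 blocks, p_in = 0.25, p_out = 0.01, f = 0.9);
- `inject_noise(net, fraction)` — rewires ⌊fraction·|E|⌋ links to random
  non-edges, preserving |E|, emulating observation noise.
- `fig1_network()` — the five-node worked example with two pairs of
  topologically equivalent nodes.

What passing tests on these graphs shows — and does not. Planted
partitions make the "regularity" assumption true by construction; real
interaction networks mix community, hub and motif structure, their noise is
not uniform rewiring, and their degree sequences are far more skewed. The
suite therefore validates correctness of the computation and the *direction*
of the filtering effect, not effect sizes on any real network. Statistics on
problem sizes used throughout the tests (n ≤ 100, ≥ 20 seeds where means are
compared to chance) were chosen so the whole suite completes in well under a
minute while keeping Monte-Carlo error far below the asserted margins.

## Design decisions

- **LP index.** Implemented as A² + εA³ (length-2 plus damped length-3
  paths); ε = 0 gives CN exactly.
- **Adamic–Adar log** is the natural logarithm. A common neighbour in a
  simple graph has degree ≥ 2, so 1/ln d is always finite.
- **Clustering coefficient** is the average *local* clustering (degree < 2
  nodes contribute 0); global transitivity is exposed as a secondary field.
  Degree assortativity is the Pearson correlation of endpoint degrees over
  edges counted in both orientations, NaN when degenerate.
- **Node ordering** is first-appearance order of the input; all matrices
  carry their ordering, so results are label-stable, not order-stable.
  Labels are opaque strings ("007" ≠ "7").
- **Pluggable features.** The filtering pipeline accepts an arbitrary
  feature matrix of matching shape, but the method's own choice X = A + I is
  the default and the only one exercised by the test-bench.
- **Chance-level calibration.** The sampled AUC of iid scores has two error
  sources: the finite score pools (variance (1/n₁ + 1/n₂)/12 for the exact
  AUC of one assignment) and pair-sampling noise (≤ 0.25/n_samples). With a
  ~50-link probe pool the first dominates at sd ≈ 0.04, so calibration
  checks and `scripts/acceptance.py` average over independent score
  assignments and budget both terms.

## Known limitations

- Weighted, directed, bipartite and temporal graphs are out of scope; input
  is coerced to an undirected simple graph.
- Dense n×n matrices throughout: memory is O(n²), aimed at networks up to a
  few thousand nodes.
- Exact AUC enumerates all probe × non-existent comparisons implicitly via
  sorting; for very large sparse graphs use sampled mode.
- CV selection of t refits one eigendecomposition per fold×repeat; at the
  default K = 10, repeats = 5 this is the dominant cost for n ≳ 1,000.
- No statistical testing between methods and no wall-clock profiling; the
  benchmark reports means and dispersions only.
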