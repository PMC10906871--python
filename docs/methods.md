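# Methods

## Model and conventions

A directed circuit of `N` cells is an `N×N` matrix `M` with rows
postsynaptic and columns presynaptic: `M[n, m] ≠ 0` is the connection
from cell `m` onto cell `n`. Every file this package writes repeats
that orientation in a header comment, because a silent transpose flips
the meaning of "recurrent". Autapses (diagonal entries) are excluded
from all costs and metrics: they belong to neither triangle and have no
defined feed-forward/feedback status. Indices are 0-based everywhere,
including output files.

An ordering is a permutation `π`; the reordered matrix is
`R[i, j] = M[π_i, π_j]`, a similarity transform that preserves entry
counts, degree multisets and eigenvalues (the reordered graph is
isomorphic to the original — the conservation tests check exactly
this). An edge is *recurrent under π* when it lands in the strict upper
triangle of `R`, i.e. when its presynaptic cell is placed after its
postsynaptic cell.

## The relaxed objective

The discrete feedback-edge count is a step function of the ordering, so
it is relaxed: each cell gets a continuous position `z_i ∈ [0, N−1]`,
and the total cost `C(z) = L(z) + w·P(z)` is minimized by L-BFGS-B with
analytic gradients and box bounds.

**Recurrency term.** With `Δz = z_pre − z_post + 1` per edge,
`L = (1/ΣM) Σ M[n,m]·[α(Δz) − ½]·H(Δz)` where
`α(x) = 1/(1+e^(−10x/N))` and `H(0) = 1`. The `+1` offset makes the
ideal chain step (`z_pre = z_post − 1`) cost-free; the logistic's
`10/N` slope saturates the penalty so that one very long feedback edge
cannot dominate many short ones. The cost lies in `[0, ½)`.

**Bandwidth term.** `L = (1/N²)(1/ΣM) Σ M[n,m]·Δz²` — mean squared
connection length, for unmasking bands and diagonal blocks.

**Pauli term.** `P = (1/N³) Σ (z_n − rank(z_n))²` with 0-based ordinal
ranks, ties broken by ascending index (stable double argsort). It is
zero exactly on permutations of `0…N−1`, continuous everywhere, and
non-differentiable where two positions swap rank: the one-sided
gradient components there differ by exactly `2/N³` (verified
numerically in the tests). L-BFGS-B tolerates these isolated kinks; an
occasional abnormal line-search termination is downgraded to a warning
and the best-found point is used.

The gradients implemented are the exact derivatives of the costs as
written, including the `1/ΣM` normalization and the `10/N` logistic
chain factor, and are validated against central finite differences at
non-degenerate points (away from `Δz = 0` and rank ties). Folding the
normalization into the gradient only rescales the *effective* Pauli
weight, to which the result is insensitive over a broad range; `w`
(`pauli_weight`, default 1) is exposed for exploration. `w` cannot be
learned jointly with `z` — the optimum would always drive it to zero,
since `P` constrains the representation rather than the data fit.

Weighted matrices are binarized by default (the workflow for weighted
connectomes is: threshold `|w|` at 4 synapses, sort the binary matrix,
re-apply the permutation to the weighted matrix); `use_weights=True`
lets `|w|` enter the cost as per-edge weights instead.

## Optimization protocol

- Initialization: positions uniform on `[0, N−1]`, one seeded generator
  per run; child seeds derive from the master seed via a spawning seed
  sequence, so a best-of-k sweep is deterministic and nested (best-of-k
  results are monotone in k for a fixed master seed).
- Bounds `[0, N−1]`; maximum 15 000 iterations (configurable).
- Convergence tolerance by size: `1e-8` for `N ≤ 100`, `1e-9` to
  `N ≤ 1000`, `1e-10` to `N ≤ 5000`, `1e-11` above — larger circuits
  need tighter tolerances because per-edge cost contributions shrink
  with the normalizations. Overridable per call.
- Permutation extraction: stable argsort of the final positions (ties
  by index), which guarantees a bijection regardless of how well the
  continuous minimum was resolved.
- Best-of-k selection uses the *discrete* criterion — feedback-edge
  count for recurrency, max-|i−j| bandwidth for bandwidth sorts — with
  ties broken by continuous cost, then run order, so results are
  reproducible bit-for-bit.
- Optional per-iteration traces (length cost, Pauli cost, rank switches
  between consecutive iterates) are off by default; memory grows
  linearly with iteration count when enabled.

Recurrence probabilities: over k randomized runs, each edge's
probability is the fraction of runs placing it in the upper triangle.
Since every extracted ordering is strict, exactly one direction of a
reciprocal pair is recurrent per run — the two probabilities sum to 1
by construction. Context breaks the symmetry: embedded reciprocal pairs
usually resolve with one direction near 1 and the other near 0, while
an isolated two-cell loop sits at ½/½. Edges with probability above
0.45 (just under the symmetric ½) are classified recurrent.

## Synthetic circuits

The generators emulate three planted structures, all with zero
diagonal and a seeded generator (bit-identical matrices per seed):

- **triangle** (`n`, `p_lower=0.5`, `p_upper=0.04`, `p_subdiag=1`):
  strict lower triangle Bernoulli(`p_lower`) except the first
  subdiagonal, Bernoulli(`p_subdiag`) — at the default 1 this plants a
  backbone chain through all cells; strict upper triangle
  Bernoulli(`p_upper`) plants sparse recurrent edges. Defaults give a
  50-cell circuit ≈8 % of whose edges are recurrent.
- **band** (`width_frac=0.4`, `p=0.5`): Bernoulli entries inside a
  centered band `|i−j| ≤ round(width_frac·N)/2`. The band is centered
  because a one-sided stripe would conflate bandwidth structure with
  feed-forwardness; both the smooth-index sort and the baselines see
  the same construction, so the comparison is fair either way.
- **block** (`block_frac=0.25`, `p=0.5`): Bernoulli blocks tiled along
  the diagonal, the last block truncated at the matrix edge.

`scramble` applies a random simultaneous row/column permutation and
returns it, so experiments can evaluate recovery in the original
frame. These circuits are Erdős–Rényi within their planted structure;
real connectomes have degree heterogeneity, community structure beyond
the planted kind, and weighted, signed synapses. Passing tests on these
generators therefore demonstrates that the optimizer recovers *planted*
order of the stated kinds, not that any particular biological circuit
will be sorted correctly.

## Evaluation quantities

- `upper_fraction`: strict-upper nonzeros over all off-diagonal
  nonzeros. Normalizing by total edges (not upper-triangle capacity)
  makes original/scrambled/sorted values comparable across densities
  and gives the exact complement identity upper + lower = 1.
- `matrix_bandwidth`: classic max-|i−j| over nonzeros.
- `mean_squared_length`: the bandwidth cost evaluated at integer
  positions — average of `(j − i + 1)²/N²` over edges. Band/block
  recovery is compared on this quantity (relative to the original
  matrix) rather than on max-|i−j|: a block-diagonal matrix barely
  constrains its single farthest entry, so max bandwidth is nearly
  blind to block recovery, and reverse Cuthill-McKee — which optimizes
  the max measure directly — trivially wins on it while losing on the
  aggregate measure in every trial. Both numbers are reported side by
  side by the `benchmark` command.
- `rank_switches`, `reciprocal_pairs`, `count_simple_paths` (directed
  simple paths with a cap on intermediate vertices),
  `threshold_adjacency` (binarize at `|w| ≥ t`, default 4) complete the
  workflow metrics.

## Baselines

Out-degree sorting (descending column counts, stable ties), reverse
Cuthill-McKee on the symmetrized pattern (scipy's implementation,
components concatenated), and a greedy feedback-arc-set sequence
heuristic (peel sinks to the back, sources to the front, otherwise the
vertex maximizing out-degree minus in-degree). The greedy heuristic is
the classic textbook surrogate: its feedback sets are valid (removal
leaves a DAG) and upper-bound the exhaustive optimum, typically
overestimating it — the behavior the comparison is designed to show.
Schur reordering extracts the orthogonal factor of a real Schur
factorization, rounds it, and verifies it is a permutation matrix and
that the resulting reordering is feedback-free; on any cyclic circuit
it raises rather than returning a silently wrong order. The Schur
factor of a nilpotent matrix is not unique, so verification — not
construction — is the correctness guarantee.

## Problem sizes and determinism

The shipped test-and-reproduction workloads use circuits of 8–200
cells with up to 1000 restarts (a 50-cell, 1000-restart probability
matrix takes ~15–20 s on one CPU; single sorts of 200 cells ~40 ms).
The optimizer itself handles thousands of cells; restart counts, sizes
and the tolerance schedule are all exposed. Every entry point takes a
seed, and all randomness (generation, scrambling, initialization)
derives from it.

## Known limitations

- **Very sparse circuits.** The saturating logistic leaves almost no
  gradient on long feedback edges, and the Pauli term's local wells can
  hold such edges in place: on a scrambled bare chain of 20 cells the
  sort reliably gets within 1–3 feedback edges of the (unique)
  feedback-free order but essentially never reaches it, no matter the
  restart count, Pauli weight or tolerance. Dense feed-forward
  circuits (the regime of lower-triangle densities 0.2–0.5) are
  recovered accurately; below roughly 10 % density, prefer the greedy
  feedback-arc-set baseline, which solves DAGs exactly.
- The recurrence-probability classification assumes a binary matrix;
  weighted evidence enters only through prior thresholding (or the
  opt-in weighted cost).
- The best-of-k criterion for bandwidth sorts is max-|i−j|, which can
  be indifferent among orderings that differ on the aggregate
  mean-squared measure.
- The Schur baseline requires exact acyclicity; one cycle anywhere
  makes it fail (by design, loudly).
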