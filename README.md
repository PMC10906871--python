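# smoothindex

Seriation of directed connectivity matrices by continuous relaxation of
vertex indices.

Connectomic reconstructions deliver cell-to-cell connectivity matrices
whose rows and columns arrive in an arbitrary order. Renumbering the
cells along the flow of information makes circuit structure visible:
with rows postsynaptic and columns presynaptic, feed-forward synapses
fall below the main diagonal and recurrent (feedback) synapses above
it, so isolating recurrency becomes a matrix-reordering problem — a
relative of the NP-hard minimum feedback arc set. `smoothindex` is for
systems neuroscientists and network analysts who want to quantify and
identify recurrent connections (or unmask bands and blocks) in directed
circuits of tens to thousands of cells.

## The method

Instead of searching the `N!` discrete orderings, each vertex `i` gets
a real-valued position `z_i` on a continuous axis (its *smooth index*),
and a differentiable cost `C(z) = L(z) + w·P(z)` is minimized with
bound-constrained L-BFGS-B using analytic gradients:

- **Recurrency length term.** For every edge `m → n` let
  `Δz = z_m − z_n + 1`. Then

  `L(z) = (1/ΣM) Σ_n Σ_m M[n,m] · [α(Δz) − ½] · H(Δz)`,

  with `α(x) = 1/(1 + e^(−10x/N))` a saturating logistic and `H` the
  Heaviside step (`H(0) = 1`): each feedback edge pays according to its
  saturated length, so the cost is a smooth proxy for the feedback-edge
  count.
- **Bandwidth length term.** `L(z) = (1/N²)(1/ΣM) Σ M[n,m] · Δz²`, the
  mean squared connection length, which pulls every edge toward a unit
  chain step and exposes bands and diagonal blocks.
- **Pauli term.** `P(z) = (1/N³) Σ_n (z_n − rank(z_n))²`, a
  data-independent exclusion penalty that keeps positions from
  collapsing onto each other; it vanishes exactly on permutations of
  `0…N−1`.

At the minimum, the permutation is read off as the argsort of the
positions and applied as the similarity transform `R = P M P⁻¹`.
Because random initializations land in different local minima,
restarts are aggregated two ways: best-of-k by the discrete criterion
(feedback-edge count or bandwidth), and per-edge *recurrence
probabilities* — the fraction of runs in which an edge lands in the
upper triangle — which classify individual synapses as recurrent
(default threshold 0.45).

Baselines for comparison: out-degree sorting, reverse Cuthill-McKee, a
greedy feedback-arc-set heuristic, and Schur-decomposition reordering
for verified feed-forward circuits.

## Worked example

```python
import numpy as np
from smoothindex import (generate_triangle_matrix, scramble, si_sort,
                         apply_permutation, upper_fraction, recurrence_probability,
                         invert_permutation)

# a 50-cell, mostly feed-forward circuit with a few planted recurrent edges
original = generate_triangle_matrix(50, p_lower=0.5, p_upper=0.04, seed=1)
scrambled, pi = scramble(original, seed=2)
print("original upper fraction:  %.3f" % upper_fraction(original))
print("scrambled upper fraction: %.3f" % upper_fraction(scrambled))

best = si_sort(scrambled, objective="recurrency", runs=10, seed=3)
print("reordered upper fraction: %.3f"
      % upper_fraction(apply_permutation(scrambled, best.permutation)))
print("recurrent edges: original %d, reordered %d"
      % (np.count_nonzero(np.triu(original, 1)), best.recurrent_edge_count))

probs = recurrence_probability(scrambled, runs=200, seed=4)
recovered = apply_permutation(probs.probs, invert_permutation(pi))
hits = ((recovered > 0.45) & (np.triu(original, 1) != 0)).sum()
print("recovered %d of %d planted recurrent edges"
      % (hits, np.count_nonzero(np.triu(original, 1))))
```

prints

```
original upper fraction:  0.063
scrambled upper fraction: 0.492
reordered upper fraction: 0.067
recurrent edges: original 46, reordered 49
recovered 43 of 46 planted recurrent edges
```

Scrambling hides the feed-forward structure (half the edges land above
the diagonal); ten randomized sorts bring the upper fraction back to
the original's level, and thresholding the 200-run recurrence
probabilities pinpoints 43 of the 46 planted recurrent edges.

The same workflow is available from the shell:

```sh
smoothindex generate --kind triangle --n 50 --seed 1 --scramble --out m.csv
smoothindex sort m.csv --runs 10 --seed 3 --perm-out perm.txt
smoothindex probability m.csv --runs 1000 --threshold 0.45
smoothindex benchmark --algorithms si,outdegree,fas --sizes 50,200
```

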