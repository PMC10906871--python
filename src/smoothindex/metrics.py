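"""Evaluation metrics for seriation results.

All metrics use the matrix convention of the rest of the package:
rows are postsynaptic, columns are presynaptic, so a nonzero entry in
the strict upper triangle is a feedback (recurrent) connection under
the current ordering.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .exceptions import DegenerateMatrixError, ShapeError

__all__ = [
    "upper_fraction",
    "matrix_bandwidth",
    "mean_squared_length",
    "rank_switches",
    "reciprocal_pairs",
    "count_simple_paths",
    "threshold_adjacency",
]


def _square(M) -> np.ndarray:
    A = np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"expected a square matrix, got shape {A.shape}")
    return A


def upper_fraction(M) -> float:
    """Fraction of off-diagonal nonzeros lying in the strict upper triangle.

    Normalizing by all off-diagonal nonzeros (rather than by upper
    capacity) makes the value comparable across densities and invariant
    partners sum to one: upper + lower fraction = 1 for any reordering.
    """
    A = _square(M)
    upper = np.count_nonzero(np.triu(A, 1))
    lower = np.count_nonzero(np.tril(A, -1))
    if upper + lower == 0:
        raise DegenerateMatrixError("matrix has no off-diagonal edges")
    return upper / (upper + lower)


def matrix_bandwidth(M) -> int:
    """Maximum ``|i - j|`` over nonzero entries; 0 if the pattern is
    empty or diagonal-only."""
    A = _square(M)
    i, j = np.nonzero(A)
    if len(i) == 0:
        return 0
    return int(np.abs(i - j).max())


def mean_squared_length(M) -> float:
    """Mean squared connection length of a matrix under its current order.

    For each off-diagonal edge at entry ``[post i, pre j]`` the length
    is ``j - i + 1`` (presynaptic index minus postsynaptic index, offset
    so a unit chain step scores zero); the squared lengths are averaged
    over edges and normalized by ``N**2``.  This is the quantity the
    bandwidth objective minimizes, evaluated at integer positions, and
    the comparison measure for band/block structure recovery: unlike
    the max-|i-j| bandwidth it rewards concentrating *all* edges near
    the diagonal, not only the single farthest one.
    """
    A = _square(M)
    n = A.shape[0]
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    i, j = np.nonzero(B)
    if len(i) == 0:
        raise DegenerateMatrixError("matrix has no off-diagonal edges")
    d = j.astype(float) - i.astype(float) + 1.0
    return float((d * d).mean() / (n * n))


def rank_switches(z_prev, z_curr) -> int:
    """Number of vertices whose ordinal rank changed between two
    position vectors (ties broken by index, consistently on both)."""
    a = np.asarray(z_prev, dtype=float)
    b = np.asarray(z_curr, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError(f"position vectors must be 1-d and equal length, got {a.shape} vs {b.shape}")
    from .costs import ranks

    return int(np.count_nonzero(ranks(a) != ranks(b)))


def reciprocal_pairs(M) -> set[frozenset]:
    """Unordered pairs {a, b} connected in both directions."""
    A = _square(M)
    both = (A != 0) & (A.T != 0)
    np.fill_diagonal(both, False)
    i, j = np.nonzero(np.triu(both, 1))
    return {frozenset((int(a), int(b))) for a, b in zip(i, j)}


def count_simple_paths(M, src: int, dst: int, max_intermediate: int) -> int:
    """Number of directed simple paths from ``src`` to ``dst`` with at
    most ``max_intermediate`` interior vertices.

    Edges follow the connectivity convention: ``M[n, m]`` is the edge
    ``m -> n``.  A path of k interior vertices has k+1 edges, so the
    search depth is capped at ``max_intermediate + 1`` edges.
    """
    A = _square(M)
    n = A.shape[0]
    if not (0 <= src < n and 0 <= dst < n):
        raise IndexError(f"src/dst out of range for n={n}: {src}, {dst}")
    if src == dst:
        raise ValueError("src and dst must differ (simple paths exclude cycles)")
    if max_intermediate < 0:
        raise ValueError(f"max_intermediate must be >= 0, got {max_intermediate}")
    # transpose: networkx reads entry [i, j] as edge i -> j
    G = nx.from_numpy_array((A != 0).T.astype(int), create_using=nx.DiGraph)
    return sum(1 for _ in nx.all_simple_paths(G, src, dst, cutoff=max_intermediate + 1))


def threshold_adjacency(W, t: int = 4) -> np.ndarray:
    """Binarize a weighted matrix: 1 where ``|W| >= t``, else 0.

    Signs (excitatory/inhibitory) are discarded; the default of 4
    synapses suppresses weak, possibly spurious connections before
    seriation while the weighted matrix can be re-displayed afterwards
    with the same ordering.
    """
    if t < 1:
        raise ValueError(f"threshold must be >= 1, got {t}")
    A = _square(W)
    return (np.abs(A) >= t).astype(float)
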