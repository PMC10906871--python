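"""Reference reordering algorithms for comparison with smooth-index sorting.

* :func:`outdegree_sort` — topological-style ordering by descending
  out-degree; fast and a common first pass on connectomes.
* :func:`reverse_cuthill_mckee` — the standard bandwidth-reduction
  ordering, applied to the symmetrized pattern.
* :func:`greedy_fas` — the classic greedy sequence heuristic for the
  minimum feedback arc set (iteratively peel sinks to the back, sources
  to the front, otherwise the vertex with maximal out-degree minus
  in-degree).  This is a standard surrogate heuristic, not any specific
  published FAS implementation.
* :func:`schur_permutation` — extract an ordering from the orthogonal
  factor of a real Schur factorization; valid only for circuits that
  are genuinely feed-forward (permutation-similar to a triangular
  matrix), and verified to be so.

All functions return permutations in the same convention as
:func:`smoothindex.optimize.apply_permutation`: the reordered matrix is
``M[pi][:, pi]``.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import reverse_cuthill_mckee as _rcm

from .costs import as_matrix
from .exceptions import NotFeedForwardError

__all__ = [
    "outdegree_sort",
    "reverse_cuthill_mckee",
    "greedy_fas",
    "schur_permutation",
]


def outdegree_sort(M) -> np.ndarray:
    """Order vertices by descending out-degree, ties by ascending index.

    With columns presynaptic, the out-degree of vertex ``m`` is the
    number of off-diagonal nonzeros in column ``m``.
    """
    A = as_matrix(M).copy()
    np.fill_diagonal(A, 0.0)
    out = np.count_nonzero(A, axis=0)
    return np.argsort(-out, kind="stable")


def reverse_cuthill_mckee(M) -> np.ndarray:
    """Reverse Cuthill-McKee ordering of the symmetrized pattern.

    Disconnected components are ordered one after the other, as in the
    standard sparse-matrix implementation.
    """
    A = as_matrix(M)
    pattern = ((A != 0) | (A.T != 0)).astype(np.int8)
    np.fill_diagonal(pattern, 0)
    perm = _rcm(scipy.sparse.csr_matrix(pattern), symmetric_mode=True)
    return np.asarray(perm, dtype=np.intp)


def greedy_fas(M):
    """Greedy sequence heuristic for the minimum feedback arc set.

    Returns ``(pi, feedback)`` where ``pi`` is the vertex sequence and
    ``feedback`` the set of ``(post, pre)`` edges pointing backwards in
    it; removing those edges leaves a DAG.  The feedback count
    upper-bounds (never undercuts) the true minimum.
    """
    A = as_matrix(M)
    n = A.shape[0]
    pattern = A != 0
    np.fill_diagonal(pattern, False)
    # succ[m] = targets of m (rows with entry in column m); pred[n] = sources
    succ = [set(np.nonzero(pattern[:, m])[0]) for m in range(n)]
    pred = [set(np.nonzero(pattern[n_, :])[0]) for n_ in range(n)]

    remaining = set(range(n))
    front: list[int] = []
    back: list[int] = []

    def remove(v: int) -> None:
        remaining.discard(v)
        for u in succ[v]:
            pred[u].discard(v)
        for u in pred[v]:
            succ[u].discard(v)
        succ[v] = set()
        pred[v] = set()

    while remaining:
        changed = True
        while changed:
            changed = False
            for v in sorted(remaining):
                if not succ[v]:  # sink: nothing downstream, place last
                    back.append(v)
                    remove(v)
                    changed = True
            for v in sorted(remaining):
                if not pred[v]:  # source: nothing upstream, place first
                    front.append(v)
                    remove(v)
                    changed = True
        if remaining:
            v = max(sorted(remaining), key=lambda u: len(succ[u]) - len(pred[u]))
            front.append(v)
            remove(v)

    pi = np.array(front + back[::-1], dtype=np.intp)
    pos = np.empty(n, dtype=np.intp)
    pos[pi] = np.arange(n)
    post, pre = np.nonzero(A * (1 - np.eye(n)))
    feedback = {
        (int(a), int(b)) for a, b in zip(post, pre) if pos[b] > pos[a]
    }
    return pi, feedback


def schur_permutation(M) -> np.ndarray:
    """Ordering from the Schur factorization of a feed-forward circuit.

    For an acyclic ``M`` there is a permutation similarity to a lower
    triangular matrix; the orthogonal Schur factor then is (up to
    column signs) a permutation matrix, which this function rounds,
    verifies and returns (reversed, so that the feed-forward edges land
    in the lower triangle).  If the rounded factor is not a permutation
    matrix — in particular whenever the circuit contains a cycle — a
    :class:`NotFeedForwardError` is raised rather than returning a
    silently wrong ordering.
    """
    A = as_matrix(M)
    _, Z = scipy.linalg.schur(A, output="real")
    Q = np.abs(Z)
    rounded = np.round(Q)
    if (
        not np.all((np.abs(Q - rounded) < 1e-6))
        or not np.all(rounded.sum(axis=0) == 1)
        or not np.all(rounded.sum(axis=1) == 1)
    ):
        raise NotFeedForwardError(
            "Schur factor does not round to a permutation matrix; "
            "the circuit is not feed-forward"
        )
    # column j of the factor selects original vertex q_j; the Schur form
    # is upper triangular, so reverse to put feed-forward edges below
    # the diagonal.
    q = np.argmax(rounded, axis=0)
    pi = q[::-1].astype(np.intp)
    R = A[np.ix_(pi, pi)]
    if np.count_nonzero(np.triu(R, 1)):
        raise NotFeedForwardError(
            "Schur-derived ordering leaves entries in the upper triangle; "
            "the circuit is not feed-forward"
        )
    return pi
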