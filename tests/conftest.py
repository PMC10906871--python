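import itertools

import numpy as np
import pytest

from smoothindex import generators, scramble


def chain_matrix(n: int) -> np.ndarray:
    """Directed chain 0 -> 1 -> ... -> n-1 as a [post, pre] matrix."""
    M = np.zeros((n, n))
    M[np.arange(1, n), np.arange(n - 1)] = 1.0
    return M


def brute_force_min_feedback(M: np.ndarray) -> int:
    """Exhaustive minimum feedback-edge count over all n! orderings.

    Independent oracle for the seriation heuristics: for every
    permutation, count edges whose presynaptic vertex is placed after
    its postsynaptic vertex.  Only feasible for n <= 8.
    """
    n = M.shape[0]
    assert n <= 8, "exhaustive oracle limited to n <= 8"
    post, pre = np.nonzero(M)
    mask = post != pre
    post, pre = post[mask], pre[mask]
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    pos = np.argsort(perms, axis=1)
    counts = (pos[:, pre] > pos[:, post]).sum(axis=1)
    return int(counts.min())


def matched_eigenvalue_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Largest pairwise distance under the optimal matching of the two
    eigenvalue multisets (insensitive to sort-order artifacts)."""
    from scipy.optimize import linear_sum_assignment

    ev_a = np.linalg.eigvals(A)
    ev_b = np.linalg.eigvals(B)
    D = np.abs(ev_a[:, None] - ev_b[None, :])
    r, c = linear_sum_assignment(D)
    return float(D[r, c].max())


def central_fd_gradient(f, z: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of a scalar function."""
    g = np.empty_like(z)
    for i in range(len(z)):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        g[i] = (f(zp) - f(zm)) / (2 * h)
    return g


def nondegenerate_positions(rng: np.random.Generator, n: int, edges, gap: float = 1e-3):
    """Random positions bounded away from rank ties and from dz == 0.

    The costs are non-differentiable exactly where two positions tie in
    rank or where an edge length crosses the Heaviside threshold;
    finite-difference checks must stay clear of both.
    """
    pre, post = edges
    while True:
        z = rng.uniform(0.0, n - 1.0, size=n)
        if np.diff(np.sort(z)).min() < gap:
            continue
        d = z[pre] - z[post] + 1.0
        if np.abs(d).min() < gap:
            continue
        return z


@pytest.fixture
def rng():
    return np.random.default_rng(20240220)


@pytest.fixture
def small_triangle():
    """A fixed scrambled mostly-feed-forward circuit (n=12)."""
    M = generators.generate_triangle_matrix(12, seed=7)
    Ms, pi = scramble(M, seed=8)
    return M, Ms, pi
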