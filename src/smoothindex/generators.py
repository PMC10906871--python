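"""Seeded synthetic connectivity-matrix generators.

Three families of test circuits with planted structure:

* **triangle** — mostly feed-forward random circuits: the strict lower
  triangle is Bernoulli(``p_lower``) except for the first subdiagonal,
  which is Bernoulli(``p_subdiag``) (default 1, guaranteeing a backbone
  chain through all cells), and the strict upper triangle is
  Bernoulli(``p_upper``), planting a small set of recurrent edges.
* **band** — entries Bernoulli(``p``) inside a centered diagonal band of
  total width ``width_frac * n``.
* **block** — square Bernoulli(``p``) blocks of size ``block_frac * n``
  tiled along the diagonal (cell assemblies).

The diagonal is always zero (no autapses).  :func:`scramble` applies a
random simultaneous row/column permutation, hiding the planted
structure while keeping the graph isomorphic; it returns the
permutation used so the scrambling can be inverted.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "generate_triangle_matrix",
    "generate_band_matrix",
    "generate_block_matrix",
    "scramble",
]


def _check_n(n: int) -> None:
    if n < 2:
        raise ConfigurationError(f"matrix size must be >= 2, got {n}")


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {p}")


def generate_triangle_matrix(
    n: int,
    p_lower: float = 0.5,
    p_upper: float = 0.04,
    p_subdiag: float = 1.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Random mostly-feed-forward circuit with planted recurrent edges."""
    _check_n(n)
    for name, p in (("p_lower", p_lower), ("p_upper", p_upper), ("p_subdiag", p_subdiag)):
        _check_prob(name, p)
    rng = np.random.default_rng(seed)
    U = rng.random((n, n))
    M = np.zeros((n, n))
    M[np.tril_indices(n, -1)] = (U < p_lower)[np.tril_indices(n, -1)]
    M[np.triu_indices(n, 1)] = (U < p_upper)[np.triu_indices(n, 1)]
    sub = (np.arange(1, n), np.arange(n - 1))
    M[sub] = rng.random(n - 1) < p_subdiag
    return M


def generate_band_matrix(
    n: int,
    width_frac: float = 0.4,
    p: float = 0.5,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Bernoulli entries inside a centered band of total width
    ``width_frac * n`` around the main diagonal (diagonal itself zero)."""
    _check_n(n)
    _check_prob("p", p)
    if width_frac < 0:
        raise ConfigurationError(f"width_frac must be >= 0, got {width_frac}")
    half = round(width_frac * n) / 2.0
    if half > n - 1:
        warnings.warn(
            f"band width {width_frac} exceeds matrix size; clamping to full matrix",
            stacklevel=2,
        )
        half = float(n - 1)
    rng = np.random.default_rng(seed)
    i, j = np.indices((n, n))
    mask = (np.abs(i - j) <= half) & (i != j)
    M = np.zeros((n, n))
    M[mask] = rng.random(int(mask.sum())) < p
    return M


def generate_block_matrix(
    n: int,
    block_frac: float = 0.25,
    p: float = 0.5,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Bernoulli blocks of size ``block_frac * n`` along the diagonal;
    the last block is truncated at the matrix edge."""
    _check_n(n)
    _check_prob("p", p)
    if not 0.0 < block_frac <= 1.0:
        raise ConfigurationError(f"block_frac must be in (0, 1], got {block_frac}")
    b = max(1, round(block_frac * n))
    rng = np.random.default_rng(seed)
    M = np.zeros((n, n))
    for start in range(0, n, b):
        stop = min(start + b, n)
        size = stop - start
        block = (rng.random((size, size)) < p).astype(float)
        M[start:stop, start:stop] = block
    np.fill_diagonal(M, 0.0)
    return M


def scramble(M, seed: Optional[int] = None):
    """Hide structure with a random index permutation.

    Returns ``(scrambled, pi)`` where ``scrambled[i, j] = M[pi[i], pi[j]]``;
    applying the inverse of ``pi`` restores the original matrix.
    """
    from .optimize import apply_permutation

    A = np.asarray(M, dtype=float)
    rng = np.random.default_rng(seed)
    pi = rng.permutation(A.shape[0])
    return apply_permutation(A, pi), pi
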