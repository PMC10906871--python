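"""Differentiable seriation costs over relaxed vertex positions.

A directed circuit of N cells is stored as an N x N connectivity matrix
``M`` with the convention that **rows are postsynaptic and columns are
presynaptic**: ``M[n, m] != 0`` means cell ``m`` synapses onto cell
``n``.  When the cells are numbered along the flow of information,
feed-forward connections occupy the strict lower triangle and recurrent
(feedback) connections the strict upper triangle.

Instead of searching over discrete orderings, each cell ``i`` is given a
real-valued position ``z_i`` on a continuous axis (its *smooth index*).
Three cost terms are defined over the position vector ``z``:

recurrency
    The saturated mean length of all feedback connections.  For every
    edge ``m -> n`` let ``dz = z_m - z_n + 1`` (presynaptic position
    minus postsynaptic position, offset so that the ideal chain step
    ``z_m = z_n - 1`` sits exactly at ``dz = 0``).  The edge contributes
    ``(alpha(dz) - 1/2) * H(dz)`` where ``alpha`` is a logistic with
    slope ``10/N`` and ``H`` is the Heaviside step (``H(0) = 1``).  The
    sum is normalized by the total edge weight, so the cost lies in
    ``[0, 1/2)``.

bandwidth
    The mean squared connection length ``dz**2`` over all edges,
    normalized by ``N**2`` and the total edge weight; minimizing it
    pulls every edge towards the unit chain step.

Pauli
    A data-independent exclusion penalty ``sum((z_i - rank(z_i))**2) /
    N**3`` that keeps the positions from collapsing onto each other:
    it vanishes exactly when the positions are a permutation of
    ``0 .. N-1``.  It is continuous but not differentiable where two
    positions swap rank; the one-sided derivative components there
    differ by ``2/N**3``.

All cost functions return a :class:`CostValue` carrying the scalar cost
and its analytic gradient with respect to ``z``.  The gradients are the
true derivatives of the implemented costs (including every
normalization factor), which property tests verify against central
finite differences.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import expit

from .exceptions import ConfigurationError, DegenerateMatrixError, ShapeError

__all__ = [
    "CostValue",
    "EdgeData",
    "logistic_alpha",
    "ranks",
    "recurrency_objective",
    "bandwidth_objective",
    "pauli_objective",
    "total_objective",
]

OBJECTIVES = ("recurrency", "bandwidth")


class CostValue(NamedTuple):
    """A scalar cost together with its gradient along each position."""

    cost: float
    gradient: np.ndarray


class EdgeData(NamedTuple):
    """Edge-list view of a connectivity matrix used by the cost kernels.

    ``pre[k] -> post[k]`` is the k-th directed edge with weight
    ``weight[k]`` (1 for binarized matrices, ``|M|`` in weighted mode);
    the diagonal (autapses) is always excluded.
    """

    n: int
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    total_weight: float


def as_matrix(M) -> np.ndarray:
    """Validate and return ``M`` as a square float array, N >= 2."""
    A = np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"connectivity matrix must be square, got shape {A.shape}")
    if A.shape[0] < 2:
        raise ShapeError(f"connectivity matrix needs at least 2 vertices, got {A.shape[0]}")
    if not np.all(np.isfinite(A)):
        raise ShapeError("connectivity matrix contains non-finite entries")
    return A


def edge_data(M, use_weights: bool = False) -> EdgeData:
    """Extract the off-diagonal edge list from a connectivity matrix.

    By default the matrix pattern is binarized (every edge has weight
    1); with ``use_weights=True`` the absolute values of the entries
    enter the costs as per-edge weights.
    """
    A = as_matrix(M)
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    post, pre = np.nonzero(A)
    if len(pre) == 0:
        raise DegenerateMatrixError("matrix has no off-diagonal edges")
    w = np.abs(A[post, pre]) if use_weights else np.ones(len(pre))
    return EdgeData(n, pre, post, w, float(w.sum()))


def _check_positions(z, n: int) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.shape[0] != n:
        raise ShapeError(f"position vector has length {z.shape}, expected ({n},)")
    if not np.all(np.isfinite(z)):
        raise ShapeError("position vector contains non-finite values")
    return z


def logistic_alpha(x, n: int):
    """Logistic saturation ``1 / (1 + exp(-10 x / n))``.

    Maps a connection length to (0, 1) with midpoint 1/2 at ``x = 0``;
    the ``10/n`` slope makes the saturation scale with circuit size so
    that a length of ``n/10`` always maps to ``1/(1+e^-1)``.
    """
    if n < 1:
        raise ConfigurationError(f"size n must be >= 1, got {n}")
    return expit(10.0 * np.asarray(x, dtype=float) / n)


def ranks(z) -> np.ndarray:
    """0-based ordinal ranks of the positions; ties broken by index.

    The stable double argsort guarantees a deterministic rank vector
    even at exact ties, which the Pauli term and the permutation
    extraction both rely on.
    """
    z = np.asarray(z, dtype=float)
    order = np.argsort(z, kind="stable")
    r = np.empty(len(z), dtype=float)
    r[order] = np.arange(len(z), dtype=float)
    return r


def _recurrency(z: np.ndarray, e: EdgeData) -> CostValue:
    d = z[e.pre] - z[e.post] + 1.0
    h = d >= 0.0
    a = expit(10.0 * d / e.n)
    terms = e.weight * (a - 0.5) * h
    cost = float(terms.sum() / e.total_weight)
    # d/dz of alpha(10 d / n): chain factor 10/n; H contributes no
    # derivative away from d == 0 (and the cost term vanishes there).
    fprime = e.weight * (10.0 / e.n) * a * (1.0 - a) * h / e.total_weight
    grad = np.zeros(e.n)
    np.add.at(grad, e.pre, fprime)
    np.add.at(grad, e.post, -fprime)
    return CostValue(cost, grad)


def _bandwidth(z: np.ndarray, e: EdgeData) -> CostValue:
    d = z[e.pre] - z[e.post] + 1.0
    norm = e.n * e.n * e.total_weight
    cost = float((e.weight * d * d).sum() / norm)
    g = 2.0 * e.weight * d / norm
    grad = np.zeros(e.n)
    np.add.at(grad, e.pre, g)
    np.add.at(grad, e.post, -g)
    return CostValue(cost, grad)


def _pauli(z: np.ndarray) -> CostValue:
    n = len(z)
    dev = z - ranks(z)
    return CostValue(float((dev * dev).sum() / n**3), 2.0 * dev / n**3)


def recurrency_objective(z, M, use_weights: bool = False) -> CostValue:
    """Saturated mean feedback length and its gradient."""
    e = edge_data(M, use_weights)
    return _recurrency(_check_positions(z, e.n), e)


def bandwidth_objective(z, M, use_weights: bool = False) -> CostValue:
    """Mean squared connection length and its gradient."""
    e = edge_data(M, use_weights)
    return _bandwidth(_check_positions(z, e.n), e)


def pauli_objective(z) -> CostValue:
    """Exclusion penalty: mean squared deviation of positions from ranks."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or not np.all(np.isfinite(z)):
        raise ShapeError("positions must be a finite 1-d vector")
    return _pauli(z)


def total_cost_from_edges(
    z: np.ndarray, e: EdgeData, objective: str, pauli_weight: float
) -> tuple[float, np.ndarray, float, float]:
    """Total cost C = L + w*P on a prebuilt edge list.

    Returns ``(C, grad C, L, P)``; the optimizer calls this in its
    inner loop and for trace recording.
    """
    if objective == "recurrency":
        length = _recurrency(z, e)
    elif objective == "bandwidth":
        length = _bandwidth(z, e)
    else:
        raise ConfigurationError(
            f"unknown objective {objective!r}; expected one of {OBJECTIVES}"
        )
    pauli = _pauli(z)
    cost = length.cost + pauli_weight * pauli.cost
    grad = length.gradient + pauli_weight * pauli.gradient
    return cost, grad, length.cost, pauli.cost


def total_objective(
    z, M, objective: str = "recurrency", pauli_weight: float = 1.0,
    use_weights: bool = False,
) -> CostValue:
    """Total cost ``C(z) = L(z) + w * P(z)`` with its gradient.

    ``pauli_weight`` rebalances the exclusion penalty against the
    data-dependent length term; the seriation quality is tolerant over
    a broad range around the default of 1.
    """
    if pauli_weight <= 0:
        raise ConfigurationError(f"pauli_weight must be > 0, got {pauli_weight}")
    e = edge_data(M, use_weights)
    z = _check_positions(z, e.n)
    c, g, _, _ = total_cost_from_edges(z, e, objective, pauli_weight)
    return CostValue(c, g)
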