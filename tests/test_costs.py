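"""Unit and property tests for the relaxed cost functions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smoothindex import (
    ConfigurationError,
    DegenerateMatrixError,
    ShapeError,
    bandwidth_objective,
    logistic_alpha,
    pauli_objective,
    ranks,
    recurrency_objective,
    total_objective,
)
from smoothindex.costs import edge_data

from conftest import central_fd_gradient, nondegenerate_positions


class TestLogisticAlpha:
    def test_midpoint_is_half(self):
        for n in (1, 2, 50, 1000):
            assert logistic_alpha(0.0, n) == pytest.approx(0.5)

    def test_saturates_to_one(self):
        assert logistic_alpha(1e6, 10) == pytest.approx(1.0)
        assert logistic_alpha(-1e6, 10) == pytest.approx(0.0)

    def test_tenth_of_n_maps_to_fixed_value(self):
        # x = n/10 makes the exponent exactly 1 regardless of n
        for n in (5, 50, 500):
            assert logistic_alpha(n / 10, n) == pytest.approx(1 / (1 + np.exp(-1)))

    def test_strictly_increasing(self):
        x = np.linspace(-30, 30, 101)
        y = logistic_alpha(x, 20)
        assert np.all(np.diff(y) > 0)

    def test_invalid_size(self):
        with pytest.raises(ConfigurationError):
            logistic_alpha(1.0, 0)


class TestRecurrency:
    def test_single_feedback_edge_costs_almost_half(self):
        # pre 1 -> post 0 is an upper-triangle entry; with z=(0,1) its
        # length is 2 and the saturated logistic puts the cost just
        # under the 1/2 ceiling
        M = np.array([[0, 1], [0, 0]], float)
        cv = recurrency_objective([0.0, 1.0], M)
        assert cv.cost == pytest.approx(1 / (1 + np.exp(-10.0)) - 0.5, abs=1e-10)
        assert cv.cost == pytest.approx(0.4999546, abs=1e-6)

    def test_adjacent_feedforward_edge_is_free(self):
        # pre 0 -> post 1 with unit spacing: dz = 0, alpha(0) - 1/2 = 0
        M = np.array([[0, 0], [1, 0]], float)
        cv = recurrency_objective([0.0, 1.0], M)
        assert cv.cost == 0.0

    def test_cost_in_range(self, rng):
        for _ in range(20):
            M = (rng.random((6, 6)) < 0.4).astype(float)
            np.fill_diagonal(M, 0)
            if not M.any():
                continue
            z = rng.uniform(0, 5, 6)
            assert 0.0 <= recurrency_objective(z, M).cost < 0.5

    def test_empty_matrix_rejected(self):
        with pytest.raises(DegenerateMatrixError):
            recurrency_objective([0.0, 1.0], np.zeros((2, 2)))

    def test_length_mismatch_rejected(self):
        M = np.array([[0, 1], [0, 0]], float)
        with pytest.raises(ShapeError):
            recurrency_objective([0.0, 1.0, 2.0], M)

    def test_diagonal_ignored(self):
        M = np.array([[1.0, 1.0], [0.0, 1.0]])
        M_nodiag = np.array([[0.0, 1.0], [0.0, 0.0]])
        z = [0.3, 1.7]
        assert recurrency_objective(z, M).cost == pytest.approx(
            recurrency_objective(z, M_nodiag).cost
        )


class TestBandwidth:
    def test_unit_step_edge_is_free(self):
        M = np.array([[0, 0], [1, 0]], float)
        assert bandwidth_objective([0.0, 1.0], M).cost == 0.0

    def test_feedback_edge_hand_value(self):
        # dz = 2, cost = (1/N^2) * dz^2 = 4/4
        M = np.array([[0, 1], [0, 0]], float)
        assert bandwidth_objective([0.0, 1.0], M).cost == pytest.approx(1.0)

    def test_zero_iff_chain_geometry(self, rng):
        n = 6
        M = np.zeros((n, n))
        M[np.arange(1, n), np.arange(n - 1)] = 1
        z = np.arange(n, dtype=float)
        assert bandwidth_objective(z, M).cost == 0.0
        z[3] += 0.5
        assert bandwidth_objective(z, M).cost > 0.0


class TestPauli:
    @pytest.mark.parametrize("z", [(0.0, 1.0, 2.0), (2.0, 0.0, 1.0), (3.0, 1.0, 0.0, 2.0)])
    def test_zero_on_rank_permutations(self, z):
        assert pauli_objective(z).cost == 0.0

    def test_hand_value(self):
        cv = pauli_objective([0.0, 0.5, 2.0])
        assert cv.cost == pytest.approx(0.25 / 27)
        np.testing.assert_allclose(cv.gradient, [0.0, 2 * (-0.5) / 27, 0.0])

    def test_rank_tie_break_by_index(self):
        np.testing.assert_array_equal(ranks([1.0, 1.0, 0.0]), [1.0, 2.0, 0.0])

    def test_continuity_at_switch(self):
        # crossing a neighbor changes both ranks but not the cost value
        n = 5
        base = np.array([0.0, 1.0, 2.4, 3.0, 4.0])
        eps = 1e-8
        left = base.copy()
        left[1] = base[2] - eps
        right = base.copy()
        right[1] = base[2] + eps
        assert abs(pauli_objective(left).cost - pauli_objective(right).cost) < 1e-6 / n**3

    def test_gradient_jump_at_switch(self):
        # one-sided derivative components differ by exactly 2/N^3
        n = 5
        base = np.array([0.0, 1.0, 2.4, 3.0, 4.0])
        eps = 1e-9
        left = base.copy()
        left[1] = base[2] - eps
        right = base.copy()
        right[1] = base[2] + eps
        jump = pauli_objective(left).gradient[1] - pauli_objective(right).gradient[1]
        assert jump == pytest.approx(2.0 / n**3, abs=1e-6)


class TestTotal:
    def test_additivity(self, rng):
        M = (rng.random((6, 6)) < 0.5).astype(float)
        np.fill_diagonal(M, 0)
        z = rng.uniform(0, 5, 6)
        for w in (1.0, 0.5, 2.0):
            tot = total_objective(z, M, "recurrency", pauli_weight=w)
            L = recurrency_objective(z, M)
            P = pauli_objective(z)
            assert tot.cost == pytest.approx(L.cost + w * P.cost, rel=1e-12)
            np.testing.assert_allclose(tot.gradient, L.gradient + w * P.gradient)

    def test_pauli_vanishes_on_rank_vector(self, rng):
        M = (rng.random((5, 5)) < 0.5).astype(float)
        np.fill_diagonal(M, 0)
        z = rng.permutation(5).astype(float)
        tot = total_objective(z, M, "recurrency")
        assert tot.cost == pytest.approx(recurrency_objective(z, M).cost)

    def test_unknown_objective(self):
        M = np.array([[0, 1], [0, 0]], float)
        with pytest.raises(ConfigurationError):
            total_objective([0.0, 1.0], M, "frobnicate")

    def test_nonpositive_pauli_weight(self):
        M = np.array([[0, 1], [0, 0]], float)
        with pytest.raises(ConfigurationError):
            total_objective([0.0, 1.0], M, "recurrency", pauli_weight=0.0)

    def test_weighted_mode_matches_edge_duplication(self):
        # an edge of weight 2 must count like two unit edges
        W = np.array([[0.0, 2.0, 0.0], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        z = np.array([0.2, 1.9, 0.7])
        cv = recurrency_objective(z, W, use_weights=True)
        e = edge_data(W, use_weights=True)
        assert e.total_weight == 4.0
        # manual re-evaluation duplicating the weight-2 edge
        manual = 0.0
        for post, pre, w in [(0, 1, 2.0), (1, 0, 1.0), (2, 0, 1.0)]:
            d = z[pre] - z[post] + 1
            if d >= 0:
                manual += w * (1 / (1 + np.exp(-10 * d / 3)) - 0.5)
        assert cv.cost == pytest.approx(manual / 4.0)


@pytest.mark.parametrize("objective", ["recurrency", "bandwidth"])
def test_translation_invariance_of_length_terms(rng, objective):
    """Length costs depend only on position differences; the Pauli
    penalty anchors positions to ranks and is not invariant."""
    M = (rng.random((8, 8)) < 0.4).astype(float)
    np.fill_diagonal(M, 0)
    fn = recurrency_objective if objective == "recurrency" else bandwidth_objective
    z = rng.uniform(0, 7, 8)
    base = fn(z, M).cost
    for c in (-1.3, 0.7, 5.0):
        assert fn(z + c, M).cost == pytest.approx(base, rel=1e-9)
    assert pauli_objective(z + 3.0).cost != pytest.approx(pauli_objective(z).cost)


@pytest.mark.parametrize("n", [4, 8, 16])
@pytest.mark.parametrize("objective", ["recurrency", "bandwidth", "pauli"])
def test_gradients_match_finite_differences(rng, n, objective):
    """Analytic Jacobians agree with a central-difference oracle at
    random non-degenerate points (spot check; the full 100-point sweep
    runs in the acceptance suite)."""
    M = (rng.random((n, n)) < 0.5).astype(float)
    np.fill_diagonal(M, 0)
    e = edge_data(M)
    for _ in range(10):
        z = nondegenerate_positions(rng, n, (e.pre, e.post))
        if objective == "recurrency":
            cv, f = recurrency_objective(z, M), lambda zz: recurrency_objective(zz, M).cost
        elif objective == "bandwidth":
            cv, f = bandwidth_objective(z, M), lambda zz: bandwidth_objective(zz, M).cost
        else:
            cv, f = pauli_objective(z), lambda zz: pauli_objective(zz).cost
        fd = central_fd_gradient(f, z)
        err = np.linalg.norm(fd - cv.gradient) / max(np.linalg.norm(cv.gradient), 1e-12)
        assert err < 1e-5


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=2, max_size=12))
def test_pauli_cost_nonnegative_and_zero_only_on_permutations(zs):
    z = np.asarray(zs)
    cv = pauli_objective(z)
    assert cv.cost >= 0.0
    if cv.cost == 0.0:
        assert set(z.tolist()) == set(range(len(z)))
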