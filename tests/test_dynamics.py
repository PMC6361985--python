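"""Influence-system construction and Friedkin-Johnsen / DeGroot dynamics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from numpy.testing import assert_allclose, assert_array_equal

from allocdyn.dynamics import (
    FriedkinJohnsenModel,
    InfluenceSystem,
    OpinionArray,
    SingularInfluenceError,
    degroot_consensus_certificate,
    degroot_iterate,
    fj_equilibrium,
    fj_iterate,
    fj_step,
    influence_from_chips,
    total_influence_matrix,
    weights_from_chips,
)
from allocdyn.geometry import hull_contains

from conftest import random_influence, random_simplex

# the 2-member system whose equilibrium is hand-computable:
# W symmetric 1/2, a_ii = 1/2, V = [[3/4, 1/4], [1/4, 3/4]]
W2 = np.array([[0.5, 0.5], [0.5, 0.5]])
X2 = OpinionArray([[0.0], [100.0]], simplex_constrained=False)


class TestWeightsFromChips:
    @pytest.mark.parametrize("chips,self_index,expected", [
        ((100, 0, 0), 0, (1.0, 0.0, 0.0)),       # conversation had no influence
        ((0, 50, 50), 0, (0.0, 0.5, 0.5)),       # approach fully abandoned
        ((40, 40, 20), 0, (0.4, 0.4, 0.2)),
        ((30, 30), 0, (0.5, 0.5)),               # slipped total renormalized
    ])
    def test_normalization(self, chips, self_index, expected):
        assert_allclose(weights_from_chips(chips, self_index), expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="unusable"):
            weights_from_chips((0, 0, 0), 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            weights_from_chips((-1, 50, 51), 0)

    def test_bad_self_index(self):
        with pytest.raises(ValueError):
            weights_from_chips((50, 50), 2)

    def test_matrix_constructor_row_stochastic(self, rng):
        chips = rng.integers(0, 50, size=(4, 4)) + 1
        system = influence_from_chips(chips)
        assert_allclose(system.W.sum(axis=1), 1.0, atol=1e-12)
        assert_allclose(system.a, 1.0 - np.diag(system.W))


class TestInfluenceSystem:
    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            InfluenceSystem([[0.5, 0.3], [0.5, 0.5]])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            InfluenceSystem([[1.5, -0.5], [0.5, 0.5]])

    def test_susceptibility_derived_from_diagonal(self):
        system = InfluenceSystem([[0.7, 0.3], [0.2, 0.8]])
        assert_allclose(system.a, [0.3, 0.2])
        assert_allclose(np.diag(system.A), system.a)


class TestFJStep:
    def test_zero_susceptibility_returns_initial(self):
        # all w_ii = 1: opinions anchored, any X(k) maps back to X(0)
        system = InfluenceSystem(np.eye(3))
        X0 = OpinionArray(random_simplex(np.random.default_rng(0), 3, 3))
        Xk = OpinionArray(random_simplex(np.random.default_rng(1), 3, 3))
        assert_array_equal(fj_step(Xk, system, X0).X, X0.X)

    def test_full_susceptibility_is_degroot(self, rng):
        # w_ii = 0 for all i makes the update pure weighted averaging
        W = np.array([[0.0, 0.6, 0.4], [0.5, 0.0, 0.5], [0.3, 0.7, 0.0]])
        system = InfluenceSystem(W)
        X0 = OpinionArray(random_simplex(rng, 3, 3))
        Xk = OpinionArray(random_simplex(rng, 3, 3))
        assert_allclose(fj_step(Xk, system, X0).X, W @ Xk.X)

    def test_two_member_hand_computed_step(self):
        out = fj_step(X2, InfluenceSystem(W2), X2)
        assert_allclose(out.X, [[25.0], [75.0]])

    def test_shape_mismatch_raises(self):
        system = InfluenceSystem(W2)
        X3 = OpinionArray(np.zeros((3, 1)), simplex_constrained=False)
        with pytest.raises(ValueError, match="mismatch"):
            fj_step(X3, system, X3)


class TestFJIterate:
    def test_anchored_system_converges_immediately(self):
        system = InfluenceSystem(np.eye(2))
        traj = fj_iterate(X2, system)
        assert traj.converged and traj.iterations == 1
        assert_array_equal(traj.states[1].X, X2.X)

    def test_two_member_limit(self):
        traj = fj_iterate(X2, InfluenceSystem(W2), tol=1e-12)
        assert traj.converged
        assert_allclose(traj.final.X, [[25.0], [75.0]], atol=1e-9)

    def test_contraction_always_converges(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            system = InfluenceSystem(random_influence(rng, n))
            X0 = OpinionArray(random_simplex(rng, n, 3))
            assert fj_iterate(X0, system).converged

    def test_trajectory_starts_at_initial(self, rng):
        system = InfluenceSystem(random_influence(rng, 3))
        X0 = OpinionArray(random_simplex(rng, 3, 3))
        traj = fj_iterate(X0, system)
        assert traj.states[0] is X0
        assert traj.iterations == len(traj.states) - 1

    def test_periodic_degroot_oscillates(self):
        # pure averaging on a 2-cycle swaps opinions forever
        traj = degroot_iterate(X2, [[0.0, 1.0], [1.0, 0.0]], max_iter=50)
        assert not traj.converged
        assert_allclose(traj.final_residual, 100.0)


class TestTotalInfluence:
    def test_anchored_identity(self):
        assert_array_equal(total_influence_matrix(InfluenceSystem(np.eye(3))),
                           np.eye(3))

    def test_two_member_hand_inverted(self):
        V = total_influence_matrix(InfluenceSystem(W2))
        assert_allclose(V, [[0.75, 0.25], [0.25, 0.75]], atol=1e-12)

    def test_row_stochastic_on_random_systems(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            V = total_influence_matrix(InfluenceSystem(random_influence(rng, n)))
            assert_allclose(V.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(V >= -1e-12) and np.all(V <= 1 + 1e-12)

    def test_singular_system_raises(self):
        # w_ii = 0 with a periodic graph makes I - AW singular
        with pytest.raises(SingularInfluenceError, match="iterat"):
            total_influence_matrix(InfluenceSystem([[0.0, 1.0], [1.0, 0.0]]))

    def test_agrees_with_iteration(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 7))
            system = InfluenceSystem(random_influence(rng, n))
            X0 = OpinionArray(random_simplex(rng, n, 3))
            V = total_influence_matrix(system)
            traj = fj_iterate(X0, system, tol=1e-12)
            assert_allclose(V @ X0.X, traj.final.X, atol=1e-10)


class TestFJEquilibrium:
    def test_anchored_equilibrium_is_initial_exactly(self, rng):
        system = InfluenceSystem(np.eye(4))
        X0 = OpinionArray(random_simplex(rng, 4, 3))
        pred = fj_equilibrium(X0, system)
        assert_array_equal(pred.X_hat, X0.X)
        assert_array_equal(pred.changes, np.zeros_like(X0.X))

    def test_two_member_equilibrium_and_changes(self):
        pred = fj_equilibrium(X2, InfluenceSystem(W2))
        assert_allclose(pred.X_hat, [[25.0], [75.0]], atol=1e-12)
        assert_allclose(pred.changes, [[25.0], [-25.0]], atol=1e-12)
        assert pred.method == "closed_form"

    def test_simplex_row_sums_preserved(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 5))
            system = InfluenceSystem(random_influence(rng, n))
            X0 = OpinionArray(random_simplex(rng, n, 4))
            pred = fj_equilibrium(X0, system)
            assert_allclose(pred.X_hat.sum(axis=1), 100.0, atol=1e-8)

    def test_columnwise_equals_whole_matrix(self, rng):
        # per-column propagation is equivalent to the matrix update
        n = 4
        system = InfluenceSystem(random_influence(rng, n))
        X0 = OpinionArray(random_simplex(rng, n, 3))
        whole = fj_equilibrium(X0, system).X_hat
        cols = [fj_equilibrium(
            OpinionArray(X0.X[:, [j]], simplex_constrained=False),
            system).X_hat for j in range(3)]
        assert_allclose(whole, np.hstack(cols), atol=1e-12)

    def test_equilibrium_in_initial_hull(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 5))
            system = InfluenceSystem(random_influence(rng, n))
            X0 = OpinionArray(random_simplex(rng, n, 3))
            pred = fj_equilibrium(X0, system)
            for row in pred.X_hat:
                assert hull_contains(X0.X, row, tol=1e-6)

    def test_unresolvable_system_propagates_error(self):
        # singular closed form AND non-convergent iteration
        with pytest.raises(SingularInfluenceError):
            fj_equilibrium(X2, InfluenceSystem([[0.0, 1.0], [1.0, 0.0]]),
                           max_iter=100)


class TestConsensusCertificate:
    def test_isolated_members_no_consensus(self):
        cert = degroot_consensus_certificate(np.eye(3))
        assert not cert.consensus_guaranteed
        assert cert.reachable_node is None

    def test_complete_graph_guarantees_consensus(self):
        cert = degroot_consensus_certificate(np.full((4, 4), 0.25))
        assert cert.consensus_guaranteed
        assert cert.aperiodic is True
        assert cert.reachable_node is not None

    def test_periodic_pair_not_certified(self):
        cert = degroot_consensus_certificate([[0.0, 1.0], [1.0, 0.0]])
        assert cert.reachable_node is not None    # each member reaches the other
        assert cert.aperiodic is None             # w_ii > 0 certificate fails
        assert not cert.consensus_guaranteed

    def test_star_graph_reachable_center(self):
        # members 1 and 2 weight member 0; 0 listens to no one
        W = np.array([[1.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5]])
        cert = degroot_consensus_certificate(W)
        assert cert.reachable_node == 0
        assert cert.consensus_guaranteed


class TestModelAPI:
    def test_fit_matches_functional_path(self, rng):
        X0 = random_simplex(rng, 3, 3)
        W = random_influence(rng, 3)
        res = FriedkinJohnsenModel(X0, W).fit()
        pred = fj_equilibrium(OpinionArray(X0), InfluenceSystem(W))
        assert_allclose(res.equilibrium, pred.X_hat)
        assert_allclose(res.total_influence, pred.V)

    def test_iterative_method_agrees_with_closed_form(self, rng):
        X0 = random_simplex(rng, 4, 3)
        W = random_influence(rng, 4)
        model = FriedkinJohnsenModel(X0, W)
        assert_allclose(model.fit(method="iterative").equilibrium,
                        model.fit(method="closed_form").equilibrium, atol=1e-8)

    def test_from_chips(self):
        chips = np.array([[60, 20, 20], [10, 80, 10], [25, 25, 50]])
        X0 = random_simplex(np.random.default_rng(7), 3, 3)
        res = FriedkinJohnsenModel.from_chips(X0, chips).fit()
        assert_allclose(res.total_influence.sum(axis=1), 1.0, atol=1e-9)

    def test_summary_mentions_method_and_members(self, rng):
        res = FriedkinJohnsenModel(random_simplex(rng, 3, 3),
                                   random_influence(rng, 3)).fit()
        text = res.summary()
        assert "closed_form" in text and "members: 3" in text

    def test_member_count_mismatch(self, rng):
        with pytest.raises(ValueError):
            FriedkinJohnsenModel(random_simplex(rng, 3, 3),
                                 random_influence(rng, 4))


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_equilibrium_row_sums_and_hull_property(seed):
    """X_hat rows stay on the simplex and inside the initial opinions' hull."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 6))
    system = InfluenceSystem(random_influence(rng, n))
    X0 = OpinionArray(random_simplex(rng, n, 3))
    pred = fj_equilibrium(X0, system)
    assert_allclose(pred.X_hat.sum(axis=1), 100.0, atol=1e-8)
    assert np.all(pred.X_hat >= X0.X.min(axis=0) - 1e-8)
    assert np.all(pred.X_hat <= X0.X.max(axis=0) + 1e-8)
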