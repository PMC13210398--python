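"""Network-algebra unit and property tests: dynamics, equilibrium,
MR-network conversions, total effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrgraph.exceptions import (
    DegenerateScalingError,
    ModelViolationError,
    NonConvergentDynamicsError,
    SingularMatrixError,
)
from mrgraph.network import (
    DirectEffectGraph,
    MREffectNetwork,
    equilibrium,
    graph_from_mr_network,
    is_admissible,
    mixing_matrix,
    mr_network_from_graph,
    simulate_dynamics,
    spectral_radius,
    steady_state_effects,
    total_effect_network,
    total_from_mr_network,
)

from conftest import random_admissible_graph


class TestSpectralRadius:
    def test_zero_matrix(self):
        assert spectral_radius(np.zeros((3, 3))) == 0.0

    def test_nilpotent_acyclic_graph(self, acyclic_graph):
        # characteristic polynomial is lambda^3: all eigenvalues vanish
        assert spectral_radius(acyclic_graph) == pytest.approx(0.0, abs=1e-12)

    def test_three_cycle_is_cube_root_of_edge_product(self, cyclic_graph):
        # eigenvalues of a 3-cycle are the cube roots of the edge product
        expected = (0.5 * 0.05 * 0.5) ** (1.0 / 3.0)
        assert spectral_radius(cyclic_graph) == pytest.approx(expected, abs=1e-12)

    def test_complex_eigenvalues_included(self):
        rot = np.array([[0.0, -0.8], [0.8, 0.0]])  # eigenvalues +-0.8i
        assert spectral_radius(rot) == pytest.approx(0.8, abs=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            spectral_radius(np.zeros((2, 3)))


class TestDynamics:
    def test_no_propagation_when_graph_is_zero(self, rng):
        Gamma = rng.normal(size=(3, 5))
        z = rng.normal(size=5)
        eps = rng.normal(size=3)
        traj = simulate_dynamics(np.zeros((3, 3)), Gamma, z, eps, t_max=7)
        assert np.allclose(traj, Gamma @ z + eps)

    def test_final_iterate_matches_equilibrium_solve(self, cyclic_graph, rng):
        Gamma = rng.normal(size=(3, 6))
        z = rng.normal(size=6)
        eps = rng.normal(size=3)
        traj = simulate_dynamics(cyclic_graph, Gamma, z, eps, t_max=50)
        eq = equilibrium(cyclic_graph, Gamma, z, eps)
        assert np.max(np.abs(traj[-1] - eq)) < 1e-6

    def test_acyclic_trajectory_constant_after_two_steps(self, acyclic_graph, rng):
        # G^2 = 0, so the power series truncates
        Gamma = rng.normal(size=(3, 4))
        traj = simulate_dynamics(acyclic_graph, Gamma, rng.normal(size=4), rng.normal(size=3), 6)
        for t in range(1, 6):
            assert np.allclose(traj[t], traj[1])

    def test_explosive_graph_refused(self):
        G = np.array([[0.0, 1.1], [1.1, 0.0]])
        with pytest.raises(NonConvergentDynamicsError):
            simulate_dynamics(G, np.zeros((2, 1)), [0.0], [0.0, 0.0], 5)

    def test_closed_form_agreement_each_step(self, cyclic_graph, rng):
        # Y(t) = (I-G)^{-1}(I - G^t)(Gamma z + eps)
        Gamma = rng.normal(size=(3, 4))
        z = rng.normal(size=4)
        eps = rng.normal(size=3)
        traj = simulate_dynamics(cyclic_graph, Gamma, z, eps, 12)
        base = Gamma @ z + eps
        I = np.eye(3)
        for t in range(1, 13):
            closed = np.linalg.solve(I - cyclic_graph, (I - np.linalg.matrix_power(cyclic_graph, t)) @ base)
            assert np.allclose(traj[t - 1], closed, atol=1e-10)


class TestSteadyStateEffects:
    def test_identity_when_graph_zero(self, rng):
        Gamma = rng.normal(size=(3, 8))
        res = steady_state_effects(np.zeros((3, 3)), Gamma)
        assert np.allclose(res.B, Gamma)

    def test_acyclic_unit_column(self, acyclic_graph):
        Gamma = np.zeros((3, 4))
        Gamma[2, 1] = 1.0  # one SNP acting directly on Y3 only
        res = steady_state_effects(acyclic_graph, Gamma)
        assert np.allclose(res.B[:, 1], [0.2, 0.1, 1.0])

    def test_cyclic_unit_column_matches_hand_inverse(self, cyclic_graph):
        # first column of (I-G)^{-1}; det(I-G) = 0.9875
        Gamma = np.zeros((3, 1))
        Gamma[0, 0] = 1.0
        res = steady_state_effects(cyclic_graph, Gamma)
        expected = np.array([1.0, 0.05, 0.025]) / 0.9875
        assert np.allclose(res.B[:, 0], expected, atol=1e-12)

    def test_singular_system_rejected(self):
        G = np.array([[0.0, 1.0], [1.0, 0.0]])  # I - G singular
        with pytest.raises((SingularMatrixError, ModelViolationError)):
            steady_state_effects(G, np.zeros((2, 1)))


class TestMRNetworkConversions:
    def test_zero_graph_gives_identity(self):
        assert np.allclose(mr_network_from_graph(np.zeros((3, 3))).Theta, np.eye(3))

    def test_acyclic_theta_is_identity_plus_graph(self, acyclic_graph):
        theta = mr_network_from_graph(acyclic_graph).Theta
        assert np.allclose(theta, np.eye(3) + acyclic_graph, atol=1e-12)

    def test_cyclic_theta_is_column_normalized_inverse(self, cyclic_graph):
        net = mr_network_from_graph(cyclic_graph)
        W = np.linalg.inv(np.eye(3) - cyclic_graph)
        assert np.allclose(net.Theta, W / np.diag(W)[None, :], atol=1e-12)
        assert net.Theta[1, 0] == pytest.approx(0.05, abs=1e-12)
        # cross-check against the truncated power series for W
        series = sum(np.linalg.matrix_power(cyclic_graph, l) for l in range(101))
        assert np.allclose(net.Theta, series / np.diag(series)[None, :], atol=1e-10)

    def test_unit_diagonal_exact(self, rng):
        for _ in range(20):
            G = random_admissible_graph(rng, T=5)
            theta = mr_network_from_graph(G).Theta
            assert np.all(np.diag(theta) == 1.0)

    def test_identity_network_recovers_zero_graph(self):
        assert np.allclose(graph_from_mr_network(np.eye(4)).G, 0.0)

    @pytest.mark.parametrize("design", ["acyclic", "cyclic"])
    def test_round_trip_recovers_design_graphs(self, design, acyclic_graph, cyclic_graph):
        G = acyclic_graph if design == "acyclic" else cyclic_graph
        rec = graph_from_mr_network(mr_network_from_graph(G))
        assert np.max(np.abs(rec.G - G)) < 1e-8
        assert np.all(np.diag(rec.G) == 0.0)

    def test_singular_theta_raises_with_condition_context(self):
        Theta = np.ones((3, 3))
        np.fill_diagonal(Theta, 1.0)
        with pytest.raises(SingularMatrixError, match="condition number"):
            graph_from_mr_network(Theta)

    def test_degenerate_scaling_aborts(self):
        # Theta^{-1} has zero diagonal entries for this permutation matrix
        Theta = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(DegenerateScalingError):
            graph_from_mr_network(Theta)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), T=st.integers(2, 6))
    def test_round_trip_property(self, seed, T):
        rng = np.random.default_rng(seed)
        G = random_admissible_graph(rng, T=T)
        rec = graph_from_mr_network(mr_network_from_graph(G))
        assert np.max(np.abs(rec.G - G)) < 1e-8


class TestTotalEffects:
    def test_zero_graph(self):
        assert np.allclose(total_effect_network(np.zeros((3, 3))).Gtot, 0.0)

    def test_acyclic_total_equals_direct(self, acyclic_graph):
        assert np.allclose(total_effect_network(acyclic_graph).Gtot, acyclic_graph, atol=1e-12)

    def test_cyclic_self_loops_and_series_oracle(self, cyclic_graph):
        res = total_effect_network(cyclic_graph)
        assert np.all(np.diag(res.Gtot) > 0.0)
        series = sum(np.linalg.matrix_power(cyclic_graph, l) for l in range(1, 101))
        assert np.max(np.abs(res.Gtot - series)) < 1e-10

    def test_equals_mixing_matrix_minus_identity(self, rng):
        G = random_admissible_graph(rng, T=5)
        assert np.allclose(total_effect_network(G).Gtot, mixing_matrix(G).W - np.eye(5), atol=1e-10)

    def test_explosive_graph_not_well_defined(self):
        G = np.array([[0.0, 2.0], [2.0, 0.0]])
        with pytest.raises(ModelViolationError, match="not well defined"):
            total_effect_network(G)

    def test_from_mr_network_trivial(self):
        assert np.allclose(total_from_mr_network(np.eye(3), np.zeros(3)).Gtot, 0.0)

    def test_acyclic_corollary(self, acyclic_graph):
        # no cycles: Gtot = Theta - I with zero self-loops
        theta = mr_network_from_graph(acyclic_graph)
        res = total_from_mr_network(theta, np.zeros(3))
        assert np.allclose(res.Gtot, acyclic_graph, atol=1e-12)

    def test_cyclic_self_consistency(self, cyclic_graph):
        theta = mr_network_from_graph(cyclic_graph)
        t_diag = np.diag(total_effect_network(cyclic_graph).Gtot)
        res = total_from_mr_network(theta, t_diag)
        assert np.allclose(res.Gtot, total_effect_network(cyclic_graph).Gtot, atol=1e-10)


class TestContainers:
    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ModelViolationError):
            DirectEffectGraph(np.array([[0.1, 0.0], [0.0, 0.0]]))

    def test_estimated_graph_with_large_radius_flagged_not_rejected(self):
        G = np.array([[0.0, 1.5], [0.9, 0.0]])  # radius > 1
        graph = DirectEffectGraph(G)
        assert graph.spectral_warning
        assert not is_admissible(G)

    def test_mr_network_requires_unit_diagonal(self):
        with pytest.raises(ValueError, match="unit diagonal"):
            MREffectNetwork(np.array([[2.0, 0.0], [0.0, 1.0]]))


def test_mvmr_equivalence_on_noiseless_panel(rng):
    """Regressing one trait's total SNP effects on the other traits' total
    effects (over instruments valid for the exposures) returns that trait's
    row of the direct-effect graph: the multivariable-MR estimand equals the
    direct effects."""
    T = 4
    G = random_admissible_graph(rng, T=T, density=0.6)
    n_per = 3  # >= T valid instruments per trait
    S = T * n_per
    Gamma = np.zeros((T, S))
    for t in range(T):
        Gamma[t, t * n_per : (t + 1) * n_per] = rng.uniform(0.3, 1.0, n_per)
    B = steady_state_effects(G, Gamma).B
    for i in range(T):
        others = [j for j in range(T) if j != i]
        cols = np.concatenate([np.arange(j * n_per, (j + 1) * n_per) for j in others])
        coef, *_ = np.linalg.lstsq(B[np.ix_(others, cols)].T, B[i, cols], rcond=None)
        assert np.max(np.abs(coef - G[i, others])) < 1e-8
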