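"""Effective utility, its gradients, and the closed-form equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from garuds.geometry import BoxSpec, FlockState, build_adjacency
from garuds.utility import (
    GarudParams,
    effective_utility,
    lyapunov_value,
    optimal_flock_sizes,
    orientation_utility_gradient,
    position_utility_direction,
    utility_all_agents,
    utility_derivative_wrt_n,
)

from conftest import random_state
from oracles import position_direction_oracle

DEFAULT = GarudParams(0.5, 0.005, 0.25, 1.0, r0=3.0)


class TestEffectiveUtility:
    def test_term_by_term_value(self):
        # 0.5*10 - 0.005*100 + 0.25*10 - ln 10
        assert effective_utility(10, 1.0, DEFAULT) == pytest.approx(
            5.0 - 0.5 + 2.5 - np.log(10.0), abs=1e-12
        )

    def test_isolated_agent_value(self):
        p = GarudParams(0.3, 0.01, 0.7, 2.0)
        assert effective_utility(1, 1.0, p) == pytest.approx(0.3 - 0.01 + 0.7)

    def test_maximum_matches_printed_equilibrium(self):
        pred = optimal_flock_sizes(1.0, DEFAULT)
        assert effective_utility(pred.n_hat_plus, 1.0, DEFAULT) == pytest.approx(23.8, abs=0.05)

    def test_rejects_n_below_one(self):
        with pytest.raises(ValueError):
            effective_utility(0.5, 1.0, DEFAULT)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            GarudParams(0.5, 0.005, 0.25, delta=0.0)
        with pytest.raises(ValueError):
            GarudParams(-0.1, 0.005, 0.25)


class TestPerAgentUtilities:
    def test_matches_hand_evaluation_on_small_fixture(self, box20):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [10.0, 10, 10]])
        vel = np.tile([[0.0, 0, 0.7]], (3, 1))
        state = FlockState(pos, vel)
        adj = build_adjacency(state, 3.0, box20)
        h = utility_all_agents(state, adj, DEFAULT)
        expected_pair = 0.5 * 2 - 0.005 * 4 + 0.25 * 2 * 1.0 - np.log(2.0)
        expected_lone = 0.5 - 0.005 + 0.25
        np.testing.assert_allclose(h, [expected_pair, expected_pair, expected_lone])

    def test_permutation_equivariance(self, rng, box20):
        state = random_state(rng, 20)
        perm = rng.permutation(20)
        permuted = FlockState(state.positions[perm], state.velocities[perm])
        h = utility_all_agents(state, build_adjacency(state, 3.0, box20), DEFAULT)
        hp = utility_all_agents(permuted, build_adjacency(permuted, 3.0, box20), DEFAULT)
        np.testing.assert_allclose(hp, h[perm], atol=1e-12)


class TestDerivativeAndRoots:
    def test_derivative_value_at_one(self):
        assert utility_derivative_wrt_n(1, 1.0, DEFAULT) == pytest.approx(-0.26)

    def test_derivative_vanishes_at_both_roots(self):
        pred = optimal_flock_sizes(1.0, DEFAULT)
        assert abs(utility_derivative_wrt_n(pred.n_hat_minus, 1.0, DEFAULT)) < 1e-9
        assert abs(utility_derivative_wrt_n(pred.n_hat_plus, 1.0, DEFAULT)) < 1e-9

    def test_sign_pattern_around_roots(self):
        pred = optimal_flock_sizes(1.0, DEFAULT)
        mid = 0.5 * (pred.n_hat_minus + pred.n_hat_plus)
        assert utility_derivative_wrt_n(pred.n_hat_minus - 0.2, 1.0, DEFAULT) < 0
        assert utility_derivative_wrt_n(mid, 1.0, DEFAULT) > 0
        assert utility_derivative_wrt_n(pred.n_hat_plus + 5, 1.0, DEFAULT) < 0

    def test_repeated_root_at_zero_discriminant(self):
        # alpha + gamma*l = 0.2, beta = 0.005, delta = 1 -> discriminant 0, root 10
        p = GarudParams(0.2, 0.005, 0.3, 1.0)
        pred = optimal_flock_sizes(0.0, p)
        assert pred.n_hat_minus == pytest.approx(10.0)
        assert pred.n_hat_plus == pytest.approx(10.0)

    def test_negative_discriminant_is_flagged_not_raised(self):
        pred = optimal_flock_sizes(0.0, GarudParams(0.1, 0.05, 0.0, 1.0))
        assert not pred.has_real_roots
        assert np.isnan(pred.n_hat_plus)

    def test_beta_zero_rejected(self):
        with pytest.raises(ValueError):
            optimal_flock_sizes(1.0, GarudParams(0.5, 0.0, 0.25, 1.0))

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(deadline=None, derandomize=True)
    def test_stable_root_monotone_in_alignment(self, l1, l2):
        preds = [optimal_flock_sizes(l, DEFAULT) for l in (l1, l2)]
        if all(p.has_real_roots for p in preds) and l1 < l2:
            assert preds[0].n_hat_plus < preds[1].n_hat_plus


class TestOrientationGradient:
    def test_aligned_pair(self, box20):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        vel = np.array([[0.0, 0, 1.0], [0.0, 0, 1.0]])
        state = FlockState(pos, vel)
        g = orientation_utility_gradient(state, build_adjacency(state, 3.0, box20), DEFAULT)
        np.testing.assert_allclose(g, [[0, 0, 0.5], [0, 0, 0.5]])

    def test_isolated_agent_gradient_is_gamma_times_self(self, box20):
        state = FlockState(np.array([[5.0, 5, 5]]), np.array([[0.6, 0, 0.8]]))
        g = orientation_utility_gradient(state, build_adjacency(state, 3.0, box20), DEFAULT)
        np.testing.assert_allclose(g, 0.25 * state.orientations, atol=1e-12)

    def test_matches_central_finite_differences(self, rng, box20):
        """The analytic rows equal central differences of the alignment
        utility as a function of the agent's (pre-normalization)
        orientation, the neighborhood field held fixed."""
        eps = 1e-6
        for _ in range(100):
            state = random_state(rng, 5)
            adj = build_adjacency(state, 3.0, box20)
            g = orientation_utility_gradient(state, adj, DEFAULT)
            s = state.orientations
            for i in range(5):
                def f(u):
                    return DEFAULT.gamma * sum(
                        float(u @ s[j]) for j in range(5) if adj.adjacency[i, j]
                    )
                fd = np.empty(3)
                for axis in range(3):
                    e = np.zeros(3)
                    e[axis] = eps
                    fd[axis] = (f(s[i] + e) - f(s[i] - e)) / (2 * eps)
                np.testing.assert_allclose(g[i], fd, atol=1e-5)


class TestPositionDirection:
    def test_pull_toward_a_nearby_pair(self, box20):
        """An under-crowded agent just outside r0 of a pair is pulled in."""
        probe = 0.3
        pos = np.array([[5.0, 5, 5], [5.0, 5.8, 5], [5 + 3 + probe / 2, 5.4, 5.0]])
        vel = np.tile([[0.0, 0, 0.9]], (3, 1))
        state = FlockState(pos, vel)
        g = position_utility_direction(state, DEFAULT, box20, probe=probe)
        assert g[2, 0] < 0  # toward the pair (negative x)
        oracle = position_direction_oracle(
            pos, state.orientations, box20.edge_lengths, 3.0, probe, 0.5, 0.005, 0.25, 1.0
        )
        np.testing.assert_allclose(g, oracle, atol=1e-9)

    def test_push_away_from_an_overcrowded_shell(self, box20):
        """Above the stable optimum, shedding far neighbors improves h."""
        params = GarudParams(0.5, 0.02, 0.0, 1.0, r0=3.0)  # n_hat_plus = 10
        probe = 0.3
        rng = np.random.default_rng(7)
        near = 5.0 + np.c_[1.0 + 0.1 * rng.random(6), rng.normal(0, 0.2, 6), rng.normal(0, 0.2, 6)]
        shell = 5.0 + np.c_[2.85 * np.ones(6), rng.normal(0, 0.2, 6), rng.normal(0, 0.2, 6)]
        pos = np.vstack([[5.0, 5, 5], near, shell])
        vel = np.tile([[0.0, 0, 0.9]], (13, 1))
        state = FlockState(pos, vel)
        g = position_utility_direction(state, params, box20, probe=probe)
        oracle = position_direction_oracle(
            pos, state.orientations, box20.edge_lengths, 3.0, probe, 0.5, 0.02, 0.0, 1.0
        )
        np.testing.assert_allclose(g, oracle, atol=1e-9)
        assert g[0, 0] < 0  # away from the crowd sitting at +x

    def test_uniform_crowd_gives_zero_direction(self, box20):
        """When no candidate move changes anything, the force vanishes."""
        state = FlockState(np.array([[5.0, 5, 5]]), np.array([[0.0, 0, 0.9]]))
        g = position_utility_direction(state, DEFAULT, box20)
        np.testing.assert_array_equal(g, np.zeros((1, 3)))

    def test_matches_oracle_on_random_states(self, rng, box20):
        for _ in range(25):
            state = random_state(rng, 12)
            g = position_utility_direction(state, DEFAULT, box20, probe=0.3)
            oracle = position_direction_oracle(
                state.positions, state.orientations, box20.edge_lengths,
                3.0, 0.3, 0.5, 0.005, 0.25, 1.0,
            )
            np.testing.assert_allclose(g, oracle, atol=1e-9)


class TestLyapunov:
    def test_zero_at_equilibrium_positive_below(self):
        assert lyapunov_value(100.0, 100.0) == 0.0
        assert lyapunov_value(90.0, 100.0) > 0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            lyapunov_value(np.inf, 0.0)
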