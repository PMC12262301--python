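import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import srtrace as st
from srtrace import _kernels
from srtrace.learners import (
    SRState,
    empirical_transition_matrix,
    init_onestep,
    init_recency,
    init_srtd,
    onestep_update,
    predictor_value,
    recency_update,
    sr_closed_form,
    srtd_update,
)


class TestRecency:
    def test_single_update_from_uniform(self):
        state = recency_update(init_recency(alpha=0.1), 3)
        assert state.W[3] == pytest.approx(0.9 / 15 + 0.1)
        assert np.allclose(np.delete(state.W, 3), 0.9 / 15)

    def test_alpha_extremes(self):
        s0 = init_recency(alpha=0.0)
        assert np.allclose(recency_update(s0, 5).W, s0.W)
        s1 = recency_update(init_recency(alpha=1.0), 5)
        assert s1.W[5] == 1.0 and s1.W.sum() == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        alpha=hst.floats(0.0, 1.0),
        nodes=hst.lists(hst.integers(0, 14), min_size=1, max_size=50),
    )
    def test_probability_vector_conserved(self, alpha, nodes):
        state = init_recency(alpha)
        for s in nodes:
            state = recency_update(state, s)
        assert state.W.sum() == pytest.approx(1.0, abs=1e-12)
        assert (state.W >= 0).all()


class TestOneStep:
    def test_single_update_from_uniform(self):
        state = onestep_update(init_onestep(alpha=0.1), 1, 2)
        assert state.T[1, 2] == pytest.approx(0.9 / 15 + 0.1)
        assert state.T[1, 0] == pytest.approx(0.9 / 15)
        assert np.allclose(state.T[0], 1 / 15), "only the departed row changes"

    def test_alpha_one_makes_row_onehot(self):
        state = onestep_update(init_onestep(alpha=1.0), 4, 7)
        assert state.T[4, 7] == 1.0 and state.T[4].sum() == pytest.approx(1.0)

    def test_repeated_transition_approaches_one_geometrically(self):
        # closed form of the recursion: T_k = 1 - (1-a)^k (1 - 1/15)
        alpha = 0.2
        state = init_onestep(alpha)
        for k in range(1, 30):
            state = onestep_update(state, 1, 2)
            expected = 1 - (1 - alpha) ** k * (1 - 1 / 15)
            assert state.T[1, 2] == pytest.approx(expected, abs=1e-12)
        assert state.T[1, 2] > 0.99

    @settings(deadline=None, derandomize=True)
    @given(
        alpha=hst.floats(0.0, 1.0),
        steps=hst.lists(
            hst.tuples(hst.integers(0, 14), hst.integers(0, 14)),
            min_size=1, max_size=50,
        ),
    )
    def test_rows_stay_stochastic(self, alpha, steps):
        state = init_onestep(alpha)
        for sp, s in steps:
            state = onestep_update(state, sp, s)
        assert np.allclose(state.T.sum(axis=1), 1.0, atol=1e-12)
        assert (state.T >= 0).all()


class TestSRTD:
    def test_two_state_hand_stepped_update(self):
        state = SRState(M=np.zeros((2, 2)), e=np.zeros(2),
                        alpha=0.5, gamma=0.5, lam=1.0)
        state = srtd_update(state, 0, 1)
        # e[0] -> 1; delta = [0, 1]; M[0,:] += 0.5*[0,1]; e decays by gamma*lam
        assert np.allclose(state.M, [[0.0, 0.5], [0.0, 0.0]])
        assert np.allclose(state.e, [0.5, 0.0])

    def test_lambda_zero_updates_only_previous_state_row(self):
        state = init_srtd(alpha=0.3, gamma=0.7, lam=0.0)
        rng = np.random.default_rng(0)
        prev_m = state.M.copy()
        for _ in range(20):
            sp, s = rng.integers(15, size=2)
            state = srtd_update(state, sp, s)
            changed = np.flatnonzero(np.abs(state.M - prev_m).sum(axis=1) > 0)
            assert set(changed.tolist()) <= {sp}, "pure TD(0) touches one row"
            prev_m = state.M.copy()
            assert np.all(state.e == 0), "trace dies immediately at lambda=0"

    def test_alpha_zero_freezes_m_but_trace_still_evolves(self):
        state = init_srtd(alpha=0.0, gamma=0.5, lam=0.8)
        m0 = state.M.copy()
        state = srtd_update(state, 2, 3)
        assert np.array_equal(state.M, m0)
        assert state.e[2] == pytest.approx(0.4)  # (1-0)*0+1 then *gamma*lam

    def test_lambda_one_bootstrap_terms_telescope(self):
        """At lambda=1 the bootstrap term added for A->B is cancelled by the
        next update, leaving a Monte-Carlo-like composite for row A."""
        rng = np.random.default_rng(7)
        gamma, alpha = 0.8, 0.3
        m0 = rng.random((5, 5))
        a, b, c = 0, 1, 2
        s1 = SRState(M=m0.copy(), e=np.zeros(5), alpha=alpha, gamma=gamma, lam=1.0)
        s1 = srtd_update(s1, a, b)
        m1 = s1.M.copy()
        s2 = srtd_update(s1, b, c)
        onehot = np.eye(5)
        # hand-derived two-step composite: gamma*M[B,:] cancels exactly
        expected_row_a = m0[a] + alpha * (
            onehot[b] + gamma * onehot[c] + gamma**2 * m1[c] - m0[a]
        )
        assert np.allclose(s2.M[a], expected_row_a, atol=1e-12)

    def test_expected_td_error_zero_at_closed_form_fixed_point(self):
        # 3-state chain: enumerate successors under T to take the expectation
        T = np.array([[0.0, 0.7, 0.3], [0.5, 0.0, 0.5], [0.2, 0.8, 0.0]])
        gamma = 0.6
        M = sr_closed_form(T, gamma)
        onehot = np.eye(3)
        for sp in range(3):
            e_delta = sum(
                T[sp, s] * (onehot[s] + gamma * M[s] - M[sp]) for s in range(3)
            )
            assert np.allclose(e_delta, 0.0, atol=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_srtd_converges_toward_closed_form(self, modular_graph, lam):
        gamma, alpha = 0.5, 0.02
        deg = modular_graph.adjacency.sum(axis=1)
        t_true = modular_graph.adjacency / deg[:, None]
        walk = st.random_walk(modular_graph, 60_000, seed=3)
        m0 = np.full((15, 15), 1.0 / (15 * (1 - gamma)))
        m = _kernels.srtd_run(walk.nodes, 15, alpha, gamma, lam, m0)
        err = np.abs(m - sr_closed_form(t_true, gamma)).max()
        assert err < 0.2


class TestClosedFormSR:
    def test_gamma_zero_returns_transition_matrix(self):
        T = np.array([[0.2, 0.8], [0.6, 0.4]])
        assert np.allclose(sr_closed_form(T, 0.0), T)

    def test_two_state_swap_worked_example(self):
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(
            sr_closed_form(T, 0.5), [[2 / 3, 4 / 3], [4 / 3, 2 / 3]]
        )

    def test_rows_sum_to_geometric_series(self):
        rng = np.random.default_rng(1)
        T = rng.random((15, 15))
        T /= T.sum(axis=1, keepdims=True)
        gamma = 0.85
        M = sr_closed_form(T, gamma)
        assert np.allclose(M.sum(axis=1), 1 / (1 - gamma))

    def test_matches_truncated_power_series_within_tail_bound(self):
        rng = np.random.default_rng(2)
        gamma, K = 0.7, 40
        for _ in range(5):
            T = rng.random((15, 15))
            T /= T.sum(axis=1, keepdims=True)
            series = np.zeros_like(T)
            power = np.eye(15)
            for k in range(1, K + 1):
                power = power @ T
                series += gamma ** (k - 1) * power
            gap = np.abs(sr_closed_form(T, gamma) - series).max()
            assert gap <= gamma**K / (1 - gamma)

    def test_divergent_gamma_rejected(self):
        with pytest.raises(ValueError):
            sr_closed_form(np.eye(2), 1.0)


class TestEmpiricalTransitions:
    def test_small_sequences_count_correctly(self):
        T = empirical_transition_matrix([1, 2, 1, 2])
        assert T[1, 2] == 1.0 and T[2, 1] == 1.0
        T = empirical_transition_matrix([1, 2, 1, 3])
        assert T[1, 2] == 0.5 and T[1, 3] == 0.5
        assert np.allclose(T[5], 1 / 15), "never-departed rows are uniform"

    def test_matches_brute_force_counts_on_random_sequence(self):
        rng = np.random.default_rng(3)
        nodes = rng.integers(15, size=500)
        T = empirical_transition_matrix(nodes)
        for i in range(15):
            departs = np.sum(nodes[:-1] == i)
            for j in range(15):
                count = np.sum((nodes[:-1] == i) & (nodes[1:] == j))
                expected = count / departs if departs else 1 / 15
                assert T[i, j] == pytest.approx(expected)

    def test_rows_are_stochastic(self):
        nodes = np.random.default_rng(4).integers(15, size=200)
        T = empirical_transition_matrix(nodes)
        assert np.allclose(T.sum(axis=1), 1.0)


class TestPredictorValue:
    def test_sr_at_fixed_point_is_one_minus_gamma_scaled(self):
        T = np.full((15, 15), 1 / 15)
        gamma = 0.8
        M = sr_closed_form(T, gamma)
        state = SRState(M=M, e=np.zeros(15), alpha=0.1, gamma=gamma, lam=0.5)
        assert predictor_value(state, 0, 3) == pytest.approx(
            (1 - gamma) * M[0, 3]
        )

    def test_initial_predictors_are_uniform(self):
        assert predictor_value(init_onestep(0.1), 2, 9) == pytest.approx(1 / 15)
        assert predictor_value(init_srtd(0.1, 0.5, 0.5), 2, 9) == pytest.approx(1 / 15)

    def test_recency_after_full_update_is_one(self):
        state = recency_update(init_recency(1.0), 6)
        assert predictor_value(state, None, 6) == 1.0


def test_kernel_matches_reference_step_functions(modular_graph):
    """The compiled trial loop and the dataclass step functions agree."""
    walk = st.random_walk(modular_graph, 300, seed=11)
    aw, aa, gamma, lam = 0.15, 0.1, 0.8, 0.6
    w_pred, a_pred, has_prev = _kernels.predictor_series(
        walk.nodes, 15, aw, aa, gamma, lam, _kernels.KIND_SRTD,
        np.empty((15, 15)),
    )
    rec, sr = init_recency(aw), init_srtd(aa, gamma, lam)
    for t, s in enumerate(walk.nodes):
        assert w_pred[t] == pytest.approx(rec.W[s], abs=1e-12)
        if t > 0:
            sp = walk.nodes[t - 1]
            assert has_prev[t]
            assert a_pred[t] == pytest.approx(
                predictor_value(sr, sp, s), abs=1e-12
            )
            sr = srtd_update(sr, sp, s)
        rec = recency_update(rec, s)
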