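"""Numba-compiled inner loops.

The hierarchical fits evaluate the trial-by-trial likelihood thousands of
times per session; the per-trial learner sweep (15x15 SR update under a dutch
eligibility trace) is the hot path and is compiled here. Semantics are
defined by the step functions in :mod:`srtrace.learners`; a test asserts the
two paths agree trial-by-trial.
"""

import numba
import numpy as np

KIND_NONE = 0
KIND_ONESTEP = 1
KIND_SRTD = 2
KIND_STATIC = 3


@numba.njit(cache=True)
def predictor_series(nodes, n_states, alpha_w, alpha_a, gamma, lam, kind, m_static):
    """Run the recency learner plus one higher-order learner over a walk.

    Returns per-trial predictor values recorded *before* that trial's update:
    ``w_pred[t]`` is the recency weight of the upcoming node, ``a_pred[t]``
    the higher-order predictor (transition probability or normalized SR row
    entry). ``has_prev[t]`` is False on the first trial (no predecessor, so
    higher-order predictors are undefined and set to 1/n).
    """
    n = nodes.shape[0]
    w_pred = np.empty(n)
    a_pred = np.empty(n)
    has_prev = np.zeros(n, dtype=numba.boolean)

    uniform = 1.0 / n_states
    w = np.full(n_states, uniform)
    t_mat = np.full((n_states, n_states), uniform)
    # closed-form SR of the uniform transition matrix: constant 1/(n(1-gamma))
    m = np.full((n_states, n_states), uniform / (1.0 - gamma))
    e = np.zeros(n_states)

    for t in range(n):
        s = nodes[t]
        if t == 0:
            w_pred[t] = w[s]
            a_pred[t] = uniform
        else:
            s_prev = nodes[t - 1]
            has_prev[t] = True
            w_pred[t] = w[s]
            if kind == KIND_ONESTEP:
                a_pred[t] = t_mat[s_prev, s]
            elif kind == KIND_SRTD:
                row_sum = 0.0
                for j in range(n_states):
                    row_sum += m[s_prev, j]
                a_pred[t] = m[s_prev, s] / row_sum
            elif kind == KIND_STATIC:
                a_pred[t] = m_static[s_prev, s]
            else:
                a_pred[t] = 0.0

            if kind == KIND_ONESTEP:
                for j in range(n_states):
                    t_mat[s_prev, j] *= 1.0 - alpha_a
                t_mat[s_prev, s] += alpha_a
            elif kind == KIND_SRTD:
                # dutch trace increment, TD error, full M sweep, trace decay
                e[s_prev] = (1.0 - alpha_a) * e[s_prev] + 1.0
                delta = np.empty(n_states)
                for j in range(n_states):
                    delta[j] = gamma * m[s, j] - m[s_prev, j]
                delta[s] += 1.0
                for sp in range(n_states):
                    esp = e[sp]
                    if esp != 0.0:
                        for j in range(n_states):
                            m[sp, j] += alpha_a * esp * delta[j]
                decay = gamma * lam
                for j in range(n_states):
                    e[j] *= decay

        # recency update uses only the current node (runs on every trial)
        for j in range(n_states):
            w[j] *= 1.0 - alpha_w
        w[s] += alpha_w

    return w_pred, a_pred, has_prev


@numba.njit(cache=True)
def srtd_run(nodes, n_states, alpha, gamma, lam, m0, avg_tail=0):
    """SR-TD(lambda) over a walk starting from M = m0.

    Returns the final M, or, when ``avg_tail > 0``, the average of M over
    the last ``avg_tail`` steps (iterate averaging: constant-step TD
    fluctuates in a ball around the fixed point, and the stationary mean is
    the better estimate of the learned representation).
    """
    n = nodes.shape[0]
    m = m0.copy()
    e = np.zeros(n_states)
    m_sum = np.zeros((n_states, n_states))
    n_avg = 0
    for t in range(1, n):
        s_prev = nodes[t - 1]
        s = nodes[t]
        e[s_prev] = (1.0 - alpha) * e[s_prev] + 1.0
        delta = np.empty(n_states)
        for j in range(n_states):
            delta[j] = gamma * m[s, j] - m[s_prev, j]
        delta[s] += 1.0
        for sp in range(n_states):
            esp = e[sp]
            if esp != 0.0:
                for j in range(n_states):
                    m[sp, j] += alpha * esp * delta[j]
        decay = gamma * lam
        for j in range(n_states):
            e[j] *= decay
        if avg_tail > 0 and t >= n - avg_tail:
            m_sum += m
            n_avg += 1
    if n_avg > 0:
        return m_sum / n_avg
    return m
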