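"""Trial-by-trial predictive learners.

Four models of what a subject expects next while watching a walk on a graph:

* **recency** — a recency-weighted running estimate ``W`` of unconditional
  node probabilities (delta rule toward a one-hot of each observed node);
* **one-step** — a learned row-stochastic transition matrix ``T`` between
  consecutive nodes (delta rule on the departed row);
* **SR-TD(lambda)** — the successor representation ``M`` (discounted expected
  future occupancy, one-step-ahead convention ``T + gamma T^2 + ...``)
  learned by temporal-difference updates with a dutch eligibility trace,
  interpolating between pure bootstrapping (lambda=0) and Monte-Carlo-like
  trace learning (lambda=1);
* **static SR** — the closed-form SR of the empirical transition matrix of
  the whole sequence, with no trial-by-trial dynamics.

State containers are plain dataclasses over numpy arrays; the update
functions return new states and are the reference semantics for the compiled
fast path in :mod:`srtrace._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .environments import N_NODES


@dataclass(frozen=True)
class RecencyState:
    W: np.ndarray
    alpha: float


@dataclass(frozen=True)
class OneStepState:
    T: np.ndarray
    alpha: float


@dataclass(frozen=True)
class SRState:
    M: np.ndarray
    e: np.ndarray
    alpha: float
    gamma: float
    lam: float


@dataclass(frozen=True)
class StaticSR:
    M: np.ndarray
    gamma: float


def init_recency(alpha: float, n_states: int = N_NODES) -> RecencyState:
    return RecencyState(W=np.full(n_states, 1.0 / n_states), alpha=alpha)


def init_onestep(alpha: float, n_states: int = N_NODES) -> OneStepState:
    return OneStepState(T=np.full((n_states, n_states), 1.0 / n_states), alpha=alpha)


def init_srtd(
    alpha: float, gamma: float, lam: float, n_states: int = N_NODES
) -> SRState:
    """M starts at the closed-form SR of the uniform transition matrix.

    For uniform T (T^2 = T) the series collapses to the constant matrix
    1/(n(1-gamma)), whose rows sum to 1/(1-gamma).
    """
    m0 = np.full((n_states, n_states), 1.0 / (n_states * (1.0 - gamma)))
    return SRState(M=m0, e=np.zeros(n_states), alpha=alpha, gamma=gamma, lam=lam)


def recency_update(state: RecencyState, s: int) -> RecencyState:
    """W <- (1-alpha) W + alpha * onehot(s); the sum of W is preserved."""
    w = state.W * (1.0 - state.alpha)
    w[s] += state.alpha
    return replace(state, W=w)


def onestep_update(state: OneStepState, s_prev: int, s: int) -> OneStepState:
    """Decay row s_prev by (1-alpha) then add alpha at (s_prev, s)."""
    t = state.T.copy()
    t[s_prev] *= 1.0 - state.alpha
    t[s_prev, s] += state.alpha
    return replace(state, T=t)


def srtd_update(state: SRState, s_prev: int, s: int) -> SRState:
    """One SR-TD(lambda) step with a dutch trace, in the fixed order:

    1. ``e[s_prev] <- (1-alpha) e[s_prev] + 1``  (dutch increment)
    2. ``delta = onehot(s) + gamma M[s,:] - M[s_prev,:]``
    3. ``M[s',:] += alpha e[s'] delta`` for every state s'
    4. ``e <- gamma lambda e``
    """
    e = state.e.copy()
    e[s_prev] = (1.0 - state.alpha) * e[s_prev] + 1.0
    delta = state.gamma * state.M[s] - state.M[s_prev]
    delta[s] += 1.0
    m = state.M + state.alpha * np.outer(e, delta)
    e = state.gamma * state.lam * e
    return replace(state, M=m, e=e)


def sr_closed_form(T: np.ndarray, gamma: float) -> np.ndarray:
    """One-step-ahead SR: ``T (I - gamma T)^{-1} = T + gamma T^2 + ...``.

    Requires ``0 <= gamma < 1`` (the series diverges otherwise). For
    row-stochastic T every row of the result sums to 1/(1-gamma).
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must be in [0, 1), got {gamma}")
    n = T.shape[0]
    return np.linalg.solve(np.eye(n) - gamma * T, T)


def empirical_transition_matrix(nodes: np.ndarray, n_states: int = N_NODES) -> np.ndarray:
    """Count-ratio transition matrix of a sequence.

    ``T[i, j]`` = (#transitions i->j) / (#departures from i); rows of nodes
    never departed from are set uniform.
    """
    nodes = np.asarray(nodes)
    if nodes.size < 2:
        raise ValueError("sequence must have length >= 2")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (nodes[:-1], nodes[1:]), 1.0)
    departures = counts.sum(axis=1)
    t = np.full((n_states, n_states), 1.0 / n_states)
    visited = departures > 0
    t[visited] = counts[visited] / departures[visited, None]
    return t


def static_sr(nodes: np.ndarray, gamma: float, n_states: int = N_NODES) -> StaticSR:
    """SR of the empirical transition matrix of the whole sequence."""
    return StaticSR(
        M=sr_closed_form(empirical_transition_matrix(nodes, n_states), gamma),
        gamma=gamma,
    )


def predictor_value(state, s_prev: int | None, s: int) -> float:
    """The model's expectancy of the upcoming node, read without mutating state.

    Recency reads ``W[s]``; one-step reads ``T[s_prev, s]``; SR variants read
    ``M[s_prev, s]`` normalized by the row sum of ``M[s_prev, :]``.
    """
    if isinstance(state, RecencyState):
        return float(state.W[s])
    if isinstance(state, OneStepState):
        return float(state.T[s_prev, s])
    if isinstance(state, (SRState, StaticSR)):
        row = state.M[s_prev]
        total = row.sum()
        if total <= 0:
            raise ValueError("SR row sum is not positive; cannot normalize")
        return float(row[s] / total)
    raise TypeError(f"unknown learner state {type(state)!r}")
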