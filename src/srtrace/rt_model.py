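"""Shifted log-normal reaction-time model over learner predictions.

Each trial's predicted mean on the log scale is a linear combination

    mu_t = mu0 + beta_trial * trial_t + target_offset + beta_W * W[s_t]
           + beta_A * A[s_{t-1}, s_t] + beta_ntrials * r_ntrials
           + beta_lag10 * r_lag10

where ``W`` is the recency learner's probability vector, ``A`` the
higher-order predictor (one-step T, SR-TD M, or static SR, normalized), and
the last two terms are recency nuisance regressors. RTs follow a shifted
log-normal: ``log(rt - shift) ~ Normal(mu_t, sigma^2)`` with the shift fit as
a fraction of the subject's minimum observed RT.

The first 500 trials of every stage equilibrate the learners but do not
enter the likelihood; error trials and RTs below 30 ms are excluded from the
likelihood (the learners still see every trial).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .environments import N_NODES, StateSequence

EQUILIBRATION_TRIALS = 500
MIN_RT_MS = 30.0
NTRIALS_CAP = 100
LAG_WINDOW = 10

TABLE_COLUMNS = ["subject", "stage", "trial", "node", "target", "rt_ms", "correct"]

_HIGHER_KIND = {
    None: _kernels.KIND_NONE,
    "onestep": _kernels.KIND_ONESTEP,
    "srtd": _kernels.KIND_SRTD,
    "static": _kernels.KIND_STATIC,
}


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors enter mu_t and which learner parameters are free.

    ``higher`` is None (no conditional predictor), "onestep", "srtd" or
    "static". ``use_recency`` adds the recency learner's W predictor. ``lam_fixed`` pins the SR-TD trace parameter instead of
    fitting it. The nuisance regressors and motor-target offsets are always
    included.
    """

    name: str
    use_recency: bool = False
    higher: str | None = None
    lam_fixed: float | None = None

    @property
    def kind_code(self) -> int:
        return _HIGHER_KIND[self.higher]

    def param_names(self) -> list[str]:
        names = ["mu0", "beta_trial"]
        names += [f"target_{k}" for k in range(2, N_NODES + 1)]
        names += ["beta_ntrials", "beta_lag10", "shift_frac", "sigma"]
        if self.use_recency:
            names += ["beta_W", "alpha_W"]
        if self.higher in ("onestep", "srtd"):
            names += ["beta_A", "alpha_A"]
        if self.higher == "srtd":
            names += ["gamma"]
            if self.lam_fixed is None:
                names += ["lam"]
        if self.higher == "static":
            names += ["beta_A", "gamma"]
        return names


MODEL_LIBRARY = {
    "baseline": ModelSpec("baseline"),
    "recency": ModelSpec("recency", use_recency=True),
    "onestep": ModelSpec("onestep", higher="onestep"),
    "srtd": ModelSpec("srtd", higher="srtd"),
    "static_sr": ModelSpec("static_sr", higher="static"),
    "recency_onestep": ModelSpec("recency_onestep", use_recency=True, higher="onestep"),
    "recency_srtd": ModelSpec("recency_srtd", use_recency=True, higher="srtd"),
    "recency_srtd_lam1": ModelSpec(
        "recency_srtd_lam1", use_recency=True, higher="srtd", lam_fixed=1.0
    ),
    "recency_srtd_lam0": ModelSpec(
        "recency_srtd_lam0", use_recency=True, higher="srtd", lam_fixed=0.0
    ),
    "recency_static": ModelSpec("recency_static", use_recency=True, higher="static"),
}


def compute_nuisance(nodes: np.ndarray, cap: int = NTRIALS_CAP,
                     window: int = LAG_WINDOW) -> tuple[np.ndarray, np.ndarray]:
    """Recency nuisance regressors for every trial of one stage.

    ``r_ntrials[t]``: trials since the current node last occurred, capped at
    ``cap`` and set to the cap on its first occurrence. ``r_lag10[t]``:
    log(1 + occurrences of the current node in the previous ``window``
    trials).
    """
    nodes = np.asarray(nodes)
    n = len(nodes)
    r_ntrials = np.empty(n)
    r_lag10 = np.empty(n)
    last_seen = {}
    for t in range(n):
        s = int(nodes[t])
        if s in last_seen:
            r_ntrials[t] = min(t - last_seen[s], cap)
        else:
            r_ntrials[t] = cap
        lo = max(0, t - window)
        r_lag10[t] = np.log1p(int(np.sum(nodes[lo:t] == s)))
        last_seen[s] = t
    return r_ntrials, r_lag10


def shifted_lognormal_loglik(rt, mu, sigma, shift):
    """Log-density of the shifted log-normal, including the Jacobian term.

    Returns -inf where ``rt <= shift`` (outside the support).
    """
    rt = np.asarray(rt, dtype=float)
    out = np.full(rt.shape, -np.inf)
    ok = rt > shift
    y = np.log(rt[ok] - shift)
    z = (y - np.asarray(mu)[ok] if np.ndim(mu) else y - mu) / sigma
    out[ok] = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * z**2 - y
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class Stage:
    """One walk (stage) of a session, 0-based node and target codes."""

    nodes: np.ndarray
    targets: np.ndarray
    rt_ms: np.ndarray
    correct: np.ndarray
    covariate: float = 0.0
    stage_index: int = 0


@dataclass
class Session:
    """All stages for one subject plus precomputed regressors."""

    subject: str
    stages: list[Stage]
    equilibration: int = EQUILIBRATION_TRIALS
    min_rt_ms: float = MIN_RT_MS

    def __post_init__(self):
        self.min_rt = float(min(s.rt_ms[s.rt_ms > 0].min() for s in self.stages))
        self._regressors = []
        for s in self.stages:
            n = len(s.nodes)
            r_nt, r_lag = compute_nuisance(s.nodes)
            r_nt = r_nt / NTRIALS_CAP  # standardized to (0, 1] in the design
            trial_scaled = np.arange(n) / max(n - 1, 1)
            include = (
                (np.arange(n) >= self.equilibration)
                & s.correct.astype(bool)
                & (s.rt_ms >= self.min_rt_ms)
            )
            include[0] = False  # no predecessor
            self._regressors.append((trial_scaled, r_nt, r_lag, include))

    @property
    def covariate(self) -> float:
        # session-level covariate; sessions hold a single stage in fitting
        return self.stages[0].covariate

    def n_included(self) -> int:
        return int(sum(reg[3].sum() for reg in self._regressors))


def predicted_mu(params: dict, trial_scaled, target_offsets, targets,
                 w_pred, a_pred, r_ntrials, r_lag10) -> np.ndarray:
    """The combined linear predictor; absent betas are zero in ``params``."""
    mu = (
        params["mu0"]
        + params["beta_trial"] * trial_scaled
        + target_offsets[targets]
        + params.get("beta_ntrials", 0.0) * r_ntrials
        + params.get("beta_lag10", 0.0) * r_lag10
    )
    if "beta_W" in params:
        mu = mu + params["beta_W"] * w_pred
    if "beta_A" in params:
        mu = mu + params["beta_A"] * a_pred
    return mu


def _target_offsets(params: dict) -> np.ndarray:
    off = np.zeros(N_NODES)
    for k in range(2, N_NODES + 1):
        off[k - 1] = params[f"target_{k}"]
    return off


class SessionLikelihood:
    """Fast total log-likelihood of one session under a model spec.

    Precomputes the parameter-independent regressors once and caches learner
    predictor series keyed on the learner parameters (so coordinate
    perturbations of the linear coefficients during finite differencing do
    not re-run the trial loop).
    """

    def __init__(self, session: Session, spec: ModelSpec):
        self.session = session
        self.spec = spec
        self._pred_cache: dict[tuple, list] = {}

    def _predictors(self, params: dict) -> list:
        key = (
            params.get("alpha_W", 0.0),
            params.get("alpha_A", 0.0),
            params.get("gamma", 0.0),
            params.get("lam", 0.0),
        )
        hit = self._pred_cache.get(key)
        if hit is not None:
            return hit
        out = []
        for stage in self.session.stages:
            gamma = params.get("gamma", 0.0)
            lam = params.get("lam", 0.0)
            if self.spec.lam_fixed is not None:
                lam = self.spec.lam_fixed
            if self.spec.higher == "static":
                from .learners import empirical_transition_matrix, sr_closed_form

                m = sr_closed_form(
                    empirical_transition_matrix(stage.nodes), gamma
                )
                m_static = m / m.sum(axis=1, keepdims=True)
            else:
                m_static = np.empty((N_NODES, N_NODES))
            w_pred, a_pred, has_prev = _kernels.predictor_series(
                stage.nodes,
                N_NODES,
                params.get("alpha_W", 0.0),
                params.get("alpha_A", 0.0),
                min(gamma, 1.0 - 1e-9),
                lam,
                self.spec.kind_code,
                m_static,
            )
            out.append((w_pred, a_pred, has_prev))
        if len(self._pred_cache) > 200:
            self._pred_cache.clear()
        self._pred_cache[key] = out
        return out

    def loglik(self, params: dict) -> float:
        shift = params["shift_frac"] * self.session.min_rt
        sigma = params["sigma"]
        if sigma <= 0:
            return -np.inf
        offsets = _target_offsets(params)
        preds = self._predictors(params)
        total = 0.0
        n_inc = 0
        for stage, reg, (w_pred, a_pred, _) in zip(
            self.session.stages, self.session._regressors, preds
        ):
            trial_scaled, r_nt, r_lag, include = reg
            mu = predicted_mu(
                params, trial_scaled, offsets, stage.targets,
                w_pred, a_pred, r_nt, r_lag,
            )
            rt = stage.rt_ms[include]
            if rt.size == 0:
                continue
            if np.any(rt <= shift):
                return -np.inf
            y = np.log(rt - shift)
            z = (y - mu[include]) / sigma
            total += np.sum(
                -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * z * z - y
            )
            n_inc += rt.size
        if n_inc == 0:
            warnings.warn("all trials excluded; log-likelihood is an empty sum")
            return 0.0
        if not np.isfinite(total):
            return -np.inf
        return float(total)


def sequence_loglik(spec: ModelSpec, params: dict, session: Session) -> float:
    """Total log-likelihood of a session (thin wrapper for one-off use)."""
    return SessionLikelihood(session, spec).loglik(params)


def split_sessions_by_stage(sessions: list[Session]) -> list[Session]:
    """One fitting unit per stage: split multi-stage subjects into sessions.

    The hierarchical fit treats each stage of a subject as its own session
    whose prior mean is shifted by the stage covariate; single-stage
    sessions pass through unchanged.
    """
    out = []
    for s in sessions:
        if len(s.stages) == 1:
            out.append(s)
        else:
            for stage in s.stages:
                out.append(
                    Session(
                        subject=f"{s.subject}/s{stage.stage_index}",
                        stages=[stage],
                        equilibration=s.equilibration,
                        min_rt_ms=s.min_rt_ms,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Trial-table I/O


def session_to_table(session: Session) -> pd.DataFrame:
    rows = []
    for stage in session.stages:
        n = len(stage.nodes)
        rows.append(
            pd.DataFrame(
                {
                    "subject": session.subject,
                    "stage": stage.stage_index,
                    "trial": np.arange(1, n + 1),
                    "node": stage.nodes + 1,
                    "target": stage.targets + 1,
                    "rt_ms": stage.rt_ms,
                    "correct": stage.correct.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def table_to_sessions(table: pd.DataFrame,
                      covariates: dict | None = None) -> list[Session]:
    """Split a trial table into per-subject Sessions (1-based ids -> 0-based)."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s): {missing}")
    sessions = []
    for subject, sub in table.groupby("subject", sort=False):
        stages = []
        stage_ids = sorted(sub["stage"].unique())
        for stage_idx, st in sub.groupby("stage", sort=True):
            st = st.sort_values("trial")
            if covariates is not None:
                cov = covariates.get((subject, stage_idx), 0.0)
            elif len(stage_ids) > 1:
                cov = -1.0 if stage_idx == stage_ids[0] else 1.0
            else:
                cov = 0.0
            stages.append(
                Stage(
                    nodes=st["node"].to_numpy(np.int64) - 1,
                    targets=st["target"].to_numpy(np.int64) - 1,
                    rt_ms=st["rt_ms"].to_numpy(float),
                    correct=st["correct"].to_numpy(bool),
                    covariate=cov,
                    stage_index=int(stage_idx),
                )
            )
        sessions.append(Session(subject=str(subject), stages=stages))
    return sessions


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
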