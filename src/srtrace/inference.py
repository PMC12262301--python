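"""Hierarchical parameter estimation and model comparison.

Subject-level parameters are estimated by MAP under a group-level Gaussian
prior with identity covariance on an unconstrained scale (logit for unit-
interval parameters, log for sigma). Group means (and, when two stages are
present, a stage-difference coefficient per parameter with the stage coded
-1/+1) are re-estimated by closed-form least squares in an expectation-
maximization loop; per-subject marginal likelihoods are approximated by
Laplace's method at the MAP. Models are scored by the negative log marginal
likelihood plus an AIC penalty of one nat per group-level parameter divided
equally between subjects, and compared with one-sided paired t-tests across
subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from .rt_model import ModelSpec, Session, SessionLikelihood

_LOGIT_PARAMS = {"shift_frac", "alpha_W", "alpha_A", "gamma", "lam"}
_LOG_PARAMS = {"sigma"}
_BOUND_EPS = 1e-9


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def transform_params(spec: ModelSpec, natural: dict) -> np.ndarray:
    """Natural-scale parameter dict -> unconstrained vector (spec order)."""
    out = np.empty(len(spec.param_names()))
    for i, name in enumerate(spec.param_names()):
        v = float(natural[name])
        if name in _LOGIT_PARAMS:
            if not 0.0 < v < 1.0:
                warnings.warn(f"{name}={v} clamped into (0, 1)")
                v = np.clip(v, _BOUND_EPS, 1.0 - _BOUND_EPS)
            out[i] = _logit(v)
        elif name in _LOG_PARAMS:
            if v <= 0.0:
                warnings.warn(f"{name}={v} clamped to be positive")
                v = _BOUND_EPS
            out[i] = np.log(v)
        else:
            out[i] = v
    return out


def untransform_params(spec: ModelSpec, u: np.ndarray) -> dict:
    """Unconstrained vector -> natural-scale dict; fixed lambda filled in."""
    natural = {}
    for name, val in zip(spec.param_names(), u):
        if name in _LOGIT_PARAMS:
            natural[name] = float(_expit(val))
        elif name in _LOG_PARAMS:
            natural[name] = float(np.exp(val))
        else:
            natural[name] = float(val)
    if spec.higher == "srtd" and spec.lam_fixed is not None:
        natural["lam"] = float(np.clip(spec.lam_fixed, 1e-6, 1.0 - 1e-6))
    return natural


@dataclass
class FitConfig:
    n_restarts: int = 3
    restart_scale: float = 0.5
    max_opt_iter: int = 300
    hess_step: float = 1e-3
    em_max_iter: int = 200
    em_tol: float = 1e-3
    seed: int = 0


@dataclass
class GroupParams:
    param_names: list
    means: np.ndarray
    stage_coefs: np.ndarray

    def prior_mean(self, covariate: float) -> np.ndarray:
        return self.means + self.stage_coefs * covariate


@dataclass
class SubjectFit:
    subject: str
    map_u: np.ndarray
    map_natural: dict
    neg_log_posterior: float
    hessian: np.ndarray | None = None
    neg_log_marginal: float = np.nan
    converged: bool = True
    hessian_repaired: bool = False


@dataclass
class EMResult:
    spec: ModelSpec
    group: GroupParams
    fits: list
    total_trace: list
    converged: bool


@dataclass
class ModelScore:
    model: str
    subjects: list
    per_subject_scores: np.ndarray
    group_penalty: float


def default_start(spec: ModelSpec, sessions: list[Session]) -> np.ndarray:
    """Data-driven starting group means on the unconstrained scale."""
    logs = []
    for s in sessions:
        shift0 = 0.5 * s.min_rt
        for stage in s.stages:
            rt = stage.rt_ms[stage.rt_ms > shift0]
            logs.append(np.log(rt - shift0))
    y = np.concatenate(logs)
    natural = {name: 0.0 for name in spec.param_names()}
    natural.update(
        mu0=float(np.mean(y)), sigma=float(max(np.std(y), 0.05)),
        shift_frac=0.5,
    )
    for name in spec.param_names():
        if name in ("alpha_W", "alpha_A"):
            natural[name] = 0.15
        elif name == "gamma":
            natural[name] = 0.7
        elif name == "lam":
            natural[name] = 0.5
    return transform_params(spec, natural)


class _Objective:
    """Negative log posterior of one session on the unconstrained scale."""

    def __init__(self, lik: SessionLikelihood, prior_mean: np.ndarray):
        self.lik = lik
        self.spec = lik.spec
        self.prior_mean = prior_mean
        self.d = len(prior_mean)

    def log_prior(self, u: np.ndarray) -> float:
        r = u - self.prior_mean
        return float(-0.5 * r @ r - 0.5 * self.d * np.log(2 * np.pi))

    def __call__(self, u: np.ndarray) -> float:
        natural = untransform_params(self.spec, u)
        ll = self.lik.loglik(natural)
        if not np.isfinite(ll):
            return 1e10
        return -ll - self.log_prior(u)


def _fd_hessian(f, x, step):
    """Central finite-difference Hessian (symmetric by construction)."""
    d = len(x)
    h = np.full(d, step)
    f0 = f(x)
    hess = np.empty((d, d))
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        fp[i] = f(x + ei)
        fm[i] = f(x - ei)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            val = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def map_estimate_subject(
    session: Session,
    spec: ModelSpec,
    prior_mean: np.ndarray,
    config: FitConfig | None = None,
    seed: int = 0,
    start: np.ndarray | None = None,
    compute_hessian: bool = True,
) -> SubjectFit:
    """MAP fit of one session with seeded multistart L-BFGS."""
    config = config or FitConfig()
    lik = SessionLikelihood(session, spec)
    obj = _Objective(lik, prior_mean)
    rng = np.random.default_rng(seed)
    starts = [prior_mean if start is None else start]
    for _ in range(max(config.n_restarts - 1, 0)):
        starts.append(prior_mean + config.restart_scale * rng.standard_normal(obj.d))
    best = None
    any_ok = False
    for x0 in starts:
        res = scipy.optimize.minimize(
            obj, x0, method="L-BFGS-B",
            options={"maxiter": config.max_opt_iter},
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    fit = SubjectFit(
        subject=session.subject,
        map_u=best.x,
        map_natural=untransform_params(spec, best.x),
        neg_log_posterior=float(best.fun),
        converged=bool(any_ok),
    )
    if compute_hessian:
        fit.hessian = _fd_hessian(obj, best.x, config.hess_step)
        fit.neg_log_marginal, fit.hessian_repaired = laplace_marginal(
            fit.neg_log_posterior, fit.hessian
        )
    return fit


def laplace_marginal(neg_log_posterior: float, hessian: np.ndarray):
    """Laplace approximation to the negative log marginal likelihood.

    ``neg_log_posterior`` must include the prior normalization constant.
    Non-positive-definite curvature is repaired by clipping eigenvalues,
    with the repair flagged.
    """
    d = hessian.shape[0]
    eigvals = np.linalg.eigvalsh(0.5 * (hessian + hessian.T))
    repaired = bool(np.any(eigvals <= 0))
    eigvals = np.clip(eigvals, 1e-6, None)
    logdet = float(np.sum(np.log(eigvals)))
    nlm = neg_log_posterior - 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet
    return float(nlm), repaired


def em_fit(
    sessions: list[Session],
    spec: ModelSpec,
    config: FitConfig | None = None,
) -> EMResult:
    """Hierarchical EM over sessions.

    E-like step: per-session MAP + Laplace marginal under the current group
    prior (warm-started from the previous iteration's MAP after the first
    pass). M step: closed-form least squares of MAP vectors on the stage
    covariate. Stops when the total negative log marginal improves by less
    than ``config.em_tol``; the best iterate is kept.
    """
    if len(sessions) < 2:
        raise ValueError("em_fit requires at least 2 sessions")
    config = config or FitConfig()
    names = spec.param_names()
    covs = np.array([s.covariate for s in sessions])
    has_stages = np.any(covs != 0)
    means = default_start(spec, sessions)
    coefs = np.zeros_like(means)
    group = GroupParams(param_names=names, means=means, stage_coefs=coefs)

    best_total = np.inf
    best = None
    totals = []
    prev_maps = [None] * len(sessions)
    oscillated = False
    for it in range(config.em_max_iter):
        fits = []
        for i, session in enumerate(sessions):
            cfg = config if it == 0 else FitConfig(
                n_restarts=1, restart_scale=config.restart_scale,
                max_opt_iter=config.max_opt_iter, hess_step=config.hess_step,
            )
            fit = map_estimate_subject(
                session, spec, group.prior_mean(covs[i]),
                config=cfg, seed=config.seed * 100003 + i,
                start=prev_maps[i],
            )
            prev_maps[i] = fit.map_u
            fits.append(fit)
        total = float(sum(f.neg_log_marginal for f in fits))
        totals.append(total)
        if total < best_total - 1e-12:
            best_total = total
            best = (GroupParams(names, group.means.copy(), group.stage_coefs.copy()),
                    fits)
        elif it > 0 and total > totals[-2] + max(1.0, 10 * config.em_tol):
            oscillated = True
        # M step: joint least squares of MAP vectors on [1, covariate]
        maps = np.array([f.map_u for f in fits])
        if has_stages:
            x = np.column_stack([np.ones(len(sessions)), covs])
            beta, *_ = np.linalg.lstsq(x, maps, rcond=None)
            group = GroupParams(names, beta[0], beta[1])
        else:
            group = GroupParams(names, maps.mean(axis=0), np.zeros_like(means))
        if it > 0 and abs(totals[-2] - total) < config.em_tol:
            break
    converged = len(totals) < config.em_max_iter or (
        len(totals) >= 2 and abs(totals[-1] - totals[-2]) < config.em_tol
    )
    if oscillated:
        warnings.warn("EM objective oscillated; best iterate kept")
    group_best, fits_best = best
    return EMResult(
        spec=spec, group=group_best, fits=fits_best,
        total_trace=totals, converged=converged,
    )


def model_score(result: EMResult, n_group_params: int | None = None) -> ModelScore:
    """Per-subject penalized scores: neg log marginal + k_group / n_subjects."""
    n_sub = len(result.fits)
    if n_group_params is None:
        k = len(result.group.means)
        if np.any(result.group.stage_coefs != 0):
            k += len(result.group.stage_coefs)
        n_group_params = k
    penalty = n_group_params / n_sub
    scores = np.array([f.neg_log_marginal + penalty for f in result.fits])
    return ModelScore(
        model=result.spec.name,
        subjects=[f.subject for f in result.fits],
        per_subject_scores=scores,
        group_penalty=float(n_group_params),
    )


def compare_models(scores_a: np.ndarray, scores_b: np.ndarray):
    """One-sided paired t-test that model b scores lower (fits better) than a.

    Returns dict with t, dof, p (one-sided), and the 95% CI of the mean
    score difference a - b (positive favors b).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    d = a - b
    n = len(d)
    dof = n - 1
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return {"t": 0.0, "dof": dof, "p": 0.5,
                    "ci": (0.0, 0.0), "mean_diff": 0.0, "degenerate": True}
        return {"t": np.inf if mean > 0 else -np.inf, "dof": dof,
                "p": 0.0 if mean > 0 else 1.0, "ci": (mean, mean),
                "mean_diff": float(mean), "degenerate": True}
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(scipy.stats.t.sf(t, dof))
    tcrit = scipy.stats.t.ppf(0.975, dof)
    return {"t": float(t), "dof": dof, "p": p,
            "ci": (float(mean - tcrit * se), float(mean + tcrit * se)),
            "mean_diff": float(mean), "degenerate": False}
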