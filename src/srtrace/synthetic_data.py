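"""Fully synthetic graph-walk RT experiments.

Generates datasets from the same hierarchical generative model the fitting
pipeline assumes: subject-level parameters drawn from a group Gaussian on the
unconstrained scale, RTs drawn per trial from a shifted log-normal whose mean
follows the combined recency + higher-order predictor regression, on random
walks over the task graphs. Also provides pure trace (lambda=1) and
bootstrap (lambda=0) SR-TD agents for the model-agnostic signature analyses.

Default group means are chosen to emulate a serial reaction-time experiment:
median RTs around 700 ms over a 200 ms irreducible motor floor, ~25% log-
normal trial noise, practice speed-up over the session, slower two-key
responses, and negative predictor weights (higher expectancy -> faster RT).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .environments import (
    N_NODES,
    Graph,
    assign_motor_targets,
    build_graph,
    random_walk,
)
from .inference import transform_params, untransform_params
from .rt_model import (
    MODEL_LIBRARY,
    NTRIALS_CAP,
    ModelSpec,
    Session,
    Stage,
    compute_nuisance,
    predicted_mu,
    _target_offsets,
)

DEFAULT_SHIFT_MS = 200.0


def default_group_means(spec: ModelSpec) -> dict:
    """Natural-scale generative group means for every parameter of ``spec``."""
    means = {
        "mu0": 6.2, "beta_trial": -0.15,
        "beta_ntrials": 0.1, "beta_lag10": -0.03,
        "shift_frac": 0.5, "sigma": 0.25,
        "beta_W": -0.8, "alpha_W": 0.15,
        "beta_A": -1.2, "alpha_A": 0.1,
        "gamma": 0.8, "lam": 0.6,
    }
    # two-key combinations (codes 6-15) are slower than single keys (1-5)
    for k in range(2, N_NODES + 1):
        means[f"target_{k}"] = 0.0 if k <= 5 else 0.15
    return {name: means[name] for name in spec.param_names()}


@dataclass
class GenerativeConfig:
    """Study conditions for a simulated experiment."""

    graph_kind: str = "modular"
    model: str = "recency_srtd"
    n_subjects: int = 40
    n_trials: int = 1500
    n_stages: int = 1
    group_means: dict | None = None
    stage_coefs: dict | None = None  # unconstrained-scale, default zeros
    # identity group covariance (unconstrained scale); a dict overrides the
    # spread per parameter, e.g. {"lam": 0.0} pins lambda across subjects
    subject_sd: float | dict = 1.0
    shift_ms: float = DEFAULT_SHIFT_MS
    contamination: float = 0.0
    seed: int = 0


def _stage_mu(
    nodes: np.ndarray,
    targets: np.ndarray,
    params: dict,
    spec: ModelSpec,
) -> np.ndarray:
    gamma = params.get("gamma", 0.0)
    lam = params.get("lam", 0.0)
    if spec.lam_fixed is not None:
        lam = float(np.clip(spec.lam_fixed, 1e-6, 1 - 1e-6))
    if spec.higher == "static":
        from .learners import empirical_transition_matrix, sr_closed_form

        m = sr_closed_form(empirical_transition_matrix(nodes), gamma)
        m_static = m / m.sum(axis=1, keepdims=True)
    else:
        m_static = np.empty((N_NODES, N_NODES))
    w_pred, a_pred, _ = _kernels.predictor_series(
        nodes, N_NODES,
        params.get("alpha_W", 0.0), params.get("alpha_A", 0.0),
        min(gamma, 1 - 1e-9), lam, spec.kind_code, m_static,
    )
    r_nt, r_lag = compute_nuisance(nodes)
    r_nt = r_nt / NTRIALS_CAP  # same standardization as the fitted design
    trial_scaled = np.arange(len(nodes)) / max(len(nodes) - 1, 1)
    return predicted_mu(
        params, trial_scaled, _target_offsets(params), targets,
        w_pred, a_pred, r_nt, r_lag,
    )


def simulate_subject(
    graph: Graph,
    params: dict | list,
    spec: ModelSpec,
    n_trials: int = 1500,
    seed: int = 0,
    shift_ms: float = DEFAULT_SHIFT_MS,
    n_stages: int = 1,
    subject: str = "sim",
    contamination: float = 0.0,
) -> Session:
    """Simulate one subject: walk the graph, run the learners, draw RTs.

    ``log(rt - shift_ms) ~ Normal(mu_t, sigma^2)`` with mu_t from the model's
    predictors. ``params`` is a natural-scale dict, or a list of dicts (one
    per stage) when stage-session parameters differ. All trials are correct
    unless ``contamination > 0``, which marks a random fraction as errors or
    implausibly fast responses to exercise the exclusion filters.
    """
    rng = np.random.default_rng(seed)
    target_map = assign_motor_targets(seed=int(rng.integers(2**31 - 1)))
    params_by_stage = params if isinstance(params, list) else [params] * n_stages
    if len(params_by_stage) != n_stages:
        raise ValueError("need one parameter set per stage")
    stages = []
    for k in range(n_stages):
        params = params_by_stage[k]
        walk = random_walk(graph, n_trials, seed=int(rng.integers(2**31 - 1)),
                           stage=k)
        nodes = walk.nodes
        targets = target_map[nodes]
        mu = _stage_mu(nodes, targets, params, spec)
        rt = shift_ms + np.exp(mu + params["sigma"] * rng.standard_normal(n_trials))
        correct = np.ones(n_trials, dtype=bool)
        if contamination > 0:
            bad = rng.random(n_trials) < contamination
            errors = bad & (rng.random(n_trials) < 0.5)
            fast = bad & ~errors
            correct[errors] = False
            rt[fast] = rng.uniform(5.0, 29.0, fast.sum())
        cov = 0.0 if n_stages == 1 else (-1.0 if k == 0 else 1.0)
        stages.append(Stage(nodes=nodes, targets=targets, rt_ms=rt,
                            correct=correct, covariate=cov, stage_index=k))
    return Session(subject=subject, stages=stages)


def simulate_population(config: GenerativeConfig):
    """Simulate a cohort; returns (sessions, ground_truth, manifest).

    Subject parameters are drawn on the unconstrained scale from
    ``Normal(mean + stage_coef * covariate, subject_sd^2 I)`` and mapped back
    to the natural scale. ``ground_truth`` is a tidy frame with the drawn
    per-subject natural values (the recovery target); the manifest records
    the configuration and per-subject seeds.
    """
    spec = MODEL_LIBRARY[config.model]
    names = spec.param_names()
    means_nat = dict(default_group_means(spec))
    if config.group_means:
        means_nat.update(config.group_means)
    mean_u = transform_params(spec, means_nat)
    coef_u = np.zeros_like(mean_u)
    if config.stage_coefs:
        for i, name in enumerate(names):
            coef_u[i] = config.stage_coefs.get(name, 0.0)
    if isinstance(config.subject_sd, dict):
        sd_vec = np.ones(len(mean_u))
        for i, name in enumerate(names):
            sd_vec[i] = config.subject_sd.get(name, 1.0)
    else:
        sd_vec = np.full(len(mean_u), float(config.subject_sd))
    rng = np.random.default_rng(config.seed)
    graph = build_graph(config.graph_kind, seed=int(rng.integers(2**31 - 1)))
    sessions, truth_rows, seeds = [], [], {}
    for i in range(config.n_subjects):
        sid = f"sub{i:03d}"
        # single-stage cohorts: covariate 0; two-stage: coded -1/+1 per stage
        covs = [0.0] if config.n_stages == 1 else [-1.0, 1.0][: config.n_stages]
        per_stage = []
        for k, cov in enumerate(covs):
            u = (mean_u + coef_u * cov
                 + sd_vec * rng.standard_normal(len(mean_u)))
            natural = untransform_params(spec, u)
            per_stage.append(natural)
            for j, name in enumerate(names):
                truth_rows.append(
                    {"subject": sid, "stage": k, "parameter": name,
                     "natural": natural[name], "unconstrained": u[j]}
                )
        sub_seed = int(rng.integers(2**31 - 1))
        seeds[sid] = sub_seed
        sessions.append(
            simulate_subject(
                graph, per_stage, spec, n_trials=config.n_trials,
                seed=sub_seed, shift_ms=config.shift_ms,
                n_stages=config.n_stages, subject=sid,
                contamination=config.contamination,
            )
        )
    truth = pd.DataFrame(truth_rows)
    manifest = {
        "model": config.model,
        "graph_kind": config.graph_kind,
        "n_subjects": config.n_subjects,
        "n_trials": config.n_trials,
        "n_stages": config.n_stages,
        "group_means_natural": means_nat,
        "subject_sd": config.subject_sd,
        "shift_ms": config.shift_ms,
        "contamination": config.contamination,
        "seed": config.seed,
        "subject_seeds": seeds,
    }
    return sessions, truth, manifest


SIGNATURE_AGENT_PARAMS = {
    "mu0": 6.2, "beta_trial": 0.0,
    "beta_ntrials": 0.0, "beta_lag10": 0.0,
    "shift_frac": 0.5, "sigma": 0.1,
    "beta_A": -2.0, "alpha_A": 0.3, "gamma": 0.6,
}


def simulate_signature_agents(
    graph: Graph,
    rule: str,
    n_agents: int = 40,
    seed: int = 0,
    n_trials: int = 1500,
) -> list[Session]:
    """Pure SR-TD agents for the trace/bootstrap signature simulations.

    ``rule="trace"`` runs SR-TD(1) (eligibility-trace learning);
    ``rule="bootstrap"`` runs SR-TD(0) (pure one-step bootstrapping). All
    agents share mid-range parameters; only walks, motor maps and RT noise
    vary by seed. The SR predictor weight is strongly negative so that
    expectancy transients are visible over the noise floor.
    """
    if rule not in ("trace", "bootstrap"):
        raise ValueError(f"rule must be 'trace' or 'bootstrap', got {rule!r}")
    spec = MODEL_LIBRARY["srtd"]
    params = dict(SIGNATURE_AGENT_PARAMS)
    for k in range(2, N_NODES + 1):
        params[f"target_{k}"] = 0.0
    params["lam"] = 1.0 - 1e-6 if rule == "trace" else 1e-6
    rng = np.random.default_rng(seed)
    return [
        simulate_subject(
            graph, params, spec, n_trials=n_trials,
            seed=int(rng.integers(2**31 - 1)),
            subject=f"{rule}{i:03d}",
        )
        for i in range(n_agents)
    ]
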