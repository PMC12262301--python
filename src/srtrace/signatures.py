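"""Model-agnostic sequence signatures of trace and bootstrap learning.

Two sliding-window contrasts on the raw walk, independent of any fitted
learning model:

* **trace** — 'SXTST' vs 'X1X2TST': the RT to the final T measures the S->T
  expectation on S's second visit; only a trace mechanism can have
  strengthened S->T from the initial S->X->T triplet. The control matches
  recency of T but the tested S->T transition follows S's first appearance
  in the window.
* **bootstrap** — 'BTSBST' vs 'XTSBST': the initial B->T strengthens T-from-B;
  a bootstrap backup then chains that prediction to S on the subsequent S->B
  transition, speeding the final S->T. In the control the initial B is
  replaced by an unrelated X.

Effects are estimated with a linear mixed model of final-element RT on the
condition indicator plus motor-target fixed effects, with a correlated
random intercept and condition slope per subject (and per graph instance
when several are present); a subject-level paired-means test is the logged
fallback when mixed-model estimation fails.

Also provides the novel-cluster first-vs-second-trial analysis on the
modular graph (a recency-controlled multi-step-prediction contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .environments import Graph
from .rt_model import MIN_RT_MS, NTRIALS_CAP, Session, compute_nuisance


def find_trace_sequences(nodes: np.ndarray, overlap: bool = True) -> pd.DataFrame:
    """Scan all 5-windows for 'SXTST' (trace) and 'X1X2TST' (control).

    Window (a, b, c, d, e): trace when a=d (=S), c=e (=T) and S, X(=b), T
    pairwise distinct; control when c=e (=T), S(=d) not in {a, b} and S != T.
    The two sets are disjoint by construction. Returns one row per match
    with the window start, final index and role nodes.
    """
    nodes = np.asarray(nodes)
    n = len(nodes)
    if n < 5:
        return pd.DataFrame(columns=["kind", "t_start", "t_final", "S", "X", "T"])
    a, b, c, d, e = (nodes[i : n - 4 + i] for i in range(5))
    trace = (a == d) & (c == e) & (a != b) & (b != c) & (a != c)
    control = (c == e) & (d != a) & (d != b) & (d != c) & ~trace
    rows = []
    for kind, mask in (("trace", trace), ("trace_control", control)):
        idx = np.flatnonzero(mask)
        for t in idx:
            rows.append(
                {"kind": kind, "t_start": int(t), "t_final": int(t + 4),
                 "S": int(nodes[t + 3]), "X": int(nodes[t + 1]),
                 "T": int(nodes[t + 2])}
            )
    out = pd.DataFrame(rows, columns=["kind", "t_start", "t_final", "S", "X", "T"])
    if not overlap:
        out = _deoverlap(out, width=5)
    return out


def find_bootstrap_sequences(nodes: np.ndarray, overlap: bool = True) -> pd.DataFrame:
    """Scan all 6-windows for 'BTSBST' (bootstrap) and 'XTSBST' (control).

    Window (a, b, c, d, e, f): bootstrap when a=d (=B), b=f (=T), c=e (=S)
    with B, T, S pairwise distinct; control when b=f, c=e, d=B with
    a not in {B, T, S} and B, T, S pairwise distinct.
    """
    nodes = np.asarray(nodes)
    n = len(nodes)
    cols = ["kind", "t_start", "t_final", "B", "T", "S"]
    if n < 6:
        return pd.DataFrame(columns=cols)
    a, b, c, d, e, f = (nodes[i : n - 5 + i] for i in range(6))
    distinct = (d != b) & (b != c) & (d != c)
    boot = (a == d) & (b == f) & (c == e) & distinct
    control = (
        (b == f) & (c == e) & distinct & (a != d) & (a != b) & (a != c)
    )
    rows = []
    for kind, mask in (("bootstrap", boot), ("bootstrap_control", control)):
        idx = np.flatnonzero(mask)
        for t in idx:
            rows.append(
                {"kind": kind, "t_start": int(t), "t_final": int(t + 5),
                 "B": int(nodes[t + 3]), "T": int(nodes[t + 1]),
                 "S": int(nodes[t + 2])}
            )
    out = pd.DataFrame(rows, columns=cols)
    if not overlap:
        out = _deoverlap(out, width=6)
    return out


def _deoverlap(matches: pd.DataFrame, width: int) -> pd.DataFrame:
    """Greedy left-to-right selection of non-overlapping windows."""
    keep = []
    last_end = -1
    for _, row in matches.sort_values("t_start").iterrows():
        if row["t_start"] > last_end:
            keep.append(row)
            last_end = row["t_start"] + width - 1
    return pd.DataFrame(keep, columns=matches.columns).reset_index(drop=True)


def _structure_match_controls(m: pd.DataFrame, nodes: np.ndarray,
                              pattern: str) -> pd.DataFrame:
    """Drop control windows whose implied graph structure is weaker.

    A trace window 'SXTST' guarantees a two-step path S->X->T in the graph
    and a bootstrap window 'BTSBST' guarantees the edge B-T, which their
    controls do not; converged multi-step expectations are therefore higher
    in the condition windows for purely structural reasons. To keep the
    contrast a test of *update dynamics* rather than topology, controls are
    kept only when the sequence itself witnesses the same structure
    elsewhere: some consecutive triple (S, *, T) for trace controls, some
    consecutive pair (B, T) for bootstrap controls.
    """
    nodes = np.asarray(nodes)
    is_ctrl = m["kind"].str.endswith("_control").to_numpy()
    if pattern == "trace":
        twopaths = set(zip(nodes[:-2].tolist(), nodes[2:].tolist()))
        ok = np.array(
            [(s, t) in twopaths for s, t in zip(m["S"], m["T"])], dtype=bool
        )
    else:
        pairs = set(zip(nodes[:-1].tolist(), nodes[1:].tolist()))
        ok = np.array(
            [(b, t) in pairs for b, t in zip(m["B"], m["T"])], dtype=bool
        )
    return m.loc[~is_ctrl | ok]


def collect_matches(
    sessions: list[Session],
    pattern: str,
    overlap: bool = True,
    graphset: str = "g0",
    match_structure: bool = True,
) -> pd.DataFrame:
    """Pattern matches across sessions with final-element RTs.

    Final-element RTs pass the same exclusion filters as the likelihood
    (correct response, RT >= 30 ms). With ``match_structure`` (default),
    control windows without sequence evidence of the condition's implied
    graph structure are discarded (see :func:`_structure_match_controls`).
    """
    finder = {"trace": find_trace_sequences,
              "bootstrap": find_bootstrap_sequences}[pattern]
    rows = []
    for session in sessions:
        for stage in session.stages:
            m = finder(stage.nodes, overlap=overlap)
            if m.empty:
                continue
            if match_structure:
                m = _structure_match_controls(m, stage.nodes, pattern)
            tf = m["t_final"].to_numpy()
            ok = stage.correct[tf] & (stage.rt_ms[tf] >= MIN_RT_MS)
            m = m.loc[ok].copy()
            m["rt_ms"] = stage.rt_ms[m["t_final"].to_numpy()]
            m["target"] = stage.targets[m["t_final"].to_numpy()]
            m["subject"] = session.subject
            m["stage"] = stage.stage_index
            m["graphset"] = f"{graphset}_s{stage.stage_index}"
            rows.append(m)
    if not rows:
        return pd.DataFrame(
            columns=["kind", "t_start", "t_final", "rt_ms", "target",
                     "subject", "stage", "graphset"]
        )
    return pd.concat(rows, ignore_index=True)


def signature_effect(matches: pd.DataFrame, pattern: str) -> dict:
    """Condition effect (ms) on final-element RT.

    Fits ``rt ~ condition + C(target)`` with a correlated random intercept
    and condition slope per subject (variance components per graph instance
    added when more than one is present). Falls back to a one-sample t-test
    on per-subject mean condition differences if the mixed model fails.
    """
    flag = "is_trace" if pattern == "trace" else "is_bootstrap"
    df = matches.copy()
    df[flag] = (df["kind"] == pattern).astype(float)
    if df[flag].nunique() < 2:
        raise ValueError("both condition levels are required")
    df["rt"] = df["rt_ms"].astype(float)
    formula = f"rt ~ {flag} + C(target)"
    n_graphsets = df["graphset"].nunique()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = (
                {"graphset": "0 + C(graphset)", f"graphset_{flag}": f"0 + C(graphset):{flag}"}
                if n_graphsets > 1 else None
            )
            model = smf.mixedlm(
                formula, df, groups=df["subject"],
                re_formula=f"~{flag}", vc_formula=vc,
            )
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        import scipy.stats as st

        coef = float(fit.params[flag])
        se = float(fit.bse[flag])
        z = coef / se
        p = float(2 * st.norm.sf(abs(z)))
        return {"pattern": pattern, "coef_ms": coef, "se": se, "z": z, "p": p,
                "n_obs": int(len(df)), "n_subjects": df["subject"].nunique(),
                "method": "mixedlm"}
    except Exception as err:  # singular fits, convergence failures
        warnings.warn(f"mixed model failed ({err}); using paired-means fallback")
        per = df.groupby(["subject", flag])["rt"].mean().unstack()
        per = per.dropna()
        diffs = (per[1.0] - per[0.0]).to_numpy()
        import scipy.stats as st

        t, p = st.ttest_1samp(diffs, 0.0)
        return {"pattern": pattern, "coef_ms": float(diffs.mean()),
                "se": float(diffs.std(ddof=1) / np.sqrt(len(diffs))),
                "z": float(t), "p": float(p), "n_obs": int(len(df)),
                "n_subjects": int(len(diffs)), "method": "paired_t"}


def residualize_rts(session: Session, shift_frac: float = 0.5) -> list[np.ndarray]:
    """Residual log RTs after a per-subject trial + motor-target OLS fit.

    Residual = log(rt - shift) - fitted mu under the nuisance-only model
    (intercept, scaled trial number, motor-target offsets); excluded trials
    get NaN. Returns one array per stage.
    """
    shift = shift_frac * session.min_rt
    ys, xs, stage_slices = [], [], []
    pos = 0
    for stage, reg in zip(session.stages, session._regressors):
        trial_scaled, _, _, include = reg
        idx = np.flatnonzero(include)
        y = np.log(stage.rt_ms[idx] - shift)
        x = np.zeros((len(idx), 15))
        x[:, 0] = 1.0
        x[:, 1] = trial_scaled[idx]
        # target dummies (reference = code 0); columns for codes 1..14 pooled
        dummies = pd.get_dummies(stage.targets[idx]).reindex(
            columns=range(15), fill_value=0
        )
        x = np.column_stack([x[:, :2], dummies.to_numpy(float)[:, 1:]])
        ys.append(y)
        xs.append(x)
        stage_slices.append((pos, pos + len(idx), idx, len(stage.nodes)))
        pos += len(idx)
    y_all = np.concatenate(ys)
    x_all = np.vstack(xs)
    beta, *_ = np.linalg.lstsq(x_all, y_all, rcond=None)
    resid_all = y_all - x_all @ beta
    out = []
    for lo, hi, idx, n in stage_slices:
        arr = np.full(n, np.nan)
        arr[idx] = resid_all[lo:hi]
        out.append(arr)
    return out


def cluster_entry_table(
    sessions: list[Session], graph: Graph, max_lag: int = NTRIALS_CAP
) -> pd.DataFrame:
    """First and second trials after each cluster entry, with residual RTs."""
    if graph.cluster_of is None:
        raise ValueError("cluster-entry analysis requires a modular graph")
    cluster_of = graph.cluster_of
    rows = []
    for session in sessions:
        resids = residualize_rts(session)
        for stage, resid in zip(session.stages, resids):
            nodes = stage.nodes
            clusters = cluster_of[nodes]
            r_nt, _ = compute_nuisance(nodes, cap=max_lag)
            for t in range(1, len(nodes)):
                if clusters[t] == clusters[t - 1]:
                    continue
                for step, tt in ((0, t), (1, t + 1)):
                    if tt >= len(nodes) or np.isnan(resid[tt]):
                        continue
                    if step == 1 and clusters[tt] != clusters[t]:
                        continue  # immediately left the new cluster
                    rows.append(
                        {"subject": session.subject,
                         "stage": stage.stage_index,
                         "resid_rt": float(resid[tt]),
                         "cluster_step": step,
                         "time_since_node": int(min(r_nt[tt], max_lag))}
                    )
    return pd.DataFrame(rows)


def cluster_entry_analysis(
    sessions: list[Session], graph: Graph, max_lag: int = NTRIALS_CAP
) -> dict:
    """Mixed model resid_rt ~ time_since_node + cluster_step + (1+cluster_step|subject).

    ``cluster_step`` is 0 on the first trial in a newly entered cluster and
    1 on the second; ``time_since_node`` enters as a categorical lag (capped
    at ``max_lag``) under effects (sum-to-zero) coding, so the cluster_step
    coefficient is relative to the grand mean. A negative coefficient means
    the second trial in a new cluster is faster than the first.
    """
    df = cluster_entry_table(sessions, graph, max_lag=max_lag)
    if df.empty:
        raise ValueError("no cluster-entry trials found")
    # drop singleton lag levels, which make the fixed-effects design singular
    counts = df["time_since_node"].value_counts()
    df = df[df["time_since_node"].isin(counts[counts >= 2].index)].copy()
    import scipy.stats as st

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "resid_rt ~ C(time_since_node, Sum) + cluster_step",
                df, groups=df["subject"], re_formula="~cluster_step",
            )
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        coef = float(fit.params["cluster_step"])
        se = float(fit.bse["cluster_step"])
        z = coef / se
        return {"coef": coef, "se": se, "z": z,
                "p": float(2 * st.norm.sf(abs(z))),
                "n_obs": int(len(df)), "method": "mixedlm"}
    except Exception as err:
        warnings.warn(f"mixed model failed ({err}); using paired-means fallback")
        per = df.groupby(["subject", "cluster_step"])["resid_rt"].mean().unstack()
        per = per.dropna()
        diffs = (per[1] - per[0]).to_numpy()
        t, p = st.ttest_1samp(diffs, 0.0)
        return {"coef": float(diffs.mean()),
                "se": float(diffs.std(ddof=1) / np.sqrt(len(diffs))),
                "z": float(t), "p": float(p), "n_obs": int(len(df)),
                "method": "paired_t"}
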