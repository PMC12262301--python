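"""Fit the learning-model family to the simulated cohorts.

Hierarchical EM fits of the model family (recency-alone, one-step+recency,
combined recency+SR-TD with lambda free and lambda fixed at 1) to the
combined-model cohort, and of {recency, combined} to the recency-only
cohort. Scores (penalized negative log marginal likelihoods) and tidy
parameter tables go to results/fits/.

Run after 01_simulate_experiments.py:
    python analysis/02_fit_learning_models.py [--seed S]
"""

import argparse
from pathlib import Path

import pandas as pd

from srtrace.inference import FitConfig, em_fit, model_score
from srtrace.rt_model import MODEL_LIBRARY, read_trial_table, table_to_sessions

ROOT = Path(__file__).resolve().parents[1]

FITS = [
    ("combined", "recency"),
    ("combined", "recency_onestep"),
    ("combined", "recency_srtd"),
    ("combined", "recency_srtd_lam1"),
    ("recency", "recency"),
    ("recency", "recency_srtd"),
]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--restarts", type=int, default=2)
    ap.add_argument("--em-iters", type=int, default=8)
    args = ap.parse_args()

    data_dir = ROOT / "results" / "data"
    out = ROOT / "results" / "fits"
    out.mkdir(parents=True, exist_ok=True)
    config = FitConfig(n_restarts=args.restarts, em_max_iter=args.em_iters,
                       em_tol=1e-2, seed=args.seed)

    score_rows, param_rows = [], []
    cache = {}
    for dataset, model in FITS:
        if dataset not in cache:
            cache[dataset] = table_to_sessions(
                read_trial_table(data_dir / f"{dataset}_trials.tsv")
            )
        sessions = cache[dataset]
        result = em_fit(sessions, MODEL_LIBRARY[model], config)
        score = model_score(result)
        print(f"{dataset} / {model}: total penalized score "
              f"{score.per_subject_scores.sum():.1f} "
              f"({len(result.total_trace)} EM iterations)")
        for fit, s in zip(result.fits, score.per_subject_scores):
            score_rows.append({"dataset": dataset, "model": model,
                               "subject": fit.subject, "score": s})
            for name, u in zip(MODEL_LIBRARY[model].param_names(), fit.map_u):
                param_rows.append({
                    "dataset": dataset, "model": model,
                    "subject": fit.subject, "parameter": name,
                    "natural": fit.map_natural[name],
                    "unconstrained": float(u),
                })
    pd.DataFrame(score_rows).to_csv(out / "scores.tsv", sep="\t", index=False)
    pd.DataFrame(param_rows).to_csv(out / "parameters.tsv", sep="\t",
                                    index=False)
    print(f"wrote {out / 'scores.tsv'} and parameters.tsv")


if __name__ == "__main__":
    main()
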