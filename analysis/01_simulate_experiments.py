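"""Simulate the synthetic study cohorts.

Generates (i) a cohort from the combined recency + SR-TD(lambda) generative
model, (ii) a cohort from the recency-only model (used as the null for model
selection), and (iii) pure trace (lambda=1) and bootstrap (lambda=0) SR-TD
agent populations for the sequence-signature analyses. Trial tables, ground
truth and manifests are written under results/data/.

Run:  python analysis/01_simulate_experiments.py [--n-subjects N] [--seed S]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import srtrace as st
from srtrace.rt_model import session_to_table, write_trial_table
from srtrace.synthetic_data import GenerativeConfig, simulate_population

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-subjects", type=int, default=12)
    ap.add_argument("--n-trials", type=int, default=1500)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)

    for label, model in (("combined", "recency_srtd"), ("recency", "recency")):
        cfg = GenerativeConfig(
            model=model, n_subjects=args.n_subjects, n_trials=args.n_trials,
            seed=args.seed if label == "combined" else args.seed + 1,
        )
        sessions, truth, manifest = simulate_population(cfg)
        table = pd.concat([session_to_table(s) for s in sessions],
                          ignore_index=True)
        write_trial_table(table, out / f"{label}_trials.tsv")
        truth.to_csv(out / f"{label}_ground_truth.tsv", sep="\t", index=False)
        (out / f"{label}_manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
        print(f"{label}: {len(sessions)} subjects x {args.n_trials} trials "
              f"({model} generative model)")

    graph = st.build_graph("modular")
    for rule in ("trace", "bootstrap"):
        agents = st.simulate_signature_agents(
            graph, rule, n_agents=args.n_subjects, seed=args.seed + 10,
            n_trials=args.n_trials,
        )
        table = pd.concat([session_to_table(s) for s in agents],
                          ignore_index=True)
        write_trial_table(table, out / f"{rule}_agents_trials.tsv")
        print(f"{rule} agents: {len(agents)} x {args.n_trials} trials")


if __name__ == "__main__":
    main()
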