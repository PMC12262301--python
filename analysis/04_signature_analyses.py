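"""Model-agnostic sequence signatures and the novel-cluster analysis.

Runs the trace ('SXTST' vs 'X1X2TST') and bootstrap ('BTSBST' vs 'XTSBST')
contrasts on the simulated trace and bootstrap agent populations (the
double dissociation: each rule shows facilitation only for its own
signature), and the first-vs-second cluster-entry contrast on the
combined-model cohort. Reports to results/signatures/.

Run after 01_simulate_experiments.py:
    python analysis/04_signature_analyses.py
"""

import json
from pathlib import Path

import pandas as pd

import srtrace as st
from srtrace.rt_model import read_trial_table, table_to_sessions
from srtrace.signatures import (
    cluster_entry_analysis,
    collect_matches,
    signature_effect,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    data_dir = ROOT / "results" / "data"
    out = ROOT / "results" / "signatures"
    out.mkdir(parents=True, exist_ok=True)

    effects = {}
    for rule in ("trace", "bootstrap"):
        sessions = table_to_sessions(
            read_trial_table(data_dir / f"{rule}_agents_trials.tsv")
        )
        for pattern in ("trace", "bootstrap"):
            matches = collect_matches(sessions, pattern)
            eff = signature_effect(matches, pattern)
            effects[f"{rule}_agents_{pattern}_effect"] = eff
            print(f"{rule} agents, {pattern} signature: "
                  f"{eff['coef_ms']:+.1f} ms (SE {eff['se']:.2f}, "
                  f"z={eff['z']:.2f}, p={eff['p']:.2g}, n={eff['n_obs']})")

    sessions = table_to_sessions(
        read_trial_table(data_dir / "combined_trials.tsv")
    )
    graph = st.build_graph("modular")
    cluster = cluster_entry_analysis(sessions, graph)
    effects["cluster_entry"] = cluster
    print(f"cluster entry (second vs first trial): {cluster['coef']:+.4f} "
          f"log-units (z={cluster['z']:.2f}, p={cluster['p']:.2g})")

    (out / "signature_effects.json").write_text(
        json.dumps(effects, indent=2)
    )
    pd.DataFrame(effects).T.to_csv(out / "signature_effects.tsv", sep="\t")
    print(f"wrote {out / 'signature_effects.json'}")


if __name__ == "__main__":
    main()
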