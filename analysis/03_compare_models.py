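"""Model comparison and parameter recovery on the fitted cohorts.

One-sided paired t-tests between model scores (does the combined
recency+SR-TD model beat recency-alone and one-step+recency on data it
generated? does it win spuriously on recency-only data? does freeing lambda
beat fixing it at 1?), plus group-level parameter recovery against the
simulated ground truth. Reports to results/comparisons/.

Run after 02_fit_learning_models.py:
    python analysis/03_compare_models.py
"""

from pathlib import Path

import pandas as pd

from srtrace.inference import compare_models

ROOT = Path(__file__).resolve().parents[1]

CONTRASTS = [
    ("combined", "recency", "recency_srtd",
     "combined beats recency-alone on combined data"),
    ("combined", "recency_onestep", "recency_srtd",
     "combined beats one-step+recency on combined data"),
    ("combined", "recency_srtd_lam1", "recency_srtd",
     "free lambda beats lambda fixed at 1"),
    ("recency", "recency", "recency_srtd",
     "combined vs recency on recency-only data (expect no win)"),
]


def main():
    fits = ROOT / "results" / "fits"
    out = ROOT / "results" / "comparisons"
    out.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(fits / "scores.tsv", sep="\t")

    rows = []
    for dataset, worse, better, label in CONTRASTS:
        sub = scores[scores.dataset == dataset]
        wide = sub.pivot(index="subject", columns="model", values="score")
        res = compare_models(wide[worse].to_numpy(), wide[better].to_numpy())
        rows.append({"dataset": dataset, "worse": worse, "better": better,
                     "t": res["t"], "dof": res["dof"], "p": res["p"],
                     "ci_lo": res["ci"][0], "ci_hi": res["ci"][1],
                     "label": label})
        print(f"{label}: t({res['dof']})={res['t']:.2f}, one-sided "
              f"p={res['p']:.2e}, mean diff {res['mean_diff']:.2f} nats "
              f"[{res['ci'][0]:.2f}, {res['ci'][1]:.2f}]")
    pd.DataFrame(rows).to_csv(out / "model_comparisons.tsv", sep="\t",
                              index=False)

    # group-level recovery: estimated vs simulated subject parameters
    params = pd.read_csv(fits / "parameters.tsv", sep="\t")
    truth = pd.read_csv(ROOT / "results" / "data" / "combined_ground_truth.tsv",
                        sep="\t")
    est = params[(params.dataset == "combined")
                 & (params.model == "recency_srtd")]
    rec_rows = []
    for name in ("alpha_W", "alpha_A", "gamma", "lam", "beta_W", "beta_A"):
        t = truth.loc[truth.parameter == name, "natural"].mean()
        e = est.loc[est.parameter == name, "natural"].mean()
        rec_rows.append({"parameter": name, "true_mean": t, "est_mean": e,
                         "abs_error": abs(t - e)})
        print(f"recovery {name}: true {t:+.3f}, estimated {e:+.3f}, "
              f"|err| {abs(t - e):.3f}")
    pd.DataFrame(rec_rows).to_csv(out / "recovery.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
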