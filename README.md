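# srtrace

Trial-by-trial successor-representation learning from reaction times in
graph sequence tasks.

## The problem

In serial reaction-time tasks where the cue sequence follows a random walk
on a hidden graph, people respond faster to transitions they expect — and
those expectancies span multiple future steps, consistent with a successor
representation (SR): the matrix of discounted expected future state
occupancies,

    M = T + γT² + γ²T³ + … = T (I − γT)⁻¹,

for one-step transition matrix `T` and discount `γ`. How such long-run
predictions are *learned* trial by trial is the open question this package
addresses. The candidate rules form the SR-TD(λ) family, which updates `M`
from a TD error `δ = 1_{s_t} + γ M[s_t,:] − M[s_{t−1},:]` broadcast over a
dutch eligibility trace with decay `γλ`: `λ = 0` is pure one-step
bootstrapping, `λ = 1` is Monte-Carlo-like trace (Hebbian) learning.

`srtrace` provides, for researchers in computational cognitive
neuroscience and anyone modelling RT-based statistical learning:

* **environments** — the three 15-node degree-4 task graphs (modular /
  lattice / random), random-walk sequence generation, motor-target maps;
* **learners** — recency, one-step, SR-TD(λ) with dutch traces, and the
  static closed-form SR;
* **rt_model** — the shifted log-normal RT likelihood over learner
  predictions plus trial, motor and recency nuisance terms, with 500-trial
  equilibration and the standard exclusion rules (errors, RT < 30 ms);
* **inference** — hierarchical EM with Laplace-approximated per-subject
  marginal likelihoods (identity group covariance, stage covariates),
  AIC-penalized model scores, paired-t model comparison;
* **synthetic_data** — fully synthetic cohorts from the hierarchical
  generative model, and pure trace / bootstrap agent populations;
* **signatures** — model-agnostic trace ('SXTST' vs 'X1X2TST') and
  bootstrap ('BTSBST' vs 'XTSBST') sequence contrasts with mixed-effects
  estimation, and the novel-cluster first-vs-second-trial analysis.

See `docs/methods.md` for the model and estimation details.

## Worked example

The numbered scripts under `analysis/` run the study end-to-end on
synthetic cohorts (12 subjects by default; pass `--n-subjects 40` for the
full-size run):

```bash
python analysis/01_simulate_experiments.py --seed 1
python analysis/02_fit_learning_models.py --seed 1
python analysis/03_compare_models.py
python analysis/04_signature_analyses.py
```

`03_compare_models.py` prints, for the 12-subject default:

```
combined beats recency-alone on combined data: t(11)=1.28, one-sided p=1.14e-01, mean diff 7.95 nats [-5.77, 21.68]
combined beats one-step+recency on combined data: t(11)=1.39, one-sided p=9.55e-02, mean diff 5.14 nats [-2.98, 13.27]
free lambda beats lambda fixed at 1: t(11)=0.90, one-sided p=1.95e-01, mean diff 0.59 nats [-0.86, 2.04]
combined vs recency on recency-only data (expect no win): t(11)=-5.28, one-sided p=1.00e+00, mean diff -1.60 nats [-2.27, -0.93]
recovery alpha_W: true +0.212, estimated +0.203, |err| 0.009
recovery alpha_A: true +0.117, estimated +0.115, |err| 0.002
recovery gamma: true +0.734, estimated +0.706, |err| 0.028
recovery lam: true +0.528, estimated +0.493, |err| 0.035
recovery beta_W: true -1.212, estimated -1.460, |err| 0.248
recovery beta_A: true -1.219, estimated -0.838, |err| 0.382
```

Reading this: on data *generated* by the combined recency + SR-TD(λ) model,
the combined model's scores improve on both the recency-alone and the
one-step+recency alternatives (positive mean score differences in nats per
subject; at this demonstration size the one-sided paired t-tests are
directional but not yet significant — the full 40-subject run in the test
suite and acceptance script is powered), and on recency-only data the
combined model shows no spurious win. The recovery block compares
group-mean parameter estimates against the realized simulated population;
bounded learning parameters recover tightly even at 12 subjects, while the
unbounded β weights need the larger cohort.

`04_signature_analyses.py` prints the double dissociation for the simulated
agent populations:

```
trace agents, trace signature: -9.3 ms (SE 2.92, z=-3.19, p=0.0014, n=3025)
trace agents, bootstrap signature: -8.3 ms (SE 5.96, z=-1.40, p=0.16, n=458)
bootstrap agents, trace signature: +19.3 ms (SE 2.87, z=6.70, p=2.1e-11, n=3025)
bootstrap agents, bootstrap signature: -16.4 ms (SE 5.28, z=-3.11, p=0.0019, n=458)
cluster entry (second vs first trial): -0.0329 log-units (z=-0.39, p=0.7)
```

Trace agents respond ~9 ms faster on the final T of 'SXTST' than of the
structure-matched control (a trace update strengthened S→T) but show no
significant bootstrap-signature facilitation; bootstrap agents show
bootstrap facilitation and, if anything, *slower* trace-condition responses.
The cluster-entry contrast (second trial in a newly entered cluster faster
than the first, recency-controlled) is directional here; it is powered in
the dedicated lower-noise simulation in the test suite.

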