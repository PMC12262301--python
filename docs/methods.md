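# Methods

## The problem

In graph sequence-learning ("statistical learning") tasks, people respond to
a stream of cues generated by a random walk on a hidden graph, and their
reaction times (RTs) betray what they expect to see next: expected
transitions are answered faster. Because these expectancies span multiple
future steps (e.g. the cross-cluster surprisal effect on modular graphs),
they are well described by the successor representation (SR) — the
discounted expected future occupancy of each state given the current one.
This package asks the *learning-rule* question: which trial-by-trial update
dynamics best explain the transient fluctuations of those expectancies, and
provides the simulation, fitting and analysis machinery to answer it on
synthetic cohorts (and, via the generic trial-table reader, on real data in
the same format).

## Task environments

Three 15-node, degree-4-regular undirected graphs:

* **modular** — 3 clusters of 5 nodes, complete within-cluster except
  between each cluster's two connector nodes, with the connectors joined in
  a ring of clusters (one cross-cluster edge per cluster pair). Degree-4
  regularity equates one-step transition probabilities across within- and
  between-cluster edges, which is what makes multi-step prediction
  signatures observable.
* **lattice** — a ring in which each node is joined to its two nearest
  neighbours on each side (circulant {1, 2}).
* **random** — a uniformly sampled connected 4-regular graph
  (rejection-sampled for connectivity, seeded).

Stimulus sequences are unbiased random walks (uniform start, uniform over
neighbours). Since all graphs are regular, the walk's stationary
distribution is uniform, so long-run node frequencies are matched across
topologies. Each node is mapped to one of 15 motor responses (5 single-key
plus 10 two-key combinations) by a per-subject random bijection.

## Learning models

All learners see every trial (including trials later excluded from the
likelihood — the stimulus was seen regardless of the response).

* **Recency** (vector `W`, learning rate `alpha_W`):
  `W <- (1 - a) W + a * onehot(s_t)`. `W` stays a probability vector. This
  is an unconditional, recency-weighted estimate of node probabilities.
* **One-step** (matrix `T`, rate `alpha_A`): the departed row decays by
  `(1 - a)` and the observed transition gains `a`; rows stay stochastic.
* **SR-TD(lambda)** (matrix `M`, trace `e`, rate `alpha_A`, discount
  `gamma`, trace parameter `lambda`): per trial, in this exact order,

  1. `e[s_prev] <- (1 - a) e[s_prev] + 1` (dutch trace increment)
  2. `delta = onehot(s) + gamma M[s, :] - M[s_prev, :]`
  3. `M[s', :] += a e[s'] delta` for every state `s'`
  4. `e <- gamma lambda e`

  `lambda = 0` is pure bootstrapping (only the predecessor row updates);
  `lambda = 1` is Monte-Carlo-like trace learning, in which each bootstrap
  term `gamma M[s, :]` is cancelled by the next trial's update because the
  trace decays by exactly `gamma`. The SR here is the one-step-ahead
  convention `M = T + gamma T^2 + gamma^2 T^3 + ... = T (I - gamma T)^{-1}`;
  at the fixed point each row sums to `1/(1 - gamma)`. `M` is initialized at
  the closed form of the uniform transition matrix, which collapses to the
  constant matrix `1/(n (1 - gamma))` (and therefore depends on the fitted
  `gamma`, so it is re-derived at every likelihood evaluation). `e` starts
  at zero for each walk.
* **Static SR**: the closed form applied to the count-ratio empirical
  transition matrix of the entire observed sequence (never-departed rows set
  uniform); no trial-by-trial dynamics.

Predictor read-out happens *before* the trial's update: recency contributes
`W[s_t]`, one-step `T[s_prev, s_t]`, and the SR variants the row-normalized
`M[s_prev, s_t] / sum_j M[s_prev, j]`.

## Reaction-time model

RTs are shifted log-normal: `log(rt_t - shift) ~ Normal(mu_t, sigma^2)`,
where `shift` is fit as a fraction (logit-constrained to (0, 1)) of the
subject's minimum observed RT and

    mu_t = mu0 + beta_trial * trial_t + target_offset(code_t)
         + beta_W * W[s_t] + beta_A * A[s_prev, s_t]
         + beta_ntrials * r_ntrials + beta_lag10 * r_lag10

with `trial_t` rescaled to [0, 1], motor-target code 1 as the reference
level (14 free offsets), `A` the higher-order predictor (absent terms have
their beta fixed at 0; the baseline model sets both predictor betas to 0),
and two recency nuisance regressors: `r_ntrials`, the number of trials since
the current node last occurred (capped at 100, set to the cap on first
occurrence, and standardized to lag/100 in the design so that unit-scale
priors are meaningful), and `r_lag10 = log(1 + occurrences of the node in
the previous 10 trials)` (the log1p form keeps it finite at zero counts).
The first 500 trials of each walk equilibrate the learners but do not enter
the likelihood; error trials and RTs < 30 ms are likewise excluded (the
first trial of a walk has no predecessor and is skipped — it is inside the
equilibration window anyway). Learner state is carried across the
equilibration boundary within a walk and reset between walks.

## Hierarchical estimation

Subject(-session)-level parameters live on an unconstrained scale (logit for
unit-interval parameters, log for `sigma`) under a group Gaussian prior with
**identity covariance** (never estimated). Group means — plus one
stage-difference coefficient per parameter when subjects perform two walks,
with the stage covariate coded -1/+1 — are re-estimated by closed-form least
squares of the subject MAP vectors on the covariate, inside an EM loop:

* E-like step: per-session MAP by multi-start L-BFGS (3 seeded restarts by
  default; warm-started from the previous iteration's MAP after the first
  pass), then a Laplace approximation to the session's negative log marginal
  likelihood, `-log p(y) ~ -log p(y|th) - log p(th) - (d/2) log 2pi
  + (1/2) log det H`, with `H` the central finite-difference Hessian of the
  negative log posterior (step 1e-3; non-positive-definite curvature is
  repaired by eigenvalue clipping at 1e-6 and flagged).
* M step: means (and stage coefficients) by least squares.
* Stopping: total negative log marginal improvement below tolerance
  (1e-3 by default) or the iteration cap; the best iterate is kept and
  oscillation is flagged.

Models are scored per subject by the negative log marginal likelihood plus
an AIC-style penalty of **1 nat per group-level parameter divided equally
between subjects** (the per-subject arithmetic is a package convention; it
is configurable, and only matters for comparisons across models with
different group-parameter counts). Models are compared by one-sided paired
t-tests on these scores across subjects, with the 95% CI of the mean
difference reported.

Numerical notes: the per-trial learner sweep is compiled with numba; learner
predictor series are cached keyed on the learner parameters, so finite
differences along linear coefficients do not re-run the trial loop.
Boundary parameter values are clamped into the open interval with a warning;
lambda-fixed model variants drop `lambda` from the parameter vector and pin
it internally (clamped into (0, 1) by 1e-6).

## Synthetic cohorts

`synthetic_data` draws subject-session parameters on the unconstrained scale
from `Normal(mean + stage_coef * covariate, I)` (the same identity
covariance the fit assumes; per-parameter spread overrides are available,
e.g. to pin `lambda` for a distinguishability cohort), walks the graph,
runs the generating learners, and draws
`rt = shift_ms + exp(mu_t + sigma z)` with a fixed 200 ms motor floor.
Default group means emulate a serial reaction-time experiment: `mu0 = 6.2`
(median RT ~ 700 ms over the floor), `sigma = 0.25` (~25% log-normal trial
noise), practice speed-up `beta_trial = -0.15`, two-key responses 0.15
log-units slower than single-key, nuisance weights `beta_ntrials = 0.1`
(per 100-trial lag), `beta_lag10 = -0.03`, and negative predictor weights
(`beta_W = -0.8`, `beta_A = -1.2`; higher expectancy means faster RT) with
`alpha_W = 0.15`, `alpha_A = 0.1`, `gamma = 0.8`, `lambda = 0.6` — effect
magnitudes chosen to be detectable at cohorts of ~40 subjects. All trials
are generated correct; an optional contamination rate inserts error trials
and sub-30 ms RTs to exercise the exclusion filters. The manifest records
every draw, so recovery studies can compare estimates against the realized
simulated population.

What the generator does *not* emulate: response errors as a process, fatigue
or practice nonlinearities beyond the linear trial term, RT autocorrelation
beyond what the predictors induce, or stage-order effects beyond the linear
stage covariate. Passing tests on these cohorts therefore show that the
estimator and analyses work when the model family is correct — not that the
model family is correct for human data.

**Parameter recovery** is measured group-level: the mean of the estimated
subject-level natural-scale parameters against the mean of the *drawn*
(realized) subject-level parameters. With identity prior covariance the
realized cohort mean itself deviates from the configured group mean by
~`1/sqrt(n)` on the unconstrained scale, so the realized mean is the right
recovery target for assessing the estimator.

**Signature agents** are pure SR-TD populations (no recency component) with
the rule selected by `lambda` (trace: 1, bootstrap: 0) and mid-range shared
parameters `alpha_A = 0.3`, `gamma = 0.6`, `beta_A = -2`, `sigma = 0.1`:
strong, low-noise expectancy coupling so that single-window update
transients are visible at n ~ 40 agents.

## Sequence signatures

The trace contrast compares final-element RTs of 'SXTST' windows (S, X, T
pairwise distinct; the tested S->T follows S's *second* visit, after a
potential trace update from the S->X->T triplet) against 'X1X2TST' controls
(same recency structure for T, but the tested S->T follows S's first
appearance in the window; we additionally require S distinct from X1, X2).
The bootstrap contrast compares 'BTSBST' (the initial B->T can chain to
S->T via a bootstrap backup at S->B) against 'XTSBST'. Condition and
control window sets are disjoint by construction; overlapping windows are
all counted by default (a greedy de-overlap mode is available).

**Structure matching.** A trace condition window implies the graph contains
the triangle S-X-T, and a bootstrap condition window implies the edge B-T —
constraints the corresponding controls do not impose. Converged SR
expectancy alone therefore differs between condition and control windows
(higher when a two-step path S->?->T exists), which would produce a spurious
"signature" for *any* SR-based responder, regardless of learning rule. To
keep the contrast a test of update dynamics, controls are retained only when
the walk itself witnesses the implied structure elsewhere in the sequence
(a consecutive triple S,*,T for trace controls; a consecutive pair B,T for
bootstrap controls). This filter is sequence-based (model-agnostic) and on
by default.

Effects are estimated in milliseconds by a linear mixed model of
final-element RT on the condition indicator plus motor-target fixed
effects, with correlated random intercept and condition slope per subject
(variance components per graph instance are added when more than one is
present). Final-element RTs pass the same exclusion filters as the
likelihood. When mixed-model estimation fails, a one-sample t-test on
per-subject mean condition differences is used and logged.

The **novel-cluster analysis** (modular graph only) residualizes log RTs
against a per-subject trial + motor-target OLS fit, takes the first and
second trials after each cluster entry (the second only if the walk stayed
in the new cluster), and fits
`resid_rt ~ time_since_node + cluster_step + (1 + cluster_step | subject)`
with `time_since_node` categorical up to lag 100 under effects (sum)
coding and `cluster_step` coded 0/1. A negative `cluster_step` coefficient
(second trial faster) is the multi-step-prediction signature; the lag
control removes the recency confound. Singleton lag levels are dropped to
keep the fixed-effects design full-rank.

## Numerical and design choices

* The `r_ntrials` cap (100) and first-occurrence convention bound the
  regressor; the original convention is not documented, so ours is a
  package convention, not a claim about the source experiments.
* SR-TD convergence (against the closed form of the true transition matrix)
  is assessed on the *tail-averaged* iterate (mean of M over the last 50k of
  200k steps): constant-step TD fluctuates in a ball around the fixed point
  and the stationary mean is the meaningful estimate of what was learned.
  The convergence study uses `gamma = 0.5`, `alpha = 0.02` as its fixed
  conditions.
* EM fits at cohort scale (40 subjects x 1500 trials) use 2 restarts and a
  cap of 8 EM iterations with tolerance 1e-2 — the objective is flat well
  before that; single-subject unit tests use the full default settings.
* The lambda-identifiability study generates every subject at
  `lambda = 0.6` exactly (other parameters heterogeneous as usual) and
  compares the free-lambda model against the lambda=1 variant: a
  distinguishability check of the trace parameter at the cohort size.
* One master seed drives every stage (graph sampling, walks, parameter
  draws, optimizer restarts); derived seeds are recorded in manifests.

## Known limitations

* The Laplace approximation can misstate marginals for subjects whose
  posterior is strongly non-Gaussian (e.g. lambda pinned at a boundary);
  repaired-Hessian fits are flagged.
* `gamma` and `lambda` have likelihood plateaus; multi-start MAP mitigates
  but does not eliminate local optima.
* The mixed models use a normal approximation for p-values (z statistics);
  with ~40 subjects this is mildly anticonservative.
* Two-stage designs share one motor mapping per subject and assume the
  same graph across stages; the original experiments also counterbalanced
  graph assignment across subjects, which the generator does not model.
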