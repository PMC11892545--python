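# Methods

`periopolicy` studies what would happen to the 10-year risk of a first
non-surgical tooth extraction in a cohort of Danish 50-year-olds if the
yearly receipt of subsidised periodontal therapy were changed by policy.
Because the underlying register data are access-restricted, the package
pairs a calibrated synthetic cohort generator with the full estimation
machinery, so that every estimator can be validated against a ground truth
that real data cannot provide.

## Estimand and policies

Let `X_t ∈ {NONE, SUPRA, SUB}` be the periodontal-therapy exposure in
calendar year `t` (2011-2020), `Y_{t+1}` the absorbing indicator of a first
non-surgical extraction by year `t+1` (observed 2012-2021), `C` baseline
covariates (demographics and 1990-2010 service-history summaries), `L_t`
pre-treatment time-varying covariates (income percentile, diabetes), `W_t`
post-treatment dental-service covariates, and `O_t` the under-observation
flag (death/emigration censor at year end). The estimand at horizon `k` is
the counterfactual cumulative incidence

    psi_k(d) = P(Y^d_{k+1} = 1)

under a modified treatment policy `d` — a shift function mapping the
naturally occurring treatment and history to an assigned treatment:

* **scenario 1** — no periodontal care in two consecutive years: a treated
  year following a treated year becomes `NONE`;
* **scenario 2** — the same restriction applied to supragingival-only care;
  `SUB` years are never altered;
* **scenario 3** — care extension: an untreated year following a treated
  year is replaced by the previous year's therapy with probability 0.5;
* **identity** — the observed pattern (reference).

Scenarios 1-2 consult the *assigned* previous year by default, so
alternating-year care remains possible under the ban; a natural-history
variant is exposed in `PolicySpec` for sensitivity analyses. Scenario 3 is
defined on the natural history and randomises eligible person-years
independently. The first year has no predecessor and is always kept.

Ground truth is defined with censoring switched off: censoring is a
nuisance the analysis adjusts away, not a competing event.

## Sequentially doubly robust estimation

For each horizon `k` an independent backward recursion is run (only the
last outcome time point is used per horizon, preserving the
treatment-precedes-outcome ordering). With `V_{k+1} = Y_{k+1}` and
`H_t = (C, L_{1..t}, X_{1..t-1}, W_{1..t-1})` — `W` enters only with a
one-year lag, matching the assumed causal ordering — for `t = k..1`:

1. regress `V_{t+1}` on `(H_t, A_t)` among at-risk persons observed through
   `t+1`, giving `Q_t`;
2. set `V_t = Q_t(H_t, A^d_t) + r_t · (V_{t+1} − Q_t(H_t, A_t))`, where
   `r_t = ĝ^d_t(A_t|H_t)/ĝ_t(A_t|H_t) · 1{O_{t+1}=1}/P̂(O_{t+1}=1|H_t,A_t)`;
   persons with an event before `t` carry `V_t = 1`.

`psi_k = mean(V_1)` with standard error `sd(V_1)/sqrt(n)` (the influence-
function variance). The per-step ratio multiplies the residual; cumulative
products arise through nesting. The estimate is consistent if, at each
time, either the outcome regression or the density ratio is consistent
(verified empirically in the test suite by deliberately breaking one side).

Density ratios use the classification trick: each at-risk record is
duplicated with its natural and policy-assigned treatment, a classifier is
trained to tell the copies apart, and the ratio is the classifier's odds
at the natural record. Because the consecutive-year rules are interactive
in the previous *assigned* treatment — itself a deterministic function of
the natural history — that assigned value and its interaction with the
candidate treatment are supplied as engineered features, letting even a
main-effects GLM represent the true log-odds. The identity policy leaves
all records indistinguishable; its ratios are set to 1 directly.

All nuisances are 5-fold cross-fitted: models are trained on the fold
complement, pseudo-outcomes are propagated within training data with the
training fits, and held-out scores are pooled. Fold assignment depends only
on the person index and the seed, so two policies estimated with the same
seed share folds and their per-person scores are paired; risk-difference
variance uses the paired score differences, and risk-ratio variance the
delta method on the log scale.

G-computation (recursion without the residual term) and IPW (cumulative
ratio products) are included as cross-checks without variance estimates.

## Nuisance learners

Every nuisance model is a super learner: candidates are fitted per fold, a
convex weight vector minimises the cross-validated squared-error risk over
the simplex (SLSQP with a best-vertex guard, so the stack never does worse
than its best member), and candidates are refitted on all data. Default
candidates: a ridge-penalised GLM (the MAP counterpart of a Bayesian GLM
with a Gaussian prior), an L1-penalised GLM, and a random forest
(200 trees, minimum leaf 25). Penalties are chosen on an internal grid by
the same folds. Cross-validation uses 2 folds for treatment/ratio and
censoring models and 10 for outcome regressions. Squared error is the
stacking loss (the study did not pin one down; it is switchable in
principle by editing one function).

Two additional families exist for validation: `mean_table`, an exact
conditional-mean lookup over discrete feature combinations ("saturated"
learners for the enumerable process), and an intercept-only constant used
to break the outcome regressions in the double-robustness checks.

Numerical choices that matter:

* rows are canonicalised (lexicographic sort over features and label)
  before fold assignment, making fitted weights invariant to row order;
* standardized GLM features are winsorised at ±5 SD — without this, a few
  extreme covariate values extrapolate rare-event models (censoring) to the
  clipping bounds and single person-years can carry weights of 100;
* binary predictions are clipped to [1e-6, 1−1e-6]; censoring
  probabilities additionally floored at 0.01 (no factor exceeds 100);
* sequential pseudo-outcomes are *not* clipped to [0,1]: they legitimately
  leave the unit interval, and truncating them biases the ratio-weighted
  residuals (only the final estimate and the g-computation plug-in are
  clipped);
* the desk-scale "GLM-only" learner set uses ridge at C = 1; a
  near-unpenalised GLM overfits the ratio classifier where the stacked
  copies are almost separable;
* ratio truncation (a quantile cap) is available in `LearnerConfig` but
  off by default — weights are diagnosed (max and 99th percentile of
  cumulative products per horizon) and flagged beyond a configurable
  bound, not silently trimmed.

## The synthetic registry generator

One row per person; within year `t` the order is `L_t → X_t → W_t →
Y_{t+1} → censoring`, censoring effective at year end so a person censored
in year `t` contributes all year-`t` data. Baseline history summaries are
overdispersed binomial counts of years-with-service over 21 pre-baseline
years, driven by a person-level care latent; income percentile follows a
reflected bounded random walk on [0, 100]; diabetes is absorbing with a
logistic onset hazard; treatment is a two-stage multinomial (any therapy,
then subgingival/surgical vs supragingival-only) with persistence and the
care latent; service indicators respond to same-year treatment with
calendar trends; the extraction hazard is logistic in *measured* covariates
only (history extractions, diabetes, income, recent treated years), so
exchangeability given the recorded history holds by construction. An
optional `confounding_dial` adds an unobserved frailty to both treatment
and outcome models (0 by default). The treatment-effect parameter
`theta_treat` (log-odds per recent treated year, where "recent" means the
current and previous year) defaults to 0 — the null finding; recovery and
coverage studies override it with −0.25 to −0.35.

Default parameters reproduce the published cohort marginals at n = 20 000:
50% men, 95% Danish origin, diabetes 3.8% → 8.0% across the window, 5.9%
lost to follow-up, 25.1% ten-year extraction incidence, 67% with an oral
examination in the first year, and a mean of 6.2 follow-up years with any
periodontal therapy. Applying the policies to the generated histories
yields treated-years means of ≈3.8 (scenario 1), ≈4.7 (scenario 2) and
≈7.0 (scenario 3) against 6.2 observed — within 15% of the reported
reductions/extension.

Two deliberate departures from the published univariate spread:

* the treated-years SD comes out ≈2.2 rather than 3.6. Under a logistic
  persistence-plus-heterogeneity treatment process, an SD of 3.6 requires
  so much between-person spread that yearly therapy propensities approach
  0 and 1 — which contradicts the study's report that positivity weights
  were checked and found acceptable, and inflates the efficient variance
  of the restriction scenarios an order of magnitude beyond the interval
  widths the study shows. The acceptable-weights condition and the mean
  (6.2 years) were prioritised; the SD is a known compromise.
* education is coded with 7 categories (the six tabulated plus an explicit
  1.5% "unknown" level), and the pooled "other" education and municipality
  groups are single categories.

The generator emulates the statistical structure the analysis assumes —
time-varying confounding with treatment-confounder feedback, informative
censoring through measured history, an absorbing first-event outcome — but
not tooth-level disease progression, provider behaviour, or unmeasured
confounding (unless dialled in). Passing tests therefore certify the
estimation machinery, not substantive conclusions about real registries.

## Validation design and problem sizes

* **Exact oracle**: a tiny CPT-specified process (binary treatment, one
  binary confounder, τ ≤ 3, no censoring) whose counterfactual incidence
  is summed exactly over trajectories; stochastic policies are integrated
  out analytically. SDR, g-computation and IPW with saturated learners
  agree with enumeration within 0.01-0.015 at n = 50 000.
* **Coverage**: 100 replicates of a scaled-down design (n = 2000, τ = 5,
  single-GLM learners, protective effect θ = −0.25) under scenario 3 — the
  policy for which the study prints its one numeric CI; 95% intervals
  cover the intervened-simulation truth 90-98 times and absolute bias
  stays under one percentage point. Scenario 1 at this sample size has
  importance-weight tails that dominate the influence-score SD, so nominal
  coverage is not expected there at n = 2000.
* **Double robustness**: at n = 20 000, forcing intercept-only outcome
  regressions (working ratios) or unit ratios (working regressions) keeps
  SDR within one percentage point of truth.
* **Null reproduction**: with θ = 0 at n = 20 000, estimated risk
  differences between every scenario and the observed pattern stay within
  one percentage point at all ten horizons.

These problem sizes are the package's validation design: large enough to
resolve the biases and coverage rates being checked, small enough that the
whole suite is routinely re-runnable. The analysis scripts use the same
n = 20 000 as the study and single-GLM learners by default (the
three-member super learner is the library default and available
throughout via `learners="default"`).

## Known limitations

* Risk-ratio CIs use the unpaired-free delta method on pooled scores; no
  isotonic smoothing is applied across horizons, so incidence curves can
  be locally non-monotone at small n.
* The restriction scenarios are far from the observed law; their efficient
  variance at the 10-year horizon is inherently ~1 pp SE at n = 20 000
  even with correct nuisances. Weight diagnostics should always be read
  alongside the estimates.
* G-computation and IPW are point cross-checks only (no variance).
* The generator's service-history medians match the published table only
  approximately (they are covariates, not calibration targets).
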