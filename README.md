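# periopolicy

Counterfactual periodontal-care policies and the 10-year risk of tooth
loss: a synthetic Danish-style dental-registry cohort generator plus
longitudinal modified-treatment-policy (LMTP) estimation with sequentially
doubly robust (SDR) inference.

## The problem

National guidelines recommend frequent supportive periodontal care, yet
the evidence that annual visits prevent tooth loss is thin. With linked
registry panels one can ask a precise counterfactual question: *if the
yearly receipt of subsidised periodontal therapy had been restricted — say
to no more than once every second year — how would the 10-year cumulative
incidence of a first non-surgical tooth extraction have changed?* The
registry data behind that question are access-restricted, so this package
re-implements the entire analysis as a tested pipeline over a calibrated
synthetic cohort: every estimator can be checked against a generating
truth that real data never provide.

The cohort is one row per person: baseline covariates `C` (demographics,
1990-2010 service-history summaries), yearly pre-treatment covariates
`L_t` (income percentile, diabetes), a three-level exposure
`X_t ∈ {NONE, SUPRA, SUB}` per calendar year 2011-2020, post-treatment
service covariates `W_t`, observation flags `O_t` (death/emigration), and
the absorbing first-extraction outcome `Y_t` observed 2012-2021.

Four policies `d` are implemented as explicit shift functions: the
observed pattern (identity), no therapy in two consecutive years
(scenario 1), no supragingival-only therapy in two consecutive years
(scenario 2), and a 50/50 extension of therapy into untreated years that
follow a treated year (scenario 3). For each horizon `k` the estimand is
the counterfactual cumulative incidence `psi_k(d) = P(Y^d_{k+1} = 1)`,
estimated by the SDR recursion

    V_t = Q_t(H_t, A^d_t) + r_t · (V_{t+1} − Q_t(H_t, A_t)),   V_{k+1} = Y_{k+1}

with cross-fitted super-learner nuisances: sequential outcome regressions
`Q_t`, density ratios `r_t = g^d_t(A_t|H_t)/g_t(A_t|H_t)` estimated by the
classification trick, and censoring factors `1{O_{t+1}=1}/P̂(O_{t+1}=1 |
H_t, A_t)`. `psi_k = mean(V_1)`, `se = sd(V_1)/√n`; risk differences and
risk ratios against the observed pattern use paired per-person scores.
G-computation and IPW are included as cross-checks, and exact enumeration
on a tiny discrete process serves as an independent oracle. See
`docs/methods.md` for the full account.

## Worked example

```python
import periopolicy as pp

cfg = pp.default_config(n_persons=20_000)          # calibrated defaults
panel = pp.simulate_cohort(cfg, seed=1)
s = pp.summarize_cohort(panel)
print(f"{100*s.cumulative_incidence:.1f}% / {s.treated_years_mean:.1f}y / "
      f"{100*s.censored_fraction:.1f}%")
# -> 25.1% / 6.2y / 6.1%
#    (10-year extraction incidence, mean treated years, lost to follow-up)

lc = pp.LearnerConfig.glm_only()                   # desk-scale learners
obs = pp.estimate_sdr(panel, pp.PolicySpec("identity"), horizon=10, learner_cfg=lc, seed=2)
s1  = pp.estimate_sdr(panel, pp.PolicySpec("scenario1"), horizon=10, learner_cfg=lc, seed=2)
c = pp.contrast(s1, obs)
print(f"psi_obs={obs.psi:.3f}  psi_s1={s1.psi:.3f}  rd={100*c.rd:+.2f}pp "
      f"[{100*c.rd_ci95[0]:+.2f}; {100*c.rd_ci95[1]:+.2f}]")
# -> psi_obs=0.260  psi_s1=0.255  rd=-0.46pp [-3.13; +2.22]
```

The observed 10-year extraction risk in the synthetic cohort is 26.0%
once censoring is adjusted away; restricting periodontal care to alternate
years moves it by a fraction of a percentage point — the generator's
built-in null treatment effect, recovered by the estimator. Setting
`cfg.outcome_model.theta_treat` to a negative value makes therapy
protective, and the same pipeline then resolves the policy contrasts
against simulated truth.

The numbered scripts under `analysis/` run the study end to end — cohort
generation and Table-1-style summaries (01), person-years under each
policy (02), oracle truth curves (03), SDR estimation with contrasts and
weight diagnostics (04), and estimates-versus-truth comparison (05) —
writing their tables under `results/`. The same steps are available as a
CLI: `periopolicy simulate | policy | truth | estimate | report`.

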