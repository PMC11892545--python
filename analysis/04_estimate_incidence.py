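"""Estimate counterfactual cumulative incidence under every policy.

Runs the full pipeline on a freshly simulated 20 000-person cohort: cross-
fitted density ratios with censoring adjustment, the sequentially doubly
robust recursion per policy and horizon (1-10), risk differences and risk
ratios against the observed pattern, and weight diagnostics.  Single-GLM
nuisance learners keep the run to a few minutes; swap --learners default
via the CLI for the full ridge/lasso/forest stack.
"""

from pathlib import Path

import periopolicy as pp
from periopolicy.pipeline import RunConfig, run_analysis

OUT = Path(__file__).resolve().parents[1] / "results" / "run"

rc = RunConfig(
    dgp=pp.default_config(n_persons=20_000),
    scenarios=("scenario1", "scenario2", "scenario3"),
    horizons=tuple(range(1, 11)),
    estimator="sdr",
    learners="glm",
    n_folds=5,
    seed=1,
    output_dir=str(OUT),
)
result = run_analysis(rc)

est = result["estimates"]
print("estimated 10-year cumulative incidence (SDR, 5-fold cross-fitting):")
for _, row in est[est.horizon == 10].iterrows():
    print(f"  {row.policy:10s} {100 * row.estimate:5.2f}%  (SE {100 * row.se:.2f} pp, "
          f"max cumulative weight {row.max_weight:.0f})")
con = result["contrasts"]
row = con[(con.policy == "scenario3") & (con.horizon == 10)].iloc[0]
print(f"scenario 3 vs observed at 10 years: rd {100 * row.rd:+.2f}pp "
      f"[{100 * row.rd_ci_low:+.2f}; {100 * row.rd_ci_high:+.2f}], rr {row.rr:.3f}")
print(f"tables in {OUT}")
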