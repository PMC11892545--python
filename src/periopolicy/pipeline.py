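"""Orchestrated runs: simulate -> policy -> estimate -> contrast -> report.

A run takes a data-generating configuration (or an existing panel file), a
list of policy scenarios and horizons, estimates counterfactual cumulative
incidence per scenario and horizon, contrasts every scenario against the
identity (observed) policy, and writes tidy CSV tables plus a manifest
from which the run can be reproduced exactly.  Plot files are optional
artifacts; plotting failures never fail a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import DGPConfig
from .contrasts import contrast
from .estimator import LearnerConfig, estimate_gcomp, estimate_ipw, estimate_sdr, estimate_density_ratios, positivity_diagnostics
from .panel import PanelDataset, read_panel, registry_schema, write_panel
from .policies import NONE, SUB, SUPRA, PolicySpec, apply_policy, person_years_with_therapy
from .simulate import simulate_cohort

log = logging.getLogger("periopolicy")

_LEARNER_CHOICES = ("default", "glm", "saturated")


@dataclass
class RunConfig:
    """Everything needed to reproduce an analysis run."""

    dgp: DGPConfig | None = None
    panel_path: str | None = None
    scenarios: tuple[str, ...] = ("scenario1", "scenario2", "scenario3")
    horizons: tuple[int, ...] = tuple(range(1, 11))
    estimator: str = "sdr"
    learners: str = "default"
    n_folds: int = 5
    seed: int = 1
    output_dir: str = "results/run"
    make_plots: bool = True

    def validate(self) -> None:
        if (self.dgp is None) == (self.panel_path is None):
            raise ValueError("provide exactly one of dgp or panel_path")
        if self.panel_path is not None and not Path(self.panel_path).exists():
            raise FileNotFoundError(self.panel_path)
        bad = [s for s in self.scenarios if s not in ("identity", "scenario1", "scenario2", "scenario3")]
        if bad:
            raise ValueError(f"unknown scenarios: {bad}")
        if self.learners not in _LEARNER_CHOICES:
            raise ValueError(f"learners must be one of {_LEARNER_CHOICES}")
        if self.estimator not in ("sdr", "gcomp", "ipw"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


def _learner_cfg(name: str) -> LearnerConfig:
    return {"default": LearnerConfig.default, "glm": LearnerConfig.glm_only, "saturated": LearnerConfig.saturated}[name]()


def _policy_specs(scenarios, seed) -> list[PolicySpec]:
    specs = [PolicySpec("identity")]
    for s in scenarios:
        if s == "identity":
            continue
        specs.append(PolicySpec(s, rng_seed=seed + 7919) if s == "scenario3" else PolicySpec(s))
    return specs


def treated_proportions(panel: PanelDataset, specs: list[PolicySpec], seed: int) -> pd.DataFrame:
    """Per-year shares of SUPRA and SUB receipt under each policy, plus the
    per-person treated-years mean/SD (the report's Figure-2-style table)."""
    obs = panel.treatment_matrix()
    rows = []
    for spec in specs:
        rng = np.random.default_rng(seed + 7919) if spec.id == "scenario3" else None
        mat = obs if spec.id == "identity" else apply_policy(obs, spec, rng=rng)
        _, mean_ty, sd_ty = person_years_with_therapy(mat)
        for j, year in enumerate(panel.schema.years):
            rows.append(
                {
                    "policy": spec.id,
                    "year": year,
                    "prop_supra": float((mat[:, j] == SUPRA).mean()),
                    "prop_sub": float((mat[:, j] == SUB).mean()),
                    "prop_any": float((mat[:, j] != NONE).mean()),
                    "treated_years_mean": mean_ty,
                    "treated_years_sd": sd_ty,
                }
            )
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> dict[str, object]:
    """Execute a full configured run; returns the tables and writes CSVs."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.dgp is not None:
        log.info("simulating cohort: n=%d", config.dgp.n_persons)
        panel = simulate_cohort(config.dgp, config.seed)
        write_panel(panel, out / "panel.csv")
    else:
        panel = read_panel(config.panel_path, registry_schema())
    cfg = _learner_cfg(config.learners)
    specs = _policy_specs(config.scenarios, config.seed)
    est_fn = {"sdr": estimate_sdr, "gcomp": estimate_gcomp, "ipw": estimate_ipw}[config.estimator]

    est_rows, con_rows = [], []
    results: dict[tuple[str, int], object] = {}
    pos_frames = []
    for spec in specs:
        log.info("estimating under policy %s", spec.id)
        ratios = estimate_density_ratios(panel, spec, cfg, config.n_folds, config.seed)
        diag = positivity_diagnostics(ratios)
        diag.insert(0, "policy", spec.id)
        pos_frames.append(diag)
        for k in config.horizons:
            res = est_fn(panel, spec, k, cfg, config.n_folds, config.seed, ratios=ratios)
            results[(spec.id, k)] = res
            est_rows.append(
                {
                    "policy": spec.id,
                    "horizon": k,
                    "estimate": res.psi,
                    "se": res.se,
                    "ci_low": res.ci95[0] if res.ci95 else None,
                    "ci_high": res.ci95[1] if res.ci95 else None,
                    "estimator": res.estimator,
                    "max_weight": float(diag["max_cumulative_ratio"].iloc[:k].max()),
                }
            )
    if config.estimator == "sdr":
        for spec in specs:
            if spec.id == "identity":
                continue
            for k in config.horizons:
                c = contrast(results[(spec.id, k)], results[("identity", k)])
                con_rows.append(
                    {
                        "policy": c.policy_a,
                        "reference": c.policy_b,
                        "horizon": c.horizon,
                        "rd": c.rd,
                        "rd_se": c.rd_se,
                        "rd_ci_low": c.rd_ci95[0],
                        "rd_ci_high": c.rd_ci95[1],
                        "rr": c.rr,
                        "rr_ci_low": c.rr_ci95[0],
                        "rr_ci_high": c.rr_ci95[1],
                    }
                )
    estimates = pd.DataFrame(est_rows)
    contrasts_df = pd.DataFrame(con_rows)
    treated = treated_proportions(panel, specs, config.seed)
    positivity = pd.concat(pos_frames, ignore_index=True)
    estimates.to_csv(out / "estimates.csv", index=False)
    contrasts_df.to_csv(out / "contrasts.csv", index=False)
    treated.to_csv(out / "treated_years.csv", index=False)
    positivity.to_csv(out / "positivity.csv", index=False)
    manifest = write_manifest(config, out)
    if config.make_plots:
        try:
            _plot_curves(estimates, out / "cumulative_incidence.png")
        except Exception as exc:  # plots are optional artifacts
            log.warning("plotting failed: %s", exc)
    return {
        "panel": panel,
        "estimates": estimates,
        "contrasts": contrasts_df,
        "treated_years": treated,
        "positivity": positivity,
        "manifest": manifest,
    }


def write_manifest(config: RunConfig, out: Path) -> dict:
    d = {
        "package_version": __version__,
        "seed": config.seed,
        "scenarios": list(config.scenarios),
        "horizons": list(config.horizons),
        "estimator": config.estimator,
        "learners": config.learners,
        "n_folds": config.n_folds,
        "panel_path": config.panel_path,
        "dgp": config.dgp.to_dict() if config.dgp else None,
    }
    d["config_hash"] = hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(d, fh, indent=2)
    return d


def run_from_manifest(path, output_dir: str) -> dict[str, object]:
    """Re-execute a run from its manifest; outputs are identical CSVs."""
    with open(path) as fh:
        d = json.load(fh)
    cfg = RunConfig(
        dgp=DGPConfig.from_dict(d["dgp"]) if d.get("dgp") else None,
        panel_path=d.get("panel_path"),
        scenarios=tuple(d["scenarios"]),
        horizons=tuple(d["horizons"]),
        estimator=d["estimator"],
        learners=d["learners"],
        n_folds=d["n_folds"],
        seed=d["seed"],
        output_dir=output_dir,
        make_plots=False,
    )
    return run_analysis(cfg)


def _plot_curves(estimates: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pol, sub in estimates.groupby("policy"):
        sub = sub.sort_values("horizon")
        ax.plot(sub["horizon"], 100 * sub["estimate"], marker="o", label=pol)
        if sub["se"].notna().all():
            ax.fill_between(
                sub["horizon"], 100 * sub["ci_low"], 100 * sub["ci_high"], alpha=0.2
            )
    ax.set_xlabel("years since start of follow-up")
    ax.set_ylabel("cumulative incidence of first extraction (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
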