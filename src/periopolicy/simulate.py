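"""Synthetic registry-cohort simulator.

Within each year t the generation order is ``L_t -> X_t -> W_t -> Y_{t+1}
-> censoring``, with loss to follow-up effective at year end so that a
person censored in year t still contributes all year-t data (and a cross
section of survivors at the end of the window matches how the registry
cohort is tabulated).  The W block enters the treatment model only with a
one-year lag.  Treatment and dental-service use continue after the first
extraction (people keep visiting dentists); the estimand uses the monotone
first-event flag only.

All randomness derives from one master seed via named ``SeedSequence``
children (baseline, history, covariates, treatment, outcome, censoring,
policy), so the module's streams can be tested independently and a run is
byte-reproducible from ``(config, seed)``.

An optional ``policy`` turns the simulator into an intervened one: each
year the natural treatment is drawn from the treatment model given the
*intervened* past, the policy's shift function maps it to the assigned
treatment, and downstream covariates, outcome and censoring respond to the
assigned value.  This is the ground-truth machine used by the truth oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DGPConfig, FOLLOWUP_SERVICES, HISTORY_SERVICES
from .panel import PanelDataset, registry_schema
from .policies import NONE, SUB, SUPRA, PolicySpec, decode_levels, policy_step

_STREAMS = ("baseline", "history", "covariates", "treatment", "outcome", "censoring", "policy")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _rngs(master_seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(master_seed)
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, ss.spawn(len(_STREAMS)))}


def simulate_cohort(
    config: DGPConfig,
    seed: int | None = None,
    *,
    policy: PolicySpec | None = None,
    disable_censoring: bool = False,
    return_internals: bool = False,
):
    """Generate a panel cohort; deterministic given ``(config, seed)``.

    Parameters
    ----------
    policy
        If given, simulate under the policy-intervened treatment process.
    disable_censoring
        Switch loss to follow-up off (used to define ground truth).
    return_internals
        Also return a dict with latent variables and the true per-year
        hazards/censoring probabilities (for calibration checks).
    """
    config.validate()
    master = seed if seed is not None else (config.seed if config.seed is not None else 0)
    rng = _rngs(int(master))
    n, tau = config.n_persons, config.n_treatment_years
    years = [config.start_year + k for k in range(tau)]
    schema = registry_schema(config.n_years, config.start_year)

    # ---- baseline block -------------------------------------------------
    b = config.baseline_dists
    rb = rng["baseline"]
    u = rb.standard_normal(n)  # person-level care latent
    frailty = rb.standard_normal(n)  # unobserved, active iff confounding_dial != 0
    sex = np.where(rb.random(n) < b.p_male, "male", "female")
    origin = np.where(rb.random(n) < b.p_danish, "danish", "other")
    edu_levels = list(b.education_probs)
    education = rb.choice(edu_levels, size=n, p=[b.education_probs[k] for k in edu_levels])
    reg_levels = list(b.region_probs)
    region = rb.choice(reg_levels, size=n, p=[b.region_probs[k] for k in reg_levels])

    # ---- 1990-2010 history summaries ------------------------------------
    h = config.history_dists
    rh = rng["history"]
    H = h.n_history_years
    lam = h.latent_loading
    z: dict[str, np.ndarray] = {}
    hist_counts: dict[str, np.ndarray] = {}
    for svc in HISTORY_SERVICES:
        ic, sd = h.service_propensity[svc]
        zs = lam * u + np.sqrt(1.0 - lam**2) * rh.standard_normal(n)
        hist_counts[svc] = rh.binomial(H, _sigmoid(ic + sd * zs)) if n else np.zeros(0, int)
        z[svc] = zs
    hist_rest = rh.poisson(np.exp(h.restorations_log_mean + h.restorations_log_sd * rh.standard_normal(n)))
    hist_extr = rh.poisson(np.exp(h.extractions_log_mean + h.extractions_log_sd * rh.standard_normal(n)))
    income_base = np.clip(rh.normal(h.income_mean, h.income_sd, size=n), 0.5, 99.5)
    hist_income_sum = np.round(H * income_base + rh.normal(0.0, 30.0, size=n), 1)

    # ---- follow-up ------------------------------------------------------
    cm, tm, om, sm = (
        config.covariate_models,
        config.treatment_model,
        config.outcome_model,
        config.censoring_model,
    )
    rc, rt, ro, rcen = rng["covariates"], rng["treatment"], rng["outcome"], rng["censoring"]
    policy_rng = rng["policy"]
    dial = config.confounding_dial

    rest_rate = np.exp(cm.restorations_log_mean + cm.restorations_log_sd * rc.standard_normal(n))

    income = np.empty((n, tau))
    diabetes = np.zeros((n, tau), dtype=np.int8)
    x_nat = np.zeros((n, tau), dtype=np.int8)
    x_asg = np.zeros((n, tau), dtype=np.int8)
    w_flags = {svc: np.zeros((n, tau), dtype=np.int8) for svc in FOLLOWUP_SERVICES}
    w_rest = np.zeros((n, tau), dtype=np.int32)
    obs = np.ones((n, tau + 1), dtype=bool)
    ever_event = np.zeros(n, dtype=bool)  # event by year t+1, updated at loop end
    event_by = np.zeros((n, tau), dtype=np.int8)  # years 2..tau+1
    true_cens_p = np.full((n, tau), np.nan)
    true_hazard = np.full((n, tau), np.nan)

    inc_prev = income_base.copy()
    dia_prev = None
    exam_hist_share = hist_counts["examination"] / H if n else np.zeros(0)
    # first year has no recorded previous treatment; the share of history
    # years with periodontal therapy stands in for the persistence term
    any_hist_share = (
        np.clip((hist_counts["supragingival"] + hist_counts["subgingival"]) / H, 0.0, 1.0)
        if n
        else np.zeros(0)
    )

    for t in range(tau):
        # L_t
        step = rc.normal(cm.income_drift, cm.income_step_sd, size=n)
        inc = inc_prev + step
        inc = np.abs(inc)  # reflect at 0
        inc = 100.0 - np.abs(100.0 - inc)  # reflect at 100
        inc = np.clip(inc, 0.0, 100.0)
        if t == 0:
            di = cm.diabetes_init
            dia = (rc.random(n) < _sigmoid(di["intercept"] + di["income"] * inc / 100.0)).astype(np.int8)
        else:
            do = cm.diabetes_onset
            onset = rc.random(n) < _sigmoid(do["intercept"] + do["income"] * inc / 100.0)
            dia = np.maximum(dia_prev, onset.astype(np.int8))
        income[:, t] = inc
        diabetes[:, t] = dia

        # X_t (natural draw given intervened past, then policy shift)
        prev_any = (x_asg[:, t - 1] != NONE).astype(float) if t else any_hist_share
        prev_sub = (x_asg[:, t - 1] == SUB).astype(float) if t else np.zeros(n)
        lag_exam = w_flags["examination"][:, t - 1].astype(float) if t else exam_hist_share
        eta = (
            tm.intercept
            + tm.latent_scale * z["supragingival"]
            + tm.prev_any * prev_any
            + tm.income * (inc / 100.0 - 0.65)
            + tm.diabetes * dia
            + tm.lag_examination * (lag_exam - 0.6)
            + tm.trend * t
            + dial * frailty
        )
        any_tx = rt.random(n) < _sigmoid(eta)
        p_sub = _sigmoid(tm.sub_intercept + tm.sub_latent_scale * z["subgingival"] + tm.sub_prev * prev_sub)
        nat = np.where(any_tx, np.where(rt.random(n) < p_sub, SUB, SUPRA), NONE).astype(np.int8)
        x_nat[:, t] = nat
        if policy is not None:
            prev_a = x_asg[:, t - 1] if t else None
            prev_n = x_nat[:, t - 1] if t else None
            x_asg[:, t] = policy_step(policy, nat, prev_a, prev_n, policy_rng)
        else:
            x_asg[:, t] = nat
        treated = (x_asg[:, t] != NONE).astype(float)

        # W_t
        for svc in FOLLOWUP_SERVICES:
            c = cm.services[svc]
            p = _sigmoid(c["intercept"] + c["treated"] * treated + c["trend"] * t + c["latent"] * z[svc])
            w_flags[svc][:, t] = (rc.random(n) < p).astype(np.int8)
        w_rest[:, t] = rc.poisson(rest_rate) if n else np.zeros(0, int)

        # Y_{t+1}: first-extraction hazard among those still event-free
        recent = treated + ((x_asg[:, t - 1] != NONE).astype(float) if t else 0.0)
        hz = _sigmoid(
            om.intercept
            + om.hist_extractions * hist_extr
            + om.diabetes * dia
            + om.income * inc / 100.0
            + om.theta_treat * recent
            + dial * frailty
        )
        true_hazard[:, t] = hz
        new_event = (~ever_event) & (ro.random(n) < hz)
        ever_event = ever_event | new_event
        event_by[:, t] = ever_event.astype(np.int8)

        # censoring at year end -> O_{t+1}
        if sm.enabled and not disable_censoring:
            pc = _sigmoid(sm.intercept + sm.diabetes * dia + sm.income * inc / 100.0)
            true_cens_p[:, t] = pc
            lost = obs[:, t] & (rcen.random(n) < pc)
            obs[:, t + 1] = obs[:, t] & ~lost
        else:
            true_cens_p[:, t] = 0.0
            obs[:, t + 1] = obs[:, t]

        inc_prev, dia_prev = inc, dia

    # ---- assemble panel -------------------------------------------------
    data: dict[str, object] = {"id": np.arange(n, dtype=int)}
    data["C_sex"] = sex
    data["C_origin"] = origin
    data["C_education"] = education
    data["C_region"] = region
    data["C_hist_restorations"] = hist_rest
    data["C_hist_extractions"] = hist_extr
    data["C_hist_income_sum"] = hist_income_sum
    for svc in HISTORY_SERVICES:
        data[f"C_hist_years_{svc}"] = hist_counts[svc]
    x_str = decode_levels(x_asg) if n else np.zeros((0, tau), object)
    for j, year in enumerate(years):
        alive = obs[:, j]
        data[f"L_income_{year}"] = np.round(income[:, j], 1)
        data[f"L_diabetes_{year}"] = diabetes[:, j]
        xcol = x_str[:, j].copy()
        xcol[~alive] = "NONE"  # no service receipt after loss to follow-up
        data[f"X_{year}"] = xcol
        for svc in FOLLOWUP_SERVICES:
            data[f"W_{svc}_{year}"] = np.where(alive, w_flags[svc][:, j], 0).astype(np.int8)
        data[f"W_restorations_{year}"] = np.where(alive, w_rest[:, j], 0).astype(np.int32)
    for k in range(tau + 1):
        data[f"O_{config.start_year + k}"] = obs[:, k].astype(np.int8)
    for j in range(tau):
        year = config.start_year + 1 + j
        col = np.where(obs[:, j + 1], event_by[:, j].astype(float), np.nan)
        data[f"Y_{year}"] = col
    df = pd.DataFrame(data)
    panel = PanelDataset(df, schema)
    if not return_internals:
        return panel
    internals = {
        "u": u,
        "frailty": frailty,
        "latents": z,
        "income": income,
        "x_natural": x_nat,
        "x_assigned": x_asg,
        "event_by": event_by,
        "obs": obs,
        "true_censoring_hazard": true_cens_p,
        "true_event_hazard": true_hazard,
    }
    return panel, internals
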