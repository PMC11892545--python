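"""Configuration of the synthetic dental-registry data-generating process.

The generator emulates a cohort of Danish 50-year-olds followed annually over
an analytical window (default calendar 2011-2021): time-invariant baseline
covariates ``C`` (demographics plus 1990-2010 service-history summaries),
pre-treatment time-varying covariates ``L`` (income percentile, diabetes),
a three-level periodontal-therapy exposure ``X`` per calendar year, post-
treatment dental-service covariates ``W``, informative loss to follow-up
(death/emigration) and an absorbing first non-surgical-extraction outcome.

Default parameter values are calibrated so that a cohort of 20 000 persons
reproduces the registry cohort's published marginals (sex/origin shares,
diabetes prevalence at start and end of follow-up, service-receipt rates,
~5.9% loss to follow-up, ~25% ten-year extraction incidence and a mean of
~6.2 follow-up years with any periodontal therapy).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any


class ConfigError(ValueError):
    """Invalid data-generating-process configuration; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


#: Services with 1990-2010 "years with at least one receipt" summaries.
HISTORY_SERVICES = (
    "supragingival",
    "subgingival",
    "perio_surgery",
    "endodontic",
    "radiograph",
    "examination",
    "prevention",
)

#: Follow-up W-block binary service indicators.
FOLLOWUP_SERVICES = ("examination", "prevention", "radiograph", "endodontic")

EDUCATION_LEVELS = (
    "primary",
    "vocational",
    "short_higher",
    "medium_higher",
    "long_higher",
    "other",
    "unknown",
)

REGIONS = (
    "north_jutland",
    "central_jutland",
    "southern_denmark",
    "capital",
    "zealand",
    "other",
)


def _check_probs(name: str, probs: dict[str, float]) -> None:
    vals = list(probs.values())
    if any((not math.isfinite(v)) or v < 0 for v in vals):
        raise ConfigError(name, "probabilities must be finite and non-negative")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ConfigError(name, f"probabilities sum to {sum(vals)!r}, not 1")


def _check_finite(name: str, obj: Any) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(f"{name}.{k}", v)
    elif isinstance(obj, (tuple, list)):
        for i, v in enumerate(obj):
            _check_finite(f"{name}[{i}]", v)
    elif isinstance(obj, (int, float)):
        if not math.isfinite(obj):
            raise ConfigError(name, "must be finite")


@dataclass
class BaselineDists:
    """Category probabilities for time-invariant covariates."""

    p_male: float = 0.50
    p_danish: float = 0.9477
    education_probs: dict[str, float] = field(
        default_factory=lambda: {
            "primary": 0.2582,
            "vocational": 0.3972,
            "short_higher": 0.0526,
            "medium_higher": 0.1589,
            "long_higher": 0.0606,
            "other": 0.0575,
            "unknown": 0.0150,
        }
    )
    region_probs: dict[str, float] = field(
        default_factory=lambda: {
            "north_jutland": 0.0755,
            "central_jutland": 0.1392,
            "southern_denmark": 0.1392,
            "capital": 0.1988,
            "zealand": 0.1590,
            "other": 0.2883,
        }
    )


@dataclass
class HistoryDists:
    """1990-2010 service-history summaries.

    Years-with-service counts are overdispersed binomials over ``n_history_years``
    years: each person draws a service-specific propensity on the logit scale,
    ``logit p = intercept + sd * z`` with ``z = loading*u + sqrt(1-loading^2)*eps``
    sharing a person-level care latent ``u``.  Restoration and extraction totals
    are log-normal-mixed Poisson counts; the income-percentile *sum* over the
    21 pre-baseline years derives from the person's long-run income level.
    """

    n_history_years: int = 21
    latent_loading: float = 0.6
    service_propensity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "supragingival": (0.75, 1.5),
            "subgingival": (-3.8, 1.6),
            "perio_surgery": (-5.0, 1.2),
            "endodontic": (-2.9, 0.8),
            "radiograph": (-1.16, 0.55),
            "examination": (0.10, 0.85),
            "prevention": (-3.0, 1.0),
        }
    )
    restorations_log_mean: float = 2.5
    restorations_log_sd: float = 0.55
    extractions_log_mean: float = 0.1
    extractions_log_sd: float = 0.7
    income_mean: float = 66.0
    income_sd: float = 24.0


@dataclass
class TreatmentModel:
    """Multinomial model for the yearly exposure X in {NONE, SUPRA, SUB}.

    P(any therapy) is logistic in a slow-moving person propensity (the same
    latent that drives the supragingival history), the previous year's
    treatment indicator (persistence), current income/diabetes and lagged
    examination; given any therapy, P(SUB) is logistic in the subgingival
    history latent and previous-year SUB.
    """

    intercept: float = 0.312
    latent_scale: float = 0.45
    prev_any: float = 0.45
    income: float = 0.30
    diabetes: float = 0.10
    lag_examination: float = 0.25
    trend: float = 0.0
    sub_intercept: float = -1.60
    sub_latent_scale: float = 1.20
    sub_prev: float = 1.00


@dataclass
class CovariateModels:
    """Evolution of the time-varying covariates.

    Income percentile follows a reflected random walk on [0, 100]; diabetes is
    an absorbing state with a logistic onset hazard; each follow-up service
    indicator is logistic in same-year treatment, calendar trend and the
    person's history latent; within-year restoration counts are Poisson.
    """

    income_step_sd: float = 6.0
    income_drift: float = -0.15
    diabetes_init: dict[str, float] = field(
        default_factory=lambda: {"intercept": -2.89, "income": -0.55}
    )
    diabetes_onset: dict[str, float] = field(
        default_factory=lambda: {"intercept": -4.89, "income": -0.55}
    )
    # per-service: intercept, treated (same-year any-therapy), trend (per year
    # since start), latent (loading on the service's history latent)
    services: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "examination": {"intercept": -0.66, "treated": 2.60, "trend": -0.040, "latent": 0.30},
            "prevention": {"intercept": -2.95, "treated": 0.60, "trend": 0.135, "latent": 0.40},
            "radiograph": {"intercept": -1.60, "treated": 0.50, "trend": -0.006, "latent": 0.30},
            "endodontic": {"intercept": -2.95, "treated": 0.15, "trend": -0.045, "latent": 0.30},
        }
    )
    restorations_log_mean: float = -0.80
    restorations_log_sd: float = 0.25


@dataclass
class OutcomeModel:
    """Discrete-time hazard of the first non-surgical extraction.

    ``logit h_{t+1} = intercept + hist_extractions*n + diabetes*D_t
    + income*(I_t/100) + theta_treat * (#treated years among {t, t-1})``.
    The hazard depends on *measured* covariates only, so exchangeability given
    the recorded history holds by construction (unless ``confounding_dial``
    is switched on).  ``theta_treat`` is the log-odds effect per recent
    treated year; the default 0 encodes the null treatment effect.
    """

    intercept: float = -3.29
    hist_extractions: float = 0.10
    diabetes: float = 0.30
    income: float = -0.60
    theta_treat: float = 0.0


@dataclass
class CensoringModel:
    """Yearly hazard of loss to follow-up (death or emigration), effective at
    year end: ``logit = intercept + diabetes*D_t + income*(I_t/100)``.
    Depends on measured history only (informative but adjustable censoring).
    """

    intercept: float = -4.67
    diabetes: float = 0.50
    income: float = -0.80
    enabled: bool = True


@dataclass
class DGPConfig:
    """Full data-generating-process configuration.

    ``n_years`` counts calendar years in the analytical window (default 11,
    i.e. 2011-2021): treatment is generated for the first ``n_years - 1``
    years and the outcome is observed from the second year onwards.
    ``confounding_dial`` adds an unobserved frailty to both the treatment and
    the outcome model (0 = no unmeasured confounding).
    """

    n_persons: int = 20_000
    n_years: int = 11
    start_year: int = 2011
    baseline_dists: BaselineDists = field(default_factory=BaselineDists)
    history_dists: HistoryDists = field(default_factory=HistoryDists)
    treatment_model: TreatmentModel = field(default_factory=TreatmentModel)
    covariate_models: CovariateModels = field(default_factory=CovariateModels)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    censoring_model: CensoringModel = field(default_factory=CensoringModel)
    confounding_dial: float = 0.0
    seed: int | None = None

    @property
    def n_treatment_years(self) -> int:
        return self.n_years - 1

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigError("n_persons", "must be non-negative")
        if self.n_years < 2:
            raise ConfigError("n_years", "must be at least 2")
        p = self.baseline_dists.p_male
        if not (0.0 <= p <= 1.0):
            raise ConfigError("baseline_dists.p_male", "must be in [0, 1]")
        if not (0.0 <= self.baseline_dists.p_danish <= 1.0):
            raise ConfigError("baseline_dists.p_danish", "must be in [0, 1]")
        _check_probs("baseline_dists.education_probs", self.baseline_dists.education_probs)
        _check_probs("baseline_dists.region_probs", self.baseline_dists.region_probs)
        if set(self.baseline_dists.education_probs) != set(EDUCATION_LEVELS):
            raise ConfigError("baseline_dists.education_probs", "unexpected categories")
        if set(self.baseline_dists.region_probs) != set(REGIONS):
            raise ConfigError("baseline_dists.region_probs", "unexpected categories")
        missing = set(HISTORY_SERVICES) - set(self.history_dists.service_propensity)
        if missing:
            raise ConfigError("history_dists.service_propensity", f"missing {sorted(missing)}")
        if not (0.0 <= self.history_dists.latent_loading <= 1.0):
            raise ConfigError("history_dists.latent_loading", "must be in [0, 1]")
        for name in ("treatment_model", "covariate_models", "outcome_model", "censoring_model"):
            _check_finite(name, dataclasses.asdict(getattr(self, name)))
        _check_finite("history_dists", dataclasses.asdict(self.history_dists))
        _check_finite("confounding_dial", self.confounding_dial)
        if self.covariate_models.income_step_sd < 0:
            raise ConfigError("covariate_models.income_step_sd", "must be non-negative")
        missing = set(FOLLOWUP_SERVICES) - set(self.covariate_models.services)
        if missing:
            raise ConfigError("covariate_models.services", f"missing {sorted(missing)}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DGPConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        nested = {
            "baseline_dists": BaselineDists,
            "history_dists": HistoryDists,
            "treatment_model": TreatmentModel,
            "covariate_models": CovariateModels,
            "outcome_model": OutcomeModel,
            "censoring_model": CensoringModel,
        }
        for key, typ in nested.items():
            if key in d:
                sub = d.pop(key)
                fixed = {}
                for f in dataclasses.fields(typ):
                    if f.name in sub:
                        v = sub[f.name]
                        if isinstance(v, dict):
                            v = {
                                k: tuple(x) if isinstance(x, list) else x
                                for k, x in v.items()
                            }
                        fixed[f.name] = v
                kwargs[key] = typ(**fixed)
        kwargs.update(d)
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DGPConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_config(n_persons: int = 20_000, n_years: int = 11, **kwargs) -> DGPConfig:
    """Default calibrated configuration."""
    cfg = DGPConfig(n_persons=n_persons, n_years=n_years, **kwargs)
    cfg.validate()
    return cfg
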