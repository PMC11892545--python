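"""Sequentially doubly robust estimation of counterfactual cumulative incidence.

Implements the longitudinal modified-treatment-policy estimators for a
discrete-time survival outcome with informative censoring:

* density ratios ``g^d_t(A_t | H_t) / g_t(A_t | H_t)`` via the
  classification trick (a classifier on duplicated natural/policy-shifted
  records; the ratio is the odds of the classifier at the natural record),
* censoring adjustment through modelled observation probabilities
  ``P(O_{t+1} = 1 | H_t, A_t)``, folded multiplicatively into the ratios,
* the SDR backward recursion: with ``V_{k+1} = Y_{k+1}``, for t = k..1
  regress ``V_{t+1}`` on ``(H_t, A_t)`` among at-risk observed persons to
  get ``Q_t`` and set ``V_t = Q_t(H_t, A^d_t) + r_t (V_{t+1} - Q_t(H_t,
  A_t))``; persons with an event before t carry ``V_t = 1``,
* sample-splitting (cross-fitting): all nuisances are trained on the fold
  complement, pseudo-outcomes are propagated within training data using the
  training fits, and the held-out scores are pooled for the estimate and
  its influence-function standard error ``sd(V_1)/sqrt(n)``.

G-computation (the recursion without the residual term) and IPW (cumulative
ratio products) are provided as cross-checks; their variances are not.

The history ``H_t`` concatenates the baseline block, all ``L_{s<=t}``, the
post-treatment blocks ``W_{s<t}`` (one-year lag) and past treatment
indicators -- never ``W_t`` or future outcomes.  Income percentiles are
scaled to [0, 1]; categorical baselines are one-of-K encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learners import (
    EnsembleModel,
    LearnerSpec,
    _ConstantModel,
    default_learners,
    fit_superlearner,
    glm_learners,
    saturated_learners,
)
from .panel import PanelDataset
from .policies import PolicySpec, apply_policy

_CENS_FLOOR = 0.01


@dataclass
class LearnerConfig:
    """Which learners and fold counts each nuisance model uses.

    Defaults follow the analysis design: 2-fold CV inside the super learner
    for treatment/ratio and censoring models, 10-fold for the outcome
    regressions.  ``force_unit_ratios`` replaces the treatment-density
    ratios by 1 (the g-computation limit of the SDR recursion);
    ``intercept_only_outcome`` forces the outcome regressions to a constant
    -- both exist to probe double robustness.
    """

    outcome_learners: list[LearnerSpec] = field(default_factory=default_learners)
    treatment_learners: list[LearnerSpec] = field(default_factory=default_learners)
    censoring_learners: list[LearnerSpec] | None = None
    outcome_folds: int = 10
    treatment_folds: int = 2
    censoring_folds: int = 2
    ratio_truncation: float | None = None  # quantile cap on ratios, e.g. 0.999
    positivity_bound: float = 100.0
    force_unit_ratios: bool = False
    intercept_only_outcome: bool = False

    @classmethod
    def default(cls) -> "LearnerConfig":
        return cls()

    @classmethod
    def glm_only(cls, penalty: float = 1.0, **kw) -> "LearnerConfig":
        return cls(
            outcome_learners=glm_learners(penalty),
            treatment_learners=glm_learners(penalty),
            **kw,
        )

    @classmethod
    def saturated(cls, **kw) -> "LearnerConfig":
        return cls(
            outcome_learners=saturated_learners(),
            treatment_learners=saturated_learners(),
            **kw,
        )


# -- design matrices -------------------------------------------------------


class _Design:
    """Feature blocks extracted once from a panel."""

    def __init__(self, panel: PanelDataset):
        df, schema = panel.df, panel.schema
        self.schema = schema
        self.n, self.tau = panel.n, schema.tau
        self.levels = schema.levels
        parts = []
        for col in schema.baseline_categorical:
            d = pd.get_dummies(df[col].astype(str), prefix=col, drop_first=True)
            parts.append(d.to_numpy(dtype=float))
        for col in schema.baseline_numeric:
            x = df[col].to_numpy(dtype=float)
            if "income" in col:
                x = x / 100.0
            parts.append(x[:, None])
        self.base = np.hstack(parts) if parts else np.zeros((self.n, 0))
        self.L = []
        self.W = []
        for year in schema.years:
            lcols = []
            for name in schema.l_names:
                x = df[f"L_{name}_{year}"].to_numpy(dtype=float)
                if name == "income":
                    x = x / 100.0
                lcols.append(x[:, None])
            self.L.append(np.hstack(lcols) if lcols else np.zeros((self.n, 0)))
            wcols = [df[f"W_{name}_{year}"].to_numpy(dtype=float)[:, None] for name in schema.w_names]
            self.W.append(np.hstack(wcols) if wcols else np.zeros((self.n, 0)))
        self.O = panel.obs_matrix()
        Yev = panel.event_matrix()
        self.Ycum = np.fmax.accumulate(np.nan_to_num(Yev, nan=0.0), axis=1)
        self._code = {name: i for i, name in enumerate(schema.levels)}
        self._h_cache: dict[int, np.ndarray] = {}

    def codes(self, strings: np.ndarray) -> np.ndarray:
        out = np.empty(strings.shape, dtype=np.int8)
        flat = strings.ravel()
        res = out.ravel()
        for i, v in enumerate(flat):
            res[i] = self._code[str(v)]
        return out

    def tx_dummies(self, codes_col: np.ndarray) -> np.ndarray:
        k = len(self.levels)
        return np.column_stack([(codes_col == i).astype(float) for i in range(1, k)])

    def history(self, t: int, A_codes: np.ndarray) -> np.ndarray:
        """H_t: baseline, L_1..L_t, X_1..X_{t-1} dummies, W_1..W_{t-1}."""
        if t not in self._h_cache:
            blocks = [self.base] + self.L[:t]
            for s in range(t - 1):
                blocks.append(self.tx_dummies(A_codes[:, s]))
                blocks.append(self.W[s])
            self._h_cache[t] = np.hstack(blocks)
        return self._h_cache[t]

    def at_risk(self, t: int) -> np.ndarray:
        if t == 1:
            return np.ones(self.n, dtype=bool)
        return self.Ycum[:, t - 2] == 0

    def event_by_horizon(self, k: int) -> np.ndarray:
        """Observed event-by-year-(k+1) flag (0 where unknown)."""
        return self.Ycum[:, k - 1].copy()


def _person_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.permutation(np.arange(n) % n_folds)


# -- nuisance estimation ---------------------------------------------------


@dataclass
class RatioEstimates:
    """Cross-fitted density ratios, censoring factors and their product.

    ``r_treat``/``r_full`` are the pooled out-of-fold estimates (n x tau);
    ``per_fold_full[j]`` holds fold-j model predictions on *all* rows, used
    to propagate pseudo-outcomes within training data.
    """

    r_treat: np.ndarray
    r_full: np.ndarray
    cens_prob: np.ndarray
    per_fold_treat: np.ndarray
    per_fold_full: np.ndarray
    assigned: np.ndarray
    fold_ids: np.ndarray
    policy_id: str
    truncation: float | None = None
    notes: list[str] = field(default_factory=list)


def _prepare_ratios(
    design: _Design,
    panel: PanelDataset,
    policy: PolicySpec,
    cfg: LearnerConfig,
    fold_ids: np.ndarray,
    seed: int,
) -> RatioEstimates:
    n, tau = design.n, design.tau
    n_folds = int(fold_ids.max()) + 1 if n else 1
    natural_str = panel.treatment_matrix(codes=False)
    pol_rng = np.random.default_rng(seed + 101)
    assigned_str = apply_policy(natural_str, policy, rng=pol_rng)
    A = design.codes(natural_str)
    Ad = design.codes(assigned_str)
    notes: list[str] = []

    r_pool = np.ones((n, tau))
    r_fold = np.ones((n_folds, n, tau))
    cens_pool = np.ones((n, tau))
    cens_fold = np.ones((n_folds, n, tau))
    cens_learners = cfg.censoring_learners or cfg.treatment_learners

    for t in range(1, tau + 1):
        rows = design.at_risk(t) & design.O[:, t - 1]
        if not rows.any():
            continue
        H = design.history(t, A)
        identical = bool(np.array_equal(A[rows, t - 1], Ad[rows, t - 1]))
        if identical or cfg.force_unit_ratios:
            if identical and policy.id != "identity":
                notes.append(f"t={t}: policy leaves all treatments unchanged; ratios set to 1")
            elif policy.id == "identity" and t == 1:
                notes.append("identity policy: ratios set to 1")
        else:
            # The consecutive-year rules make the shift interactive in the
            # previous *assigned* treatment -- itself a deterministic function
            # of the natural history, hence a legitimate engineered feature of
            # H_t (identical in both stacked copies).  Supplying it, plus its
            # interaction with the candidate treatment, lets even a
            # main-effects GLM represent the true classifier log-odds.
            if t >= 2:
                prev_ad = design.tx_dummies(Ad[:, t - 2])
                prev_nat = design.tx_dummies(A[:, t - 2])
                prev_any_ad = prev_ad.sum(axis=1, keepdims=True)
                prev_any_nat = prev_nat.sum(axis=1, keepdims=True)
                extra = np.hstack([prev_ad, prev_any_ad])
            else:
                extra = np.zeros((design.n, 0))
                prev_any_ad = prev_any_nat = np.zeros((design.n, 1))

            def ratio_features(a_col):
                dum = design.tx_dummies(a_col)
                any_now = dum.sum(axis=1, keepdims=True)
                blocks = [H, extra, dum, any_now * prev_any_ad, any_now * prev_any_nat]
                if extra.shape[1]:
                    blocks.append(dum * prev_any_ad)
                return np.hstack(blocks)

            feat_nat = ratio_features(A[:, t - 1])
            feat_shift = ratio_features(Ad[:, t - 1])
            for j in range(n_folds):
                tr = rows & (fold_ids != j)
                Xstack = np.vstack([feat_nat[tr], feat_shift[tr]])
                lab = np.concatenate([np.zeros(tr.sum()), np.ones(tr.sum())])
                model = fit_superlearner(
                    Xstack, lab, "binary", cfg.treatment_folds, cfg.treatment_learners,
                    seed=seed + 13 * t + j,
                )
                p = model.predict(feat_nat[rows])
                r_fold[j, rows, t - 1] = p / (1.0 - p)
            ev = rows.copy()
            for j in range(n_folds):
                sel = ev & (fold_ids == j)
                r_pool[sel, t - 1] = r_fold[j, sel, t - 1]
        # censoring factors
        if design.schema.has_censoring:
            nxt = design.O[:, t].astype(float)
            if (nxt[rows] < 1).any():
                feat = np.hstack([H, design.tx_dummies(A[:, t - 1])])
                for j in range(n_folds):
                    tr = rows & (fold_ids != j)
                    model = fit_superlearner(
                        feat[tr], nxt[tr], "binary", cfg.censoring_folds, cens_learners,
                        seed=seed + 29 * t + j,
                    )
                    cens_fold[j, rows, t - 1] = np.clip(model.predict(feat[rows]), _CENS_FLOOR, 1.0)
                for j in range(n_folds):
                    sel = rows & (fold_ids == j)
                    cens_pool[sel, t - 1] = cens_fold[j, sel, t - 1]

    if cfg.ratio_truncation is not None:
        for t in range(tau):
            cap = np.quantile(r_pool[:, t], cfg.ratio_truncation)
            r_pool[:, t] = np.minimum(r_pool[:, t], cap)
            r_fold[:, :, t] = np.minimum(r_fold[:, :, t], cap)

    Onext = design.O[:, 1:].astype(float)  # O_{t+1} for t = 1..tau
    full_pool = r_pool * Onext / cens_pool
    full_fold = r_fold * Onext[None] / cens_fold
    return RatioEstimates(
        r_treat=r_pool,
        r_full=full_pool,
        cens_prob=cens_pool,
        per_fold_treat=r_fold,
        per_fold_full=full_fold,
        assigned=Ad,
        fold_ids=fold_ids,
        policy_id=policy.id,
        truncation=cfg.ratio_truncation,
        notes=notes,
    )


def estimate_density_ratios(
    panel: PanelDataset,
    policy: PolicySpec,
    learner_cfg: LearnerConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> RatioEstimates:
    """Cross-fitted density ratios (with censoring factors) for a policy."""
    cfg = learner_cfg or LearnerConfig()
    design = _Design(panel)
    folds = _person_folds(design.n, n_folds, seed)
    return _prepare_ratios(design, panel, policy, cfg, folds, seed)


def fit_censoring_model(
    panel: PanelDataset,
    learner_cfg: LearnerConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Cross-fitted ``P(O_{t+1} = 1 | H_t, A_t, O_t = 1)`` per person-year.

    Probabilities are clipped below at 0.01 so no censoring factor exceeds
    100; a censoring-free panel yields factors exactly 1.
    """
    ratios = estimate_density_ratios(
        panel, PolicySpec("identity"), learner_cfg, n_folds, seed
    )
    return ratios.cens_prob


def positivity_diagnostics(ratios: RatioEstimates) -> pd.DataFrame:
    """Max and 99th percentile of cumulative ratio products per horizon."""
    cum = np.cumprod(ratios.r_treat, axis=1)
    rows = [
        {
            "horizon": t + 1,
            "max_cumulative_ratio": float(cum[:, t].max()) if cum.size else float("nan"),
            "q99_cumulative_ratio": float(np.quantile(cum[:, t], 0.99)) if cum.size else float("nan"),
        }
        for t in range(cum.shape[1])
    ]
    return pd.DataFrame(rows)


# -- estimators ------------------------------------------------------------


@dataclass
class EstimateResult:
    """Counterfactual cumulative incidence at a horizon with EIF inference."""

    psi: float
    se: float | None
    ci95: tuple[float, float] | None
    horizon: int
    policy_id: str
    estimator: str
    scores: np.ndarray | None
    n: int
    n_folds: int
    seed: int
    warnings: list[str] = field(default_factory=list)


def _fit_outcome(cfg: LearnerConfig, X, y, seed) -> EnsembleModel | _ConstantModel:
    if cfg.intercept_only_outcome or len(y) < 2 * cfg.outcome_folds:
        return _ConstantModel(float(np.mean(y)))
    return fit_superlearner(X, y, "continuous", cfg.outcome_folds, cfg.outcome_learners, seed=seed)


def _estimate(panel, policy, horizon, cfg, n_folds, seed, mode, ratios=None) -> EstimateResult:
    design = _Design(panel)
    n, tau = design.n, design.tau
    if not (1 <= horizon <= tau):
        raise ValueError(f"horizon {horizon} outside 1..{tau}")
    if n == 0:
        raise ValueError("empty panel")
    if ratios is None:
        folds = _person_folds(n, n_folds, seed)
        ratios = _prepare_ratios(design, panel, policy, cfg, folds, seed)
    folds = ratios.fold_ids
    n_folds = int(folds.max()) + 1
    A = design.codes(panel.treatment_matrix(codes=False))
    Ad = ratios.assigned
    warnings = list(ratios.notes)
    diag = positivity_diagnostics(ratios)
    max_cum = float(diag["max_cumulative_ratio"].iloc[: horizon].max())
    if max_cum > cfg.positivity_bound:
        warnings.append(
            f"possible practical positivity violation: max cumulative ratio {max_cum:.1f} "
            f"exceeds {cfg.positivity_bound}"
        )

    if mode == "ipw":
        w = np.ones(n)
        for t in range(1, horizon + 1):
            active = design.at_risk(t) & design.O[:, t - 1]
            f = np.ones(n)
            f[active] = ratios.r_full[active, t - 1]
            # persons already censored contribute 0 through an earlier factor
            w = w * f
        yk = design.event_by_horizon(horizon)
        scores = w * yk
        psi = float(np.clip(scores.mean(), 0.0, 1.0))
        return EstimateResult(psi, None, None, horizon, policy.id, "ipw", scores, n, n_folds, seed, warnings)

    V_final = np.zeros((n,))
    filled = np.zeros(n, dtype=bool)
    for j in range(n_folds):
        tr_mask = folds != j
        V = design.event_by_horizon(horizon).astype(float)
        for t in range(horizon, 0, -1):
            atrisk = design.at_risk(t)
            obs_t = design.O[:, t - 1]
            obs_next = design.O[:, t]
            H = design.history(t, A)
            fitrows = tr_mask & atrisk & obs_t & obs_next
            Xfit = np.hstack([H[fitrows], design.tx_dummies(A[fitrows, t - 1])])
            Q = _fit_outcome(cfg, Xfit, V[fitrows], seed + 1000 * j + t)
            pred_rows = atrisk & obs_t
            Xnat = np.hstack([H[pred_rows], design.tx_dummies(A[pred_rows, t - 1])])
            Xd = np.hstack([H[pred_rows], design.tx_dummies(Ad[pred_rows, t - 1])])
            Qnat = Q.predict(Xnat)
            Qd = Q.predict(Xd)
            Vnew = np.where(atrisk, 0.0, 1.0)  # event before t carries V = 1
            if mode == "sdr":
                r = ratios.per_fold_full[j, pred_rows, t - 1]
                Vnew[pred_rows] = Qd + r * (V[pred_rows] - Qnat)
            else:  # gcomp: plug-in predictions are probabilities
                Vnew[pred_rows] = np.clip(Qd, 0.0, 1.0)
            V = Vnew
        ev = folds == j
        V_final[ev] = V[ev]
        filled |= ev
    assert filled.all()
    psi = float(np.clip(V_final.mean(), 0.0, 1.0))
    if mode == "sdr":
        se = float(V_final.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        ci = (psi - 1.96 * se, psi + 1.96 * se)
        return EstimateResult(psi, se, ci, horizon, policy.id, "sdr", V_final, n, n_folds, seed, warnings)
    return EstimateResult(psi, None, None, horizon, policy.id, "gcomp", V_final, n, n_folds, seed, warnings)


def estimate_sdr(
    panel: PanelDataset,
    policy: PolicySpec,
    horizon: int,
    learner_cfg: LearnerConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    ratios: RatioEstimates | None = None,
) -> EstimateResult:
    """Sequentially doubly robust estimate with EIF standard error."""
    return _estimate(panel, policy, horizon, learner_cfg or LearnerConfig(), n_folds, seed, "sdr", ratios)


def estimate_gcomp(
    panel: PanelDataset,
    policy: PolicySpec,
    horizon: int,
    learner_cfg: LearnerConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    ratios: RatioEstimates | None = None,
) -> EstimateResult:
    """Sequential-regression plug-in estimate (no ratio correction, no SE)."""
    return _estimate(panel, policy, horizon, learner_cfg or LearnerConfig(), n_folds, seed, "gcomp", ratios)


def estimate_ipw(
    panel: PanelDataset,
    policy: PolicySpec,
    horizon: int,
    learner_cfg: LearnerConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    ratios: RatioEstimates | None = None,
) -> EstimateResult:
    """Inverse-probability-weighted estimate (cumulative ratio products)."""
    return _estimate(panel, policy, horizon, learner_cfg or LearnerConfig(), n_folds, seed, "ipw", ratios)
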