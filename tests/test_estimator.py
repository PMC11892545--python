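"""Density ratios, censoring adjustment and the three estimators."""

import numpy as np
import pytest

import periopolicy as pp
from periopolicy.estimator import (
    LearnerConfig,
    estimate_density_ratios,
    fit_censoring_model,
    positivity_diagnostics,
)


@pytest.fixture(scope="module")
def tiny_ratio_fixture(tiny_cfg, tiny_panel):
    spec = pp.PolicySpec("scenario1")
    ratios = estimate_density_ratios(tiny_panel, spec, LearnerConfig.saturated(), 5, seed=2)
    return tiny_cfg, tiny_panel, spec, ratios


def test_identity_policy_gives_unit_ratios(tiny_panel):
    ratios = estimate_density_ratios(tiny_panel, pp.PolicySpec("identity"), LearnerConfig.saturated(), 5, seed=2)
    assert np.allclose(ratios.r_treat, 1.0)
    assert any("identity" in n or "unchanged" in n for n in ratios.notes)


def test_ratios_are_non_negative(tiny_ratio_fixture):
    *_, ratios = tiny_ratio_fixture
    assert (ratios.r_treat >= 0).all() and (ratios.r_full >= 0).all()


def test_estimated_ratios_match_analytic_truth(tiny_ratio_fixture):
    """Scenario 1 on the tiny process has closed-form ratios at t = 2:
    0 for treated-after-treated, 1/g(NONE | L2, A1) for the forced gap,
    1 elsewhere."""
    cfg, panel, spec, ratios = tiny_ratio_fixture
    L2 = panel.df["L_conf_2012"].to_numpy()
    A1 = (panel.df["X_2011"] == "SUB").to_numpy().astype(int)
    A2 = (panel.df["X_2012"] == "SUB").to_numpy().astype(int)
    g = np.array([cfg.treat[(l, a)] for l, a in zip(L2, A1)])
    analytic = np.where(A1 == 1, np.where(A2 == 1, 0.0, 1.0 / (1.0 - g)), 1.0)
    atrisk = panel.event_matrix()[:, 0] == 0
    err = np.abs(ratios.r_treat[atrisk, 1] - analytic[atrisk])
    assert err.mean() < 0.05


def test_censoring_free_panel_gives_unit_factors(tiny_panel):
    probs = fit_censoring_model(tiny_panel, LearnerConfig.saturated(), 5, seed=1)
    assert np.allclose(probs, 1.0)


def test_censoring_probabilities_floor_bounds_factors(small_cohort):
    probs = fit_censoring_model(small_cohort, LearnerConfig.glm_only(), 5, seed=1)
    assert probs.min() >= 0.01 - 1e-12  # factor never exceeds 100


def test_censoring_model_calibrated_against_generator_truth():
    """The generator exposes its true censoring hazards; the pooled slope of
    predicted on true observation probabilities should be near 1."""
    cfg = pp.default_config(n_persons=20_000)
    panel, internals = pp.simulate_cohort(cfg, seed=1, return_internals=True)
    probs = fit_censoring_model(panel, LearnerConfig.glm_only(), 5, seed=2)
    obs = internals["obs"]
    ph, pt = [], []
    for t in range(1, panel.tau + 1):
        rows = obs[:, t - 1]
        pt.append(1.0 - internals["true_censoring_hazard"][rows, t - 1])
        ph.append(probs[rows, t - 1])
    ph, pt = np.concatenate(ph), np.concatenate(pt)
    slope = np.cov(ph, pt)[0, 1] / np.var(pt)
    assert 0.8 < slope < 1.2


def test_sdr_identity_matches_empirical_incidence(tiny_panel):
    emp = float(np.nanmax(tiny_panel.event_matrix(), axis=1).mean())
    res = pp.estimate_sdr(tiny_panel, pp.PolicySpec("identity"), 2, LearnerConfig.saturated(), 5, seed=2)
    assert abs(res.psi - emp) < 2 * res.se + 1e-9
    assert res.ci95[0] <= res.psi <= res.ci95[1]


def test_ipw_identity_equals_empirical_incidence_exactly(tiny_panel):
    emp = float(np.nanmax(tiny_panel.event_matrix(), axis=1).mean())
    res = pp.estimate_ipw(tiny_panel, pp.PolicySpec("identity"), 2, LearnerConfig.saturated(), 5, seed=2)
    assert res.psi == pytest.approx(emp, abs=1e-12)


def test_gcomp_estimate_is_a_probability(tiny_panel):
    res = pp.estimate_gcomp(tiny_panel, pp.PolicySpec("scenario1"), 2, LearnerConfig.saturated(), 5, seed=2)
    assert 0.0 <= res.psi <= 1.0 and res.se is None


def test_equal_policies_give_identical_estimates(tiny_panel):
    """Scenario 2 never alters SUB entries, so on a panel without SUPRA it
    coincides with the identity policy."""
    a = pp.estimate_sdr(tiny_panel, pp.PolicySpec("scenario2"), 2, LearnerConfig.saturated(), 5, seed=2)
    b = pp.estimate_sdr(tiny_panel, pp.PolicySpec("identity"), 2, LearnerConfig.saturated(), 5, seed=2)
    assert a.psi == pytest.approx(b.psi, abs=1e-12)


def test_estimator_trio_converges_on_tiny_truth(tiny_cfg, tiny_panel):
    spec = pp.PolicySpec("scenario1")
    vals = [
        fn(tiny_panel, spec, 2, LearnerConfig.saturated(), 5, seed=2).psi
        for fn in (pp.estimate_sdr, pp.estimate_gcomp, pp.estimate_ipw)
    ]
    assert max(vals) - min(vals) <= 0.02


def test_positivity_diagnostics_shape_and_identity(tiny_panel):
    ratios = estimate_density_ratios(tiny_panel, pp.PolicySpec("identity"), LearnerConfig.saturated(), 5, seed=2)
    diag = positivity_diagnostics(ratios)
    assert len(diag) == tiny_panel.tau
    assert diag["max_cumulative_ratio"].max() == pytest.approx(1.0)


def test_positivity_violation_is_flagged():
    """Forcing therapy extension on a cohort that rarely repeats therapy
    produces extreme weights, which are reported, not truncated."""
    cfg = pp.default_config(n_persons=3000, n_years=6)
    cfg.treatment_model.intercept = -2.2
    cfg.treatment_model.prev_any = -1.5  # treated years are rarely repeated
    panel = pp.simulate_cohort(cfg, seed=9)
    lc = LearnerConfig.glm_only(positivity_bound=5.0)
    spec = pp.PolicySpec("scenario3", rng_seed=4, mix_probability=1.0)
    res = pp.estimate_sdr(panel, spec, 5, lc, 5, seed=3)
    assert any("positivity" in w for w in res.warnings)


def test_horizon_out_of_range(tiny_panel):
    with pytest.raises(ValueError, match="horizon"):
        pp.estimate_sdr(tiny_panel, pp.PolicySpec("identity"), 7, LearnerConfig.saturated(), 5, seed=1)
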