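"""Truth oracle: exact enumeration and intervened simulation."""

import itertools

import numpy as np
import pytest

import periopolicy as pp
from periopolicy.tiny import CapacityError, TinyDGPConfig


def brute_force_truth(cfg: TinyDGPConfig, policy_id: str, horizon: int, mix: float = 0.5) -> float:
    """Independent enumeration via itertools over all (L, A_nat, coin) paths;
    written separately from the recursive production code."""
    total = 0.0
    tau = horizon
    for ls in itertools.product((0, 1), repeat=tau):
        for anats in itertools.product((0, 1), repeat=tau):
            for coins in itertools.product((0, 1), repeat=tau):
                prob = 1.0
                surv = 1.0
                asg_prev = 0
                asg_hist = []
                ok = True
                for t in range(tau):
                    l, anat, coin = ls[t], anats[t], coins[t]
                    pl = cfg.p_l1 if t == 0 else cfg.l_trans[(ls[t - 1], asg_hist[-1])]
                    prob *= pl if l == 1 else 1 - pl
                    pa = cfg.treat[(l, asg_hist[-1] if t else 0)]
                    prob *= pa if anat == 1 else 1 - pa
                    if policy_id == "identity" or t == 0:
                        a = anat
                        prob *= 1.0 if coin == 0 else 0.0
                    elif policy_id == "scenario1":
                        a = 0 if (asg_hist[-1] == 1 and anat == 1) else anat
                        prob *= 1.0 if coin == 0 else 0.0
                    elif policy_id == "scenario3":
                        if anats[t - 1] == 1 and anat == 0:
                            a = 1 if coin == 1 else 0
                            prob *= mix if coin == 1 else 1 - mix
                        else:
                            a = anat
                            prob *= 1.0 if coin == 0 else 0.0
                    else:
                        raise ValueError(policy_id)
                    if prob == 0.0:
                        ok = False
                        break
                    asg_hist.append(a)
                    surv *= 1.0 - cfg.hazard[(l, a)]
                if ok:
                    total += prob * (1.0 - surv)
    return total


@pytest.mark.parametrize("policy_id", ["identity", "scenario1", "scenario3"])
@pytest.mark.parametrize("horizon", [1, 2])
def test_enumeration_matches_independent_brute_force(tiny_cfg, policy_id, horizon):
    spec = pp.PolicySpec(policy_id, rng_seed=1)
    got = pp.truth_by_enumeration(tiny_cfg, spec, horizon)
    want = brute_force_truth(tiny_cfg, policy_id, horizon)
    assert got.value == pytest.approx(want, abs=1e-12)
    assert got.mc_se == 0.0


def test_outcome_independent_of_treatment_gives_flat_truth():
    cfg = TinyDGPConfig(tau=1, hazard={(0, 0): 0.3, (0, 1): 0.3, (1, 0): 0.3, (1, 1): 0.3})
    for pid in ("identity", "scenario1", "scenario3"):
        t = pp.truth_by_enumeration(cfg, pp.PolicySpec(pid, rng_seed=1), 1)
        assert t.value == pytest.approx(0.3, abs=1e-12)


def test_identity_enumeration_equals_observed_law(tiny_cfg):
    """Forward computation of the observed-law event probability."""
    dist = {}
    for l in (0, 1):
        pl = tiny_cfg.p_l1 if l == 1 else 1 - tiny_cfg.p_l1
        for a in (0, 1):
            pa = tiny_cfg.treat[(l, 0)]
            dist[(l, a)] = pl * (pa if a == 1 else 1 - pa)
    surv = sum(p * (1 - tiny_cfg.hazard[s]) for s, p in dist.items())
    ev1 = 1 - surv
    got = pp.truth_by_enumeration(tiny_cfg, pp.PolicySpec("identity"), 1)
    assert got.value == pytest.approx(ev1, abs=1e-12)


def test_simulation_agrees_with_enumeration(tiny_cfg):
    for pid in ("identity", "scenario1", "scenario3"):
        spec = pp.PolicySpec(pid, rng_seed=3)
        e = pp.truth_by_enumeration(tiny_cfg, spec, 2)
        s = pp.truth_by_simulation(tiny_cfg, spec, 2, 120_000, seed=5)
        assert abs(e.value - s.value) < 3 * s.mc_se


def test_mc_se_halves_when_n_quadruples(tiny_cfg):
    spec = pp.PolicySpec("identity")
    a = pp.truth_by_simulation(tiny_cfg, spec, 2, 20_000, seed=9)
    b = pp.truth_by_simulation(tiny_cfg, spec, 2, 80_000, seed=9)
    assert a.mc_se / b.mc_se == pytest.approx(2.0, rel=0.2)


def test_horizon_out_of_range_rejected(tiny_cfg):
    with pytest.raises(ValueError, match="horizon"):
        pp.truth_by_enumeration(tiny_cfg, pp.PolicySpec("identity"), 3)
    with pytest.raises(ValueError, match="horizon"):
        pp.truth_by_simulation(tiny_cfg, pp.PolicySpec("identity"), 5, 100, seed=1)


def test_non_enumerable_config_rejected():
    with pytest.raises(CapacityError):
        TinyDGPConfig(tau=4).validate()


def test_protective_effect_orders_policies():
    """With a protective therapy, more care means lower incidence:
    scenario3 <= identity <= scenario1."""
    cfg = pp.default_config(n_persons=150_000)
    cfg.outcome_model.theta_treat = -0.35
    vals = {}
    for pid in ("scenario1", "identity", "scenario3"):
        spec = pp.PolicySpec(pid, rng_seed=11)
        vals[pid] = pp.truth_by_simulation(cfg, spec, 10, 150_000, seed=13)
    gap1 = vals["scenario1"].value - vals["identity"].value
    gap2 = vals["identity"].value - vals["scenario3"].value
    se = max(v.mc_se for v in vals.values())
    assert gap1 > 3 * se and gap2 > 3 * se
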