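"""Tiny discrete data-generating processes with exact, enumerable truth.

A validation scaffold: a short (tau <= 3) process with a binary treatment
(coded NONE/SUB), one binary time-varying confounder, no censoring, and
explicit conditional probability tables.  Small enough that counterfactual
cumulative incidence under any policy can be computed exactly by summing
trajectory probabilities under the intervened law, which makes it an
independent oracle for the estimators.

Structure per year t: ``L_t | L_{t-1}, A_{t-1}`` -> ``A_t | L_t, A_{t-1}``
-> event hazard ``P(Y_{t+1}=1 | Y_t=0, L_t, A_t)``.  Under a policy the
natural treatment is drawn from the treatment table given the *assigned*
past, then shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelDataset, PanelSchema
from .policies import PolicySpec

_MAX_PATHS = 1_000_000


class CapacityError(ValueError):
    pass


@dataclass
class TinyDGPConfig:
    """CPT-specified process.  Keys: ``l_trans[(l_prev, a_prev)]``,
    ``treat[(l, a_prev)]`` (``a_prev = 0`` in year 1), ``hazard[(l, a)]``."""

    tau: int = 2
    p_l1: float = 0.5
    l_trans: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(0, 0): 0.3, (0, 1): 0.5, (1, 0): 0.6, (1, 1): 0.8}
    )
    treat: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(0, 0): 0.3, (0, 1): 0.6, (1, 0): 0.5, (1, 1): 0.8}
    )
    hazard: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(0, 0): 0.15, (0, 1): 0.08, (1, 0): 0.25, (1, 1): 0.12}
    )

    def validate(self) -> None:
        if not (1 <= self.tau <= 3):
            raise CapacityError(f"tau={self.tau} outside the enumerable range 1..3")
        for name, table in (("l_trans", self.l_trans), ("treat", self.treat), ("hazard", self.hazard)):
            for k, v in table.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name}[{k}] = {v} not a probability")
        if not (0.0 <= self.p_l1 <= 1.0):
            raise ValueError("p_l1 not a probability")
        if 8**self.tau > _MAX_PATHS:
            raise CapacityError("state space too large to enumerate")


#: Binary coding in panels: 0 -> NONE, 1 -> SUB (any periodontal therapy).
TINY_LEVELS = ("NONE", "SUB")
_TINY_CODE = {0: "NONE", 1: "SUB"}


def tiny_schema(tau: int, start_year: int = 2011) -> PanelSchema:
    return PanelSchema(
        start_year=start_year,
        n_treatment_years=tau,
        l_names=("conf",),
        levels=TINY_LEVELS,
        has_censoring=False,
    )


def _assigned_branches(spec: PolicySpec, t: int, a_nat: int, nat_prev: int | None, asg_prev: int | None):
    """Scalar policy application in binary coding; yields (assigned, prob)."""
    if t == 1 or spec.id == "identity":
        return [(a_nat, 1.0)]
    if spec.id == "scenario1":
        prev = asg_prev if spec.history_semantics == "assigned" else nat_prev
        if prev == 1 and a_nat == 1:
            return [(0, 1.0)]
        return [(a_nat, 1.0)]
    if spec.id == "scenario2":
        # the rule restricts supragingival-only care; binary SUB is never altered
        return [(a_nat, 1.0)]
    if spec.id == "scenario3":
        if nat_prev == 1 and a_nat == 0:
            p = spec.mix_probability
            out = []
            if p > 0:
                out.append((1, p))
            if p < 1:
                out.append((0, 1.0 - p))
            return out
        return [(a_nat, 1.0)]
    raise ValueError(f"unknown policy {spec.id!r}")


def enumerate_truth(config: TinyDGPConfig, spec: PolicySpec, horizon: int) -> float:
    """Exact counterfactual P(event by year ``horizon + 1``) under the policy."""
    config.validate()
    if not (1 <= horizon <= config.tau):
        raise ValueError(f"horizon {horizon} outside 1..{config.tau}")
    total = 0.0

    def rec(t: int, prob: float, l_prev, nat_prev, asg_prev, surv: float) -> None:
        nonlocal total
        if t > horizon:
            total += prob * (1.0 - surv)
            return
        for l in (0, 1):
            pl1 = config.p_l1 if t == 1 else config.l_trans[(l_prev, asg_prev)]
            p_l = pl1 if l == 1 else 1.0 - pl1
            if p_l == 0.0:
                continue
            pa1 = config.treat[(l, asg_prev if t > 1 else 0)]
            for a_nat in (0, 1):
                p_a = pa1 if a_nat == 1 else 1.0 - pa1
                if p_a == 0.0:
                    continue
                for a_asg, p_pol in _assigned_branches(spec, t, a_nat, nat_prev, asg_prev):
                    h = config.hazard[(l, a_asg)]
                    rec(t + 1, prob * p_l * p_a * p_pol, l, a_nat, a_asg, surv * (1.0 - h))

    rec(1, 1.0, None, None, 0, 1.0)
    return total


def simulate_tiny(
    config: TinyDGPConfig,
    n: int,
    seed: int,
    policy: PolicySpec | None = None,
) -> PanelDataset:
    """Sample the tiny process (optionally policy-intervened) as a panel."""
    config.validate()
    rng = np.random.default_rng(seed)
    tau = config.tau
    L = np.zeros((n, tau), dtype=np.int8)
    A_nat = np.zeros((n, tau), dtype=np.int8)
    A = np.zeros((n, tau), dtype=np.int8)
    ever = np.zeros(n, dtype=bool)
    event_by = np.zeros((n, tau), dtype=np.int8)
    for t in range(tau):
        if t == 0:
            L[:, t] = (rng.random(n) < config.p_l1).astype(np.int8)
        else:
            p = np.array([config.l_trans[(l, a)] for l, a in zip(L[:, t - 1], A[:, t - 1])])
            L[:, t] = (rng.random(n) < p).astype(np.int8)
        a_prev = A[:, t - 1] if t else np.zeros(n, dtype=np.int8)
        p = np.array([config.treat[(l, a)] for l, a in zip(L[:, t], a_prev)]) if n else np.zeros(0)
        A_nat[:, t] = (rng.random(n) < p).astype(np.int8)
        if policy is None or policy.id == "identity" or t == 0:
            A[:, t] = A_nat[:, t]
        elif policy.id in ("scenario1", "scenario2"):
            prev = A[:, t - 1] if policy.history_semantics == "assigned" else A_nat[:, t - 1]
            # binary coding is NONE/SUB; scenario 2 never alters SUB years
            block = (prev == 1) & (A_nat[:, t] == 1) if policy.id == "scenario1" else np.zeros(n, bool)
            A[:, t] = np.where(block, 0, A_nat[:, t])
        elif policy.id == "scenario3":
            eligible = (A_nat[:, t - 1] == 1) & (A_nat[:, t] == 0)
            take = eligible & (rng.random(n) < policy.mix_probability)
            A[:, t] = np.where(take, 1, A_nat[:, t])
        else:
            raise ValueError(f"unknown policy {policy.id!r}")
        h = np.array([config.hazard[(l, a)] for l, a in zip(L[:, t], A[:, t])]) if n else np.zeros(0)
        new = (~ever) & (rng.random(n) < h)
        ever = ever | new
        event_by[:, t] = ever.astype(np.int8)

    schema = tiny_schema(tau)
    data: dict[str, object] = {"id": np.arange(n)}
    for j, year in enumerate(schema.years):
        data[f"L_conf_{year}"] = L[:, j]
        data[f"X_{year}"] = np.array([_TINY_CODE[a] for a in A[:, j]], dtype=object)
    for k in range(tau + 1):
        data[f"O_{schema.start_year + k}"] = np.ones(n, dtype=np.int8)
    for j in range(tau):
        data[f"Y_{schema.start_year + 1 + j}"] = event_by[:, j].astype(float)
    return PanelDataset(pd.DataFrame(data), schema)
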