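"""Risk differences and risk ratios between policy estimates.

Both estimates must come from the same panel and fold scheme so the
per-person influence scores are paired; the contrast variance then uses the
score differences (narrower and correct under joint estimation) rather
than adding independent variances.  The risk-ratio CI uses the delta
method on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimator import EstimateResult


class ContrastError(ValueError):
    pass


@dataclass
class ContrastResult:
    policy_a: str
    policy_b: str
    horizon: int
    rd: float
    rd_se: float
    rd_ci95: tuple[float, float]
    rr: float
    rr_se_log: float
    rr_ci95: tuple[float, float]


def contrast(a: EstimateResult, b: EstimateResult) -> ContrastResult:
    """Risk difference ``psi_a - psi_b`` and ratio ``psi_a / psi_b``."""
    if a.horizon != b.horizon:
        raise ContrastError(f"mismatched horizons: {a.horizon} vs {b.horizon}")
    if a.scores is None or b.scores is None or a.n != b.n:
        raise ContrastError("paired per-person scores are required for contrasts")
    n = a.n
    if a is b or (a.policy_id == b.policy_id and np.array_equal(a.scores, b.scores)):
        return ContrastResult(a.policy_id, b.policy_id, a.horizon, 0.0, 0.0, (0.0, 0.0), 1.0, 0.0, (1.0, 1.0))
    diff = a.scores - b.scores
    rd = float(a.psi - b.psi)
    rd_se = float(diff.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    rd_ci = (rd - 1.96 * rd_se, rd + 1.96 * rd_se)
    if b.psi <= 0:
        raise ContrastError("risk ratio undefined: reference incidence is zero")
    rr = float(a.psi / b.psi)
    infl = a.scores / max(a.psi, 1e-12) - b.scores / b.psi
    rr_se = float(infl.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    rr_ci = (rr * np.exp(-1.96 * rr_se), rr * np.exp(1.96 * rr_se))
    return ContrastResult(a.policy_id, b.policy_id, a.horizon, rd, rd_se, rd_ci, rr, rr_se, rr_ci)
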