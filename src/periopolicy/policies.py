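"""Modified treatment policies over a yearly periodontal-therapy exposure.

The exposure has three levels per calendar year: ``NONE`` (no periodontal
treatment), ``SUPRA`` (only supragingival treatment) and ``SUB`` (subgingival
or surgical periodontal treatment).  A policy is a shift function mapping the
naturally occurring treatment and the person's history to an assigned
treatment, processed year by year:

* ``scenario1`` -- no periodontal care of any kind in two consecutive years:
  a treated year following a treated year is set to ``NONE``.
* ``scenario2`` -- no supragingival-only care in two consecutive years;
  subgingival/surgical care is never altered.
* ``scenario3`` -- increased care: a year with no therapy that follows a
  treated year is replaced, with probability ``mix_probability`` (default
  0.5), by the previous year's therapy.

Scenarios 1-2 consult the *assigned* (post-policy) previous year by default,
so alternating-year care remains possible under the restriction; scenario 3
consults the natural history.  The first year has no predecessor and is
always kept as observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

NONE, SUPRA, SUB = 0, 1, 2
LEVEL_NAMES = ("NONE", "SUPRA", "SUB")
_NAME_TO_CODE = {n: i for i, n in enumerate(LEVEL_NAMES)}

POLICY_IDS = ("identity", "scenario1", "scenario2", "scenario3")


class PolicyError(ValueError):
    pass


def encode_levels(matrix) -> np.ndarray:
    """String or integer treatment matrix -> integer codes, validated."""
    arr = np.asarray(matrix)
    if arr.dtype.kind in "UOS":
        flat = arr.ravel()
        out = np.empty(flat.shape, dtype=np.int8)
        for i, v in enumerate(flat):
            try:
                out[i] = _NAME_TO_CODE[str(v)]
            except KeyError:
                raise PolicyError(f"unknown treatment level {v!r}") from None
        return out.reshape(arr.shape)
    arr = arr.astype(np.int8, copy=True)
    if arr.size and (arr.min() < 0 or arr.max() > 2):
        bad = arr[(arr < 0) | (arr > 2)][0]
        raise PolicyError(f"unknown treatment level {int(bad)!r}")
    return arr


def decode_levels(matrix: np.ndarray) -> np.ndarray:
    return np.asarray(LEVEL_NAMES, dtype=object)[np.asarray(matrix, dtype=int)]


@dataclass(frozen=True)
class PolicySpec:
    """A named policy with its history semantics and randomisation contract.

    ``history_semantics`` selects whether the consecutive-year rules consult
    the assigned (post-policy) or the natural previous-year value; scenario 3
    is defined on the natural history.  ``rng_seed`` is required for
    scenario 3 unless an explicit generator is passed to :func:`apply_policy`.
    """

    id: str = "identity"
    history_semantics: str = "assigned"
    rng_seed: int | None = None
    mix_probability: float = 0.5

    def __post_init__(self):
        if self.id not in POLICY_IDS:
            raise PolicyError(f"unknown policy id {self.id!r}")
        if self.history_semantics not in ("assigned", "natural"):
            raise PolicyError(f"unknown history_semantics {self.history_semantics!r}")
        if not (0.0 <= self.mix_probability <= 1.0):
            raise PolicyError("mix_probability must be in [0, 1]")

    @property
    def is_stochastic(self) -> bool:
        return self.id == "scenario3" and 0.0 < self.mix_probability

    def require_rng(self, rng) -> np.random.Generator | None:
        if self.id != "scenario3":
            return None
        if rng is not None:
            return rng
        if self.rng_seed is None:
            raise PolicyError("scenario3 requires an rng or rng_seed")
        return np.random.default_rng(self.rng_seed)


def policy_step(
    spec: PolicySpec,
    natural_t: np.ndarray,
    prev_assigned: np.ndarray | None,
    prev_natural: np.ndarray | None,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Assigned treatment for one year given the natural draw and histories.

    ``prev_assigned``/``prev_natural`` are ``None`` in the first year.  Used
    both by :func:`apply_policy` and by the policy-intervened simulator, where
    the "natural" value is the treatment-model draw under the intervened past.
    """
    nat = np.asarray(natural_t)
    out = nat.copy()
    if prev_assigned is None:
        return out
    if spec.id == "identity":
        return out
    prev = prev_assigned if spec.history_semantics == "assigned" else prev_natural
    if spec.id == "scenario1":
        block = (prev != NONE) & (nat != NONE)
        out[block] = NONE
    elif spec.id == "scenario2":
        block = (prev == SUPRA) & (nat == SUPRA)
        out[block] = NONE
    elif spec.id == "scenario3":
        eligible = (np.asarray(prev_natural) != NONE) & (nat == NONE)
        if eligible.any() and spec.mix_probability > 0:
            if rng is None:
                raise PolicyError("scenario3 requires an rng or rng_seed")
            take = eligible & (rng.random(nat.shape) < spec.mix_probability)
            out[take] = np.asarray(prev_natural)[take]
    return out


def apply_policy(observed, spec: PolicySpec, rng=None) -> np.ndarray:
    """Apply a policy to an observed n x tau treatment matrix.

    Years are processed left to right; for scenario 3 each eligible
    person-year is randomised independently.  Returns the assigned matrix in
    the same coding (strings in -> strings out).
    """
    strings = np.asarray(observed).dtype.kind in "UOS"
    obs = encode_levels(observed)
    if obs.ndim != 2:
        raise PolicyError("treatment matrix must be 2-dimensional (n x tau)")
    gen = spec.require_rng(rng)
    n, tau = obs.shape
    assigned = np.empty_like(obs)
    prev_a = prev_n = None
    for t in range(tau):
        assigned[:, t] = policy_step(spec, obs[:, t], prev_a, prev_n, gen)
        prev_a, prev_n = assigned[:, t], obs[:, t]
    return decode_levels(assigned) if strings else assigned


def person_years_with_therapy(matrix) -> tuple[np.ndarray, float, float]:
    """Per-person count of years with any therapy (SUPRA or SUB), plus the
    cohort mean and population SD of the counts."""
    codes = encode_levels(matrix)
    counts = (codes != NONE).sum(axis=1)
    if counts.size == 0:
        return counts, 0.0, 0.0
    return counts, float(counts.mean()), float(counts.std(ddof=0))
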