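"""Mechanics of the counterfactual treatment policies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periopolicy.policies import (
    NONE,
    SUB,
    SUPRA,
    PolicyError,
    PolicySpec,
    apply_policy,
    person_years_with_therapy,
)


def _mat(*rows):
    return np.array(rows, dtype=np.int8)


treatment_matrices = st.integers(1, 40).flatmap(
    lambda n: st.integers(2, 10).flatmap(
        lambda tau: st.lists(
            st.lists(st.integers(0, 2), min_size=tau, max_size=tau),
            min_size=n,
            max_size=n,
        ).map(lambda rows: np.array(rows, dtype=np.int8))
    )
)


class TestHandExamples:
    def test_scenario1_breaks_consecutive_care(self):
        out = apply_policy(_mat([SUB, SUB, NONE, SUPRA]), PolicySpec("scenario1"))
        assert out.tolist() == [[SUB, NONE, NONE, SUPRA]]

    def test_all_none_unchanged_under_every_policy(self):
        m = _mat([NONE] * 6, [NONE] * 6)
        for pid in ("identity", "scenario1", "scenario2", "scenario3"):
            out = apply_policy(m, PolicySpec(pid, rng_seed=1))
            assert np.array_equal(out, m)

    def test_scenario2_never_alters_subgingival_years(self, rng):
        m = rng.integers(0, 3, size=(200, 10)).astype(np.int8)
        out = apply_policy(m, PolicySpec("scenario2"))
        assert np.array_equal(out == SUB, m == SUB)

    def test_scenario3_degenerate_mix_extends_therapy(self):
        spec = PolicySpec("scenario3", rng_seed=3, mix_probability=1.0)
        out = apply_policy(_mat([SUPRA, NONE, NONE]), spec)
        # the third year's predecessor is the observed NONE, so only year 2 flips
        assert out.tolist() == [[SUPRA, SUPRA, NONE]]

    def test_string_round_trip(self):
        m = np.array([["SUB", "SUB", "NONE"]], dtype=object)
        out = apply_policy(m, PolicySpec("scenario1"))
        assert out.tolist() == [["SUB", "NONE", "NONE"]]

    def test_unknown_level_rejected(self):
        with pytest.raises(PolicyError, match="unknown treatment level"):
            apply_policy(np.array([["SUB", "WHAT"]], dtype=object), PolicySpec("identity"))

    def test_scenario3_requires_rng(self):
        m = _mat([SUB, NONE])
        with pytest.raises(PolicyError, match="requires an rng"):
            apply_policy(m, PolicySpec("scenario3"))


class TestInvariants:
    @settings(max_examples=60, deadline=None)
    @given(treatment_matrices)
    def test_scenario1_has_no_consecutive_treated_years(self, m):
        out = apply_policy(m, PolicySpec("scenario1"))
        treated = out != NONE
        assert not (treated[:, 1:] & treated[:, :-1]).any()

    @settings(max_examples=60, deadline=None)
    @given(treatment_matrices)
    def test_scenario2_has_no_consecutive_supra_and_preserves_sub(self, m):
        out = apply_policy(m, PolicySpec("scenario2"))
        supra = out == SUPRA
        assert not (supra[:, 1:] & supra[:, :-1]).any()
        assert np.array_equal(out == SUB, m == SUB)

    @settings(max_examples=60, deadline=None)
    @given(treatment_matrices)
    def test_treated_years_ordering_across_policies(self, m):
        _, obs_mean, _ = person_years_with_therapy(m)
        s1 = person_years_with_therapy(apply_policy(m, PolicySpec("scenario1")))[0]
        s2 = person_years_with_therapy(apply_policy(m, PolicySpec("scenario2")))[0]
        s3 = person_years_with_therapy(apply_policy(m, PolicySpec("scenario3", rng_seed=5)))[0]
        obs = person_years_with_therapy(m)[0]
        assert (s1 <= obs).all() and (s3 >= obs).all()
        assert s1.mean() <= s2.mean() + 1e-12 <= obs.mean() + 1e-12 <= s3.mean() + 1e-12

    @settings(max_examples=40, deadline=None)
    @given(treatment_matrices)
    def test_deterministic_policies_are_idempotent(self, m):
        for pid in ("scenario1", "scenario2"):
            once = apply_policy(m, PolicySpec(pid))
            twice = apply_policy(once, PolicySpec(pid))
            assert np.array_equal(once, twice)

    def test_scenario3_zero_mix_is_identity(self, rng):
        m = rng.integers(0, 3, size=(300, 10)).astype(np.int8)
        out = apply_policy(m, PolicySpec("scenario3", rng_seed=2, mix_probability=0.0))
        assert np.array_equal(out, m)

    def test_scenario3_alters_eligible_positions_at_mix_rate(self, rng):
        m = rng.integers(0, 3, size=(4000, 10)).astype(np.int8)
        eligible = (m[:, :-1] != NONE) & (m[:, 1:] == NONE)
        out = apply_policy(m, PolicySpec("scenario3", rng_seed=9, mix_probability=0.5))
        altered = (out[:, 1:] != m[:, 1:]) & eligible
        frac = altered.sum() / eligible.sum()
        n = eligible.sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


class TestPersonYears:
    def test_all_none(self):
        counts, mean, sd = person_years_with_therapy(np.zeros((5, 10), dtype=np.int8))
        assert mean == 0.0 and sd == 0.0 and counts.tolist() == [0] * 5

    def test_two_person_hand_case_population_sd(self):
        m = _mat([SUB] * 10, [NONE] * 10)
        _, mean, sd = person_years_with_therapy(m)
        assert mean == 5.0 and sd == 5.0

    def test_empty(self):
        counts, mean, sd = person_years_with_therapy(np.zeros((0, 10), dtype=np.int8))
        assert counts.size == 0 and mean == 0.0 and sd == 0.0
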