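"""Normalization rules, delta-rule updates and decision rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import normbandit as nb
from normbandit.value_models import RAW_FALLBACK_OUTCOME


def _state_for(design, model):
    return nb.ValueState.initialize(design, model)


class TestSubjectiveOutcomes:
    def test_unbiased_is_identity(self):
        out = nb.subjective_outcomes(nb.ModelSpec("UNBIASED"), (14.0, 86.0), 0)
        assert out.tolist() == [14.0, 86.0]

    def test_range_endpoints_and_midpoint(self):
        out = nb.subjective_outcomes(nb.ModelSpec("RANGE"), (14.0, 50.0, 86.0), 0)
        assert out.tolist() == [0.0, 0.5, 1.0]

    def test_divisive_hand_arithmetic(self):
        out = nb.subjective_outcomes(nb.ModelSpec("DIVISIVE"), (14.0, 86.0), 0)
        assert out.tolist() == [0.14, 0.86]

    def test_range_w_power_transform(self):
        params = nb.AgentParameters(0.5, 0.5, 1.0, omega=3.0)
        out = nb.subjective_outcomes(
            nb.ModelSpec("RANGE_W"), (14.0, 50.0, 86.0), 0, params
        )
        assert out[1] == pytest.approx(0.125)  # 0.5 ** 3

    def test_range_wplus_splits_chosen_and_forgone(self):
        params = nb.AgentParameters(0.5, 0.5, 1.0, omega_c=2.0, omega_u=3.0)
        out = nb.subjective_outcomes(
            nb.ModelSpec("RANGE_WPLUS"), (14.0, 50.0, 86.0), 1, params
        )
        assert out.tolist() == [0.0, 0.25, 1.0]

    def test_degenerate_range_maps_to_half(self):
        out = nb.subjective_outcomes(nb.ModelSpec("RANGE"), (50.0, 50.0), 0)
        assert out.tolist() == [0.5, 0.5]

    def test_divisive_zero_sum_errors(self):
        with pytest.raises(ValueError, match="sum"):
            nb.subjective_outcomes(nb.ModelSpec("DIVISIVE"), (0.0, 0.0), 0)

    def test_missing_omega_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            nb.subjective_outcomes(
                nb.ModelSpec("RANGE_W"), (1.0, 2.0), 0, nb.AgentParameters(0.5, 0.5, 1.0)
            )

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_oracle_against_direct_formulas(self, data):
        """All five rules agree with direct elementwise evaluation of their
        defining formulas on randomized trials, to 1e-12 relative tolerance."""
        n = data.draw(st.integers(2, 3))
        raw = np.array(
            data.draw(
                st.lists(
                    st.floats(0.0, 100.0), min_size=n, max_size=n, unique=True
                )
            )
        )
        chosen = data.draw(st.integers(0, n - 1))
        omega_c = data.draw(st.floats(0.05, 20.0))
        omega_u = data.draw(st.floats(0.05, 20.0))
        params = nb.AgentParameters(
            0.5, 0.5, 1.0, omega=omega_c, omega_c=omega_c, omega_u=omega_u
        )
        lo, hi, tot = raw.min(), raw.max(), raw.sum()
        expected = {
            "UNBIASED": raw,
            "DIVISIVE": raw / tot if tot > 0 else None,
            "RANGE": (raw - lo) / (hi - lo),
            "RANGE_W": ((raw - lo) / (hi - lo)) ** omega_c,
            "RANGE_WPLUS": np.array(
                [
                    ((r - lo) / (hi - lo)) ** (omega_c if i == chosen else omega_u)
                    for i, r in enumerate(raw)
                ]
            ),
        }
        for mid, exp in expected.items():
            if exp is None:
                continue
            got = nb.subjective_outcomes(nb.ModelSpec(mid), raw, chosen, params)
            np.testing.assert_allclose(got, exp, rtol=1e-12, atol=1e-15)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_divisive_sums_to_one_and_range_in_unit_interval(self, data):
        n = data.draw(st.integers(2, 3))
        raw = np.array(
            data.draw(
                st.lists(st.floats(1.0, 100.0), min_size=n, max_size=n, unique=True)
            )
        )
        div = nb.subjective_outcomes(nb.ModelSpec("DIVISIVE"), raw, 0)
        assert div.sum() == pytest.approx(1.0, abs=1e-12)
        rng_ = nb.subjective_outcomes(nb.ModelSpec("RANGE"), raw, 0)
        assert rng_[np.argmin(raw)] == 0.0 and rng_[np.argmax(raw)] == 1.0
        assert np.all((rng_ >= 0.0) & (rng_ <= 1.0))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_unit_omega_reduces_to_plain_range(self, data):
        n = data.draw(st.integers(2, 3))
        raw = data.draw(
            st.lists(st.floats(0.0, 100.0), min_size=n, max_size=n, unique=True)
        )
        chosen = data.draw(st.integers(0, n - 1))
        params = nb.AgentParameters(0.5, 0.5, 1.0, omega=1.0, omega_c=1.0, omega_u=1.0)
        base = nb.subjective_outcomes(nb.ModelSpec("RANGE"), raw, chosen)
        for mid in ("RANGE_W", "RANGE_WPLUS"):
            got = nb.subjective_outcomes(nb.ModelSpec(mid), raw, chosen, params)
            assert got.tolist() == base.tolist()  # bit-for-bit


class TestFeedbackResolution:
    def test_complete_feedback_identity(self, design_1a, range_model):
        state = _state_for(design_1a, range_model)
        out = nb.resolve_feedback(
            state, (14.0, 50.0), (True, True), ("NB14", "NB50")
        )
        assert out.tolist() == [14.0, 50.0]
        assert state.last_seen == {"NB14": 14.0, "NB50": 50.0}

    def test_unobserved_filled_with_last_seen(self, design_1a, range_model):
        state = _state_for(design_1a, range_model)
        state.last_seen["NB50"] = 49.0
        out = nb.resolve_feedback(
            state, (16.0, np.nan), (True, False), ("NB14", "NB50")
        )
        assert out.tolist() == [16.0, 49.0]
        assert state.last_seen["NB50"] == 49.0  # unchanged: not observed

    def test_never_observed_falls_back_to_raw_50(self, design_1a):
        state = _state_for(design_1a, nb.ModelSpec("UNBIASED"))
        out = nb.resolve_feedback(
            state, (np.nan, 52.0), (False, True), ("NB14", "NB50")
        )
        assert out.tolist() == [RAW_FALLBACK_OUTCOME, 52.0]


class TestValueUpdates:
    def test_full_step_reaches_subjective_outcome(self, design_1a, range_model):
        state = _state_for(design_1a, range_model)
        params = nb.AgentParameters(1.0, 0.0, 1.0)
        nb.update_values(state, "NB", ("NB14", "NB50"), (0.0, 1.0), 1, params)
        assert state.q[("NB", "NB50")] == 1.0
        assert state.q[("NB", "NB14")] == 0.5  # alpha_u = 0

    def test_zero_learning_rates_leave_state_unchanged(self, design_1a, range_model):
        state = _state_for(design_1a, range_model)
        before = dict(state.q)
        params = nb.AgentParameters(0.0, 0.0, 1.0)
        nb.update_values(state, "NB", ("NB14", "NB50"), (0.0, 1.0), 1, params)
        assert state.q == before

    def test_one_step_hand_computation(self, design_1a, range_model):
        state = _state_for(design_1a, range_model)
        params = nb.AgentParameters(alpha_c=0.5, alpha_u=0.2, beta=1.0)
        nb.update_values(state, "NB", ("NB14", "NB50"), (0.0, 1.0), 1, params)
        assert state.q[("NB", "NB14")] == pytest.approx(0.4)
        assert state.q[("NB", "NB50")] == pytest.approx(0.75)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_update_matches_delta_rule_oracle(self, data, design_1a, range_model):
        """One-step equivalence with the written-out delta rule
        q + alpha * (u - q) on randomized states and outcomes."""
        n = data.draw(st.integers(2, 3))
        ctx = "NT"
        opts = ("NT14", "NT32", "NT50")[:n]
        q0 = data.draw(st.lists(st.floats(0, 1), min_size=n, max_size=n))
        u = data.draw(st.lists(st.floats(0, 1), min_size=n, max_size=n))
        chosen = data.draw(st.integers(0, n - 1))
        a_c = data.draw(st.floats(0, 1))
        a_u = data.draw(st.floats(0, 1))
        state = _state_for(design_1a, range_model)
        for o, v in zip(opts, q0):
            state.q[(ctx, o)] = v
        nb.update_values(
            state, ctx, opts, u, chosen, nb.AgentParameters(a_c, a_u, 1.0)
        )
        for i, o in enumerate(opts):
            alpha = a_c if i == chosen else a_u
            assert state.q[(ctx, o)] == pytest.approx(
                q0[i] + alpha * (u[i] - q0[i]), abs=1e-12
            )

    def test_convergence_to_mean_subjective_outcome(self, design_1a, range_model):
        """With complete feedback and noiseless outcomes, Q approaches the
        subjective outcome geometrically over 45 repetitions."""
        state = _state_for(design_1a, range_model)
        params = nb.AgentParameters(0.2, 0.15, 1.0)
        for _ in range(45):
            nb.update_values(
                state, "WT", ("WT14", "WT50", "WT86"), (0.0, 0.5, 1.0), 2, params
            )
        assert abs(state.q[("WT", "WT86")] - 1.0) < 0.01
        assert abs(state.q[("WT", "WT50")] - 0.5) < 0.01
        assert abs(state.q[("WT", "WT14")] - 0.0) < 0.01


class TestDecisionRules:
    def test_zero_beta_uniform(self):
        probs = nb.softmax_probabilities((0.1, 0.9, 0.4), 0.0)
        assert probs.tolist() == pytest.approx([1 / 3] * 3)

    def test_direct_formula_value(self):
        probs = nb.softmax_probabilities((0.2, 0.8), 10.0)
        expected = 1.0 / (1.0 + np.exp(-6.0))
        assert probs[1] == pytest.approx(expected, abs=1e-12)
        assert probs[1] == pytest.approx(0.9975, abs=1e-4)

    def test_unavailable_options_get_zero(self):
        probs = nb.softmax_probabilities((0.2, 0.8, 0.5), 2.0, (True, False, True))
        assert probs[1] == 0.0
        assert probs.sum() == pytest.approx(1.0)

    def test_numerically_stable_for_huge_beta(self):
        probs = nb.softmax_probabilities((10.0, 90.0), 1e6)
        assert probs.tolist() == [0.0, 1.0]

    def test_empty_availability_errors(self):
        with pytest.raises(ValueError, match="available"):
            nb.softmax_probabilities((0.1, 0.2), 1.0, (False, False))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        q=st.lists(st.floats(-10, 10), min_size=2, max_size=3),
        beta1=st.floats(0, 50),
        beta2=st.floats(0, 50),
    )
    def test_simplex_and_beta_monotonicity(self, q, beta1, beta2):
        lo, hi = sorted((beta1, beta2))
        p_lo = nb.softmax_probabilities(q, lo)
        p_hi = nb.softmax_probabilities(q, hi)
        for p in (p_lo, p_hi):
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p >= 0)
        best = int(np.argmax(q))
        assert p_hi[best] >= p_lo[best] - 1e-9

    @pytest.mark.parametrize(
        "qa,qb,expected", [(0.9, 0.1, 1.0), (0.5, 0.5, 0.5), (0.1, 0.9, 0.0)]
    )
    def test_argmax_rule(self, qa, qb, expected):
        assert nb.argmax_choice_probability(qa, qb) == expected


def test_model_spec_q_init_and_validation():
    assert nb.ModelSpec("UNBIASED").q_init == 50.0
    assert nb.ModelSpec("RANGE").q_init == 0.5
    with pytest.raises(ValueError, match="UNBIASED.*RANGE_WPLUS"):
        nb.ModelSpec("RANG")


def test_parameter_validation():
    with pytest.raises(ValueError, match="alpha_c"):
        nb.AgentParameters(1.2, 0.5, 1.0)
    with pytest.raises(ValueError, match="beta"):
        nb.AgentParameters(0.5, 0.5, -1.0)
    with pytest.raises(ValueError, match="omega"):
        nb.AgentParameters(0.5, 0.5, 1.0, omega=-2.0)
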