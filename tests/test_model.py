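"""Variance propagation: Kalman combination, phase recursions, JND prediction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hapticmem.model import (
    ConditionSpec,
    ModelParams,
    batch_inverse_variance,
    kalman_combine,
    predict_jnd,
    standard_phase_variance,
)

variances = st.floats(1e-3, 10.0)
noises = st.floats(0.0, 1.0)
strokes = st.integers(1, 9)


def _combine_oracle(prior, obs):
    # independent arithmetic for one inverse-variance step
    return prior * obs / (prior + obs)


class TestKalmanCombine:
    @pytest.mark.parametrize(
        "prior,obs,post,gain",
        [
            (1.0, 1.0, 0.5, 0.5),
            (0.075, 0.075, 0.0375, 0.5),
            (1e12, 1.0, 1.0, 1.0),  # uninformative-prior limit
        ],
    )
    def test_examples(self, prior, obs, post, gain):
        got_post, got_gain = kalman_combine(prior, obs)
        assert got_post == pytest.approx(post, rel=1e-6)
        assert got_gain == pytest.approx(gain, rel=1e-6)

    @pytest.mark.parametrize("prior,obs", [(0, 1), (1, 0), (-1, 1), (1, -2)])
    def test_nonpositive_variance_rejected(self, prior, obs):
        with pytest.raises(ValueError):
            kalman_combine(prior, obs)

    @given(variances, variances)
    def test_posterior_below_both_and_gain_in_unit_interval(self, prior, obs):
        post, gain = kalman_combine(prior, obs)
        assert 0 < post <= min(prior, obs)
        assert 0 <= gain <= 1


class TestStandardPhase:
    def test_single_stroke_is_single_estimate(self):
        p = ModelParams(sigma2_single=1, sigma2_w_mask=0, sigma2_w_ctrl=0)
        v, _ = standard_phase_variance(p, ConditionSpec(1, False))
        assert v == 1.0

    def test_zero_noise_recovers_sample_mean_variance(self):
        p = ModelParams(sigma2_single=1, sigma2_w_mask=0, sigma2_w_ctrl=0)
        v, _ = standard_phase_variance(p, ConditionSpec(4, False))
        assert v == pytest.approx(0.25, abs=1e-12)

    def test_masked_three_stroke_recursion_matches_hand_computation(self):
        # independent step-by-step recursion with sigma2=0.075, w=0.031
        s2, w = 0.075, 0.031
        v = s2
        for _ in range(2):
            v = _combine_oracle(v + w, s2)
        p = ModelParams(sigma2_single=s2, sigma2_w_mask=w, sigma2_w_ctrl=0.0)
        got, trace = standard_phase_variance(p, ConditionSpec(3, True))
        assert got == pytest.approx(v, rel=1e-12)
        assert len(trace.standard_post_vars) == 3

    @given(variances, noises, strokes)
    def test_trace_invariants(self, s2, w, n1):
        p = ModelParams(sigma2_single=s2, sigma2_w_mask=w, sigma2_w_ctrl=w / 2)
        _, trace = standard_phase_variance(p, ConditionSpec(n1, True))
        for prior, post, gain in zip(
            trace.standard_prior_vars, trace.standard_post_vars, trace.standard_gains
        ):
            assert post <= prior
            assert post > 0
            assert 0 <= gain <= 1


class TestPredictJnd:
    def test_one_stroke_each_gives_sqrt_two(self):
        p = ModelParams(sigma2_single=1, sigma2_w_mask=0, sigma2_w_ctrl=0, n2=1)
        jnd, _ = predict_jnd(p, ConditionSpec(1, False))
        assert jnd == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_two_comparison_strokes_hand_derivation(self):
        # var(D1)=2, var(D2)=2**0.442+1; inverse-variance pool; sqrt
        d1 = 2.0
        d2 = 2.0**0.442 + 1.0
        expected = math.sqrt(_combine_oracle(d1, d2))
        p = ModelParams(sigma2_single=1, sigma2_w_mask=0, sigma2_w_ctrl=0, n2=2)
        jnd, _ = predict_jnd(p, ConditionSpec(1, False))
        assert jnd == pytest.approx(expected, rel=1e-9)
        assert jnd == pytest.approx(1.0403, abs=5e-4)

    def test_integration_benefit_monotone_without_noise(self):
        p = ModelParams(sigma2_single=0.075, sigma2_w_mask=0, sigma2_w_ctrl=0)
        jnds = [predict_jnd(p, ConditionSpec(n1, False))[0] for n1 in (1, 3, 5, 7)]
        assert all(a > b for a, b in zip(jnds, jnds[1:]))

    @given(variances, st.floats(1e-4, 0.5), strokes)
    def test_process_noise_never_helps(self, s2, w, n1):
        clean = ModelParams(sigma2_single=s2, sigma2_w_mask=0, sigma2_w_ctrl=0)
        noisy = ModelParams(sigma2_single=s2, sigma2_w_mask=w, sigma2_w_ctrl=w)
        cond = ConditionSpec(n1, False)
        assert predict_jnd(noisy, cond)[0] >= predict_jnd(clean, cond)[0]

    @given(variances, st.floats(1e-4, 0.5), st.integers(2, 9))
    def test_masking_degrades_precision(self, s2, w_ctrl, n1):
        p = ModelParams(sigma2_single=s2, sigma2_w_mask=2 * w_ctrl, sigma2_w_ctrl=w_ctrl)
        masked = predict_jnd(p, ConditionSpec(n1, True))[0]
        unmasked = predict_jnd(p, ConditionSpec(n1, False))[0]
        assert masked >= unmasked

    def test_masked_equals_unmasked_at_one_stroke_in_control_mode(self):
        p = ModelParams(sigma2_single=0.075, sigma2_w_mask=0.031, sigma2_w_ctrl=0.012)
        masked = predict_jnd(p, ConditionSpec(1, True), comparison_noise_mode="control")[0]
        unmasked = predict_jnd(p, ConditionSpec(1, False), comparison_noise_mode="control")[0]
        assert masked == pytest.approx(unmasked, rel=1e-12)
        # in condition mode the mask's noise also perturbs the difference
        # integration, so masked exceeds unmasked even at one stroke
        masked_c = predict_jnd(p, ConditionSpec(1, True))[0]
        assert masked_c > unmasked

    def test_precision_benefit_levels_out(self, ref_params):
        jnds = {
            n1: predict_jnd(ref_params, ConditionSpec(n1, False))[0]
            for n1 in (1, 3, 5, 7, 9)
        }
        gains = [jnds[n] - jnds[n + 2] for n in (1, 3, 5, 7)]
        assert all(a > b for a, b in zip(gains, gains[1:]))
        assert all(g >= 0 for g in gains)

    @given(variances, noises, strokes)
    def test_jnd_is_sqrt_of_final_difference_variance(self, s2, w, n1):
        p = ModelParams(sigma2_single=s2, sigma2_w_mask=w, sigma2_w_ctrl=w)
        jnd, trace = predict_jnd(p, ConditionSpec(n1, True))
        assert jnd == pytest.approx(math.sqrt(trace.diff_post_vars[-1]), rel=1e-12)
        assert len(trace.diff_post_vars) == p.n2
        assert all(0 <= g <= 1 for g in trace.diff_gains)


class TestBatchInverseVariance:
    @pytest.mark.parametrize(
        "vs,expected",
        [((1, 1), 0.5), ((1, 1, 1, 1), 0.25), ((2, 2.0**0.442 + 1), 1.0822501807)],
    )
    def test_examples(self, vs, expected):
        assert batch_inverse_variance(vs) == pytest.approx(expected, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            batch_inverse_variance([])

    @given(st.lists(variances, min_size=1, max_size=8))
    def test_recursive_filter_matches_closed_form_without_process_noise(self, vs):
        post = vs[0]
        for v in vs[1:]:
            post, _ = kalman_combine(post, v)  # zero process noise
        assert post == pytest.approx(batch_inverse_variance(vs), abs=1e-12)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma2_single": 0.0},
            {"sigma2_w_mask": -0.1},
            {"decay_exponent": -1.0},
            {"n2": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValueError):
            ConditionSpec(0, False)
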