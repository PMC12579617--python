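"""Diffusion kernel: density correctness against independent expansions,
closed-form oracles, and simulator agreement."""

import math

import numpy as np
import pytest
from _reference import ref_choice_prob_upper, ref_f0_large, ref_f0_small, ref_wfpt_pdf
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from ensemble_ddm.ddm import (
    DDMParams,
    choice_prob_upper,
    mean_decision_time,
    simulate_trial,
    simulate_trials,
    wfpt_logpdf,
    wfpt_pdf,
)

PARAM_POINTS = [
    DDMParams(v=0.55, a=1.46, w=0.5, t_er=0.13),
    DDMParams(v=-1.0, a=2.0, w=0.35, t_er=0.2),
    DDMParams(v=2.0, a=0.8, w=0.7, t_er=0.0),
    DDMParams(v=0.0, a=1.2, w=0.5, t_er=0.1),
]


class TestParams:
    @pytest.mark.parametrize(
        "kw", [dict(a=-1.0), dict(a=0.0), dict(w=0.0), dict(w=1.2), dict(t_er=-0.1)]
    )
    def test_invalid_rejected(self, kw):
        base = dict(v=0.5, a=1.5, w=0.5, t_er=0.1)
        with pytest.raises(ValueError):
            DDMParams(**{**base, **kw})

    def test_absolute_start(self):
        assert DDMParams(v=0, a=2.0, w=0.25).z == pytest.approx(0.5)


class TestDensity:
    def test_zero_before_nondecision_time(self):
        p = DDMParams(v=0.5, a=1.5, w=0.5, t_er=0.3)
        assert wfpt_pdf(0.29, "upper", p) == 0.0
        assert wfpt_pdf(0.3, "lower", p) == 0.0

    @given(
        v=st.floats(-2.5, 2.5),
        a=st.floats(0.6, 2.8),
        w=st.floats(0.15, 0.85),
        t=st.floats(0.01, 5.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_reflection_symmetry(self, v, a, w, t):
        up = wfpt_pdf(t, "upper", DDMParams(v=v, a=a, w=w))
        lo = wfpt_pdf(t, "lower", DDMParams(v=-v, a=a, w=1 - w))
        assert up == pytest.approx(lo, abs=1e-10, rel=1e-9)

    @pytest.mark.parametrize("params", PARAM_POINTS)
    def test_matches_reference_expansions(self, params):
        for t in (0.05, 0.2, 0.6, 1.5, 4.0):
            for boundary in ("upper", "lower"):
                ref = ref_wfpt_pdf(t + params.t_er, boundary, params.v, params.a, params.w, params.t_er)
                got = wfpt_pdf(t + params.t_er, boundary, params, eps=1e-12)
                assert got == pytest.approx(ref, abs=1e-8, rel=1e-7)

    def test_branches_agree_in_switchover_region(self):
        # around u ~ 0.5-1.5 both expansions are usable; they must agree
        for u in (0.4, 0.7, 1.0, 1.5):
            for w in (0.3, 0.5, 0.7):
                assert ref_f0_small(u, w) == pytest.approx(ref_f0_large(u, w), abs=1e-7)

    @pytest.mark.parametrize("params", PARAM_POINTS)
    def test_integrates_to_choice_probability(self, params):
        total = 0.0
        for boundary, prob in (
            ("upper", choice_prob_upper(params)),
            ("lower", 1 - choice_prob_upper(params)),
        ):
            integral, _ = integrate.quad(
                lambda t: wfpt_pdf(t, boundary, params, eps=1e-12),
                params.t_er,
                params.t_er + 80.0,
                limit=400,
            )
            assert integral == pytest.approx(prob, abs=1e-6)
            total += integral
        assert total == pytest.approx(1.0, abs=1e-6)


class TestChoiceProbability:
    def test_symmetric_unbiased(self):
        assert choice_prob_upper(DDMParams(v=0.0, a=2.0, w=0.5)) == pytest.approx(0.5)

    def test_task_scale_value(self):
        # frozen from the closed form, cross-checked by the reference
        p = DDMParams(v=0.55, a=1.46, w=0.5)
        assert choice_prob_upper(p) == pytest.approx(0.6906, abs=2e-4)
        assert choice_prob_upper(p) == pytest.approx(
            ref_choice_prob_upper(0.55, 1.46, 0.5), abs=1e-12
        )

    def test_extreme_drift_saturates(self):
        assert choice_prob_upper(DDMParams(v=50.0, a=2.0, w=0.5)) == pytest.approx(1.0)
        assert choice_prob_upper(DDMParams(v=-50.0, a=2.0, w=0.5)) == pytest.approx(0.0, abs=1e-12)

    def test_continuous_at_zero_drift(self):
        lim = choice_prob_upper(DDMParams(v=1e-7, a=1.5, w=0.4))
        assert lim == pytest.approx(0.4, abs=1e-4)


class TestMeanDecisionTime:
    def test_unbiased_zero_drift(self):
        assert mean_decision_time(DDMParams(v=0.0, a=2.0, w=0.5)) == pytest.approx(1.0)

    def test_drift_sign_symmetry_at_midpoint(self):
        up = mean_decision_time(DDMParams(v=0.7, a=1.8, w=0.5))
        dn = mean_decision_time(DDMParams(v=-0.7, a=1.8, w=0.5))
        assert up == pytest.approx(dn, rel=1e-12)

    def test_matches_simulation(self, rng):
        p = DDMParams(v=0.55, a=1.46, w=0.5, t_er=0.0)
        rt, _, _ = simulate_trials(
            np.full(20_000, p.v), p.a, p.w, 0.0, rng, dt=1e-3
        )
        se = rt.std() / math.sqrt(rt.size)
        assert abs(rt.mean() - mean_decision_time(p)) < 3 * se + 2e-3


class TestSimulator:
    def test_rt_exceeds_nondecision_time(self, rng):
        p = DDMParams(v=0.2, a=1.5, w=0.5, t_er=0.25)
        rt, _, capped = simulate_trials(np.full(500, p.v), p.a, p.w, p.t_er, rng)
        assert (rt > p.t_er).all()
        assert not capped.any()

    def test_symmetric_choice_split(self, rng):
        n = 20_000
        rt, up, _ = simulate_trials(np.zeros(n), 1.5, 0.5, 0.1, rng, dt=1e-3)
        assert abs(up.mean() - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_choice_fraction_matches_closed_form(self, rng):
        n = 30_000
        p = DDMParams(v=0.55, a=1.46, w=0.5, t_er=0.13)
        _, up, _ = simulate_trials(np.full(n, p.v), p.a, p.w, p.t_er, rng, dt=1e-3)
        prob = choice_prob_upper(p)
        assert abs(up.mean() - prob) < 3 * math.sqrt(prob * (1 - prob) / n)

    def test_single_trial_interface(self, rng):
        out = simulate_trial(DDMParams(v=1.0, a=1.0, w=0.5, t_er=0.1), rng)
        assert out.boundary in ("upper", "lower")
        assert out.rt > 0.1
        assert out.capped is False

    def test_bad_dt_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_trials(np.zeros(3), 1.0, 0.5, 0.0, rng, dt=0.0)


def test_logpdf_consistent_with_pdf():
    p = DDMParams(v=0.3, a=1.4, w=0.45, t_er=0.1)
    t = np.array([0.3, 0.6, 1.2])
    assert np.allclose(np.exp(wfpt_logpdf(t, "upper", p)), wfpt_pdf(t, "upper", p))
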