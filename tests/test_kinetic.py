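"""Forward models, outcome algebra, decay handling and frame weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from hierpet._conv import curve_frame_integrals
from hierpet.kinetic import (
    ArterialInput,
    BloodData,
    C11_HALF_LIFE_MIN,
    FrameSchedule,
    SRTMParams,
    TimeActivityCurve,
    TwoTCMParams,
    build_model_grid,
    compute_weights,
    decay_uncorrect,
    outcomes_from_rates,
    solve_2tcm,
    solve_srtm,
)


def ode_2tcm_frames(params, input, schedule):
    """Independent oracle: adaptive ODE integration of the state equations,
    with the frame average obtained from an augmented cumulative integral."""
    tk, cp, wp = input.times, input.cp_parent_values, input.wholeplasma_values

    def rhs(t, y):
        cpt = np.interp(t, tk, cp, left=0.0)
        wpt = np.interp(t, tk, wp, left=0.0)
        c1, c2, _ = y
        d1 = params.K1 * cpt - (params.k2 + params.k3) * c1 + params.k4 * c2
        d2 = params.k3 * c1 - params.k4 * c2
        ct = (1 - params.vB) * (c1 + c2) + params.vB * wpt
        return [d1, d2, ct]

    bounds = np.concatenate([schedule.start, [schedule.total_minutes]])
    sol = solve_ivp(rhs, [0, schedule.total_minutes], [0.0, 0.0, 0.0],
                    t_eval=bounds, rtol=1e-11, atol=1e-13, method="LSODA",
                    max_step=1.0)
    return np.diff(sol.y[2]) / schedule.duration


class TestFrameSchedule:
    def test_default_is_20_frames_spanning_110_minutes(self, schedule):
        assert schedule.n_frames == 20
        assert schedule.total_minutes == 110.0
        assert abs(schedule.duration.sum() - 110.0) < 1e-12
        # 3x20s, 3x1, 3x2, 2x5, 9x10 minutes
        np.testing.assert_allclose(
            schedule.duration,
            [1 / 3] * 3 + [1] * 3 + [2] * 3 + [5] * 2 + [10] * 9)

    def test_rejects_overlapping_or_nonpositive_frames(self):
        with pytest.raises(ValueError):
            FrameSchedule([0.0, 1.0], [2.0, 1.0])
        with pytest.raises(ValueError):
            FrameSchedule([0.0, 1.0], [1.0, 0.0])


class TestSolve2TCM:
    def test_no_uptake_reduces_to_blood_volume_term(self, schedule, exp_input):
        p = TwoTCMParams(K1=0.0, k2=0.1, k3=0.05, k4=0.03, vB=0.05)
        got = solve_2tcm(p, exp_input, schedule).activity
        knots, segf = build_model_grid(schedule, exp_input.times)
        wp_avg = curve_frame_integrals(
            knots, exp_input.c_wholeplasma(knots)[None, :], segf,
            schedule.n_frames)[0] / schedule.duration
        np.testing.assert_allclose(got, 0.05 * wp_avg, rtol=1e-12)

    def test_k3_zero_collapses_to_one_tissue_model(self, schedule, exp_input):
        p = TwoTCMParams(K1=0.3, k2=0.15, k3=0.0, k4=0.02, vB=0.0)
        got = solve_2tcm(p, exp_input, schedule).activity
        oracle = ode_2tcm_frames(p, exp_input, schedule)
        np.testing.assert_allclose(got, oracle, rtol=1e-7)

    def test_matches_ode_oracle_on_reference_parameters(self, schedule,
                                                        exp_input):
        p = TwoTCMParams(K1=0.5, k2=0.2, k3=0.05, k4=0.03, vB=0.0)
        got = solve_2tcm(p, exp_input, schedule).activity
        oracle = ode_2tcm_frames(p, exp_input, schedule)
        assert np.max(np.abs(got - oracle) / np.abs(oracle)) < 1e-6

    def test_frame_average_tends_to_point_value_for_short_frames(
            self, exp_input):
        p = TwoTCMParams(K1=0.3, k2=0.2, k3=0.05, k4=0.03, vB=0.02)
        t0 = 30.0

        def frame_avg(dur):
            sch = FrameSchedule([0.0, t0], [t0, dur])
            return solve_2tcm(p, exp_input, sch).activity[-1]

        ref = frame_avg(0.002)  # effectively the point value at t0
        errs = [abs(frame_avg(d) - ref) for d in (2.0, 0.5, 0.05)]
        assert errs[1] < errs[0] and errs[2] < errs[1]
        assert errs[2] < 1e-3 * abs(ref)

    def test_input_scaling_equivalence(self, schedule, exp_input):
        """cp -> c*cp with (K1/c, VND/c) leaves the tissue curve unchanged."""
        c = 2.5
        scaled = ArterialInput(exp_input.times,
                               c * exp_input.cp_parent_values,
                               exp_input.wholeplasma_values, exp_input.fP)
        p1 = TwoTCMParams(K1=0.4, k2=0.2, k3=0.06, k4=0.03, vB=0.04)
        p2 = TwoTCMParams(K1=0.4 / c, k2=0.2 / 1.0, k3=0.06, k4=0.03, vB=0.04)
        a1 = solve_2tcm(p1, exp_input, schedule).activity
        a2 = solve_2tcm(p2, scaled, schedule).activity
        np.testing.assert_allclose(a1, a2, rtol=1e-10)


class TestSolveSRTM:
    def test_identity_when_r1_one_and_bp_zero(self, schedule):
        t = np.linspace(0, 110, 500)
        cr = t * np.exp(-0.15 * t)
        got = solve_srtm(SRTMParams(1.0, 0.2, 0.0), t, cr, schedule).activity
        knots, segf = build_model_grid(schedule, t)
        ref_avg = curve_frame_integrals(
            knots, np.interp(knots, t, cr)[None, :], segf,
            schedule.n_frames)[0] / schedule.duration
        np.testing.assert_allclose(got, ref_avg, rtol=1e-12)

    def test_matches_convolution_oracle(self, schedule):
        R1, k2p, BP = 0.9, 0.15, 2.0
        t = np.linspace(0, 110, 2000)
        cr = t * np.exp(-0.2 * t)
        got = solve_srtm(SRTMParams(R1, k2p, BP), t, cr, schedule).activity
        # fine-grid trapezoid convolution oracle
        dt = 0.0005
        tg = np.arange(0, 110 + dt, dt)
        crg = np.interp(tg, t, cr)
        k2 = R1 * k2p
        k2a = k2 / (1 + BP)
        ker = np.exp(-k2a * tg)
        from scipy.signal import fftconvolve
        conv = (fftconvolve(crg, ker)[:tg.size]
                - 0.5 * (crg[0] * ker + ker[0] * crg)) * dt
        ct = R1 * crg + (k2 - R1 * k2a) * conv
        cum = np.concatenate([[0], np.cumsum((ct[1:] + ct[:-1]) / 2 * dt)])
        bounds = np.concatenate([schedule.start, [110.0]])
        oracle = np.diff(np.interp(bounds, tg, cum)) / schedule.duration
        assert np.max(np.abs(got - oracle) / np.abs(oracle)) < 1e-6


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    K1=st.floats(0.02, 0.6), k2=st.floats(0.02, 0.6),
    k3=st.floats(0.005, 0.3), k4=st.floats(0.005, 0.2),
    fP=st.floats(0.02, 0.5),
)
def test_outcome_identities_hold_exactly(K1, k2, k3, k4, fP):
    p = TwoTCMParams(K1=K1, k2=k2, k3=k3, k4=k4, vB=0.05)
    o = outcomes_from_rates(p, fP=fP)
    assert o.BPP == pytest.approx(o.BPND * o.VND, rel=1e-14)
    assert o.VT == pytest.approx(o.VND + o.BPP, rel=1e-14)
    assert o.BPF == pytest.approx(o.BPP / fP, rel=1e-14)


def test_outcomes_reference_values():
    o = outcomes_from_rates(
        TwoTCMParams(K1=0.1, k2=0.05, k3=0.02, k4=0.01, vB=0.0), fP=0.08)
    assert (o.BPND, o.VND, o.BPP, o.VT, o.BPF) == (2.0, 2.0, 4.0, 6.0, 50.0)
    assert outcomes_from_rates(
        TwoTCMParams(K1=0.2, k2=0.1, k3=0.03, k4=0.03, vB=0.0)).BPND == 1.0
    assert outcomes_from_rates(
        TwoTCMParams(0.1, 0.05, 0.02, 0.01), fP=None).BPF is None
    with pytest.raises(ValueError):
        outcomes_from_rates(TwoTCMParams(0.1, 0.05, 0.02, 0.01), fP=0.0)


class TestDecayAndWeights:
    def test_decay_uncorrect_halves_at_half_life(self):
        hl = C11_HALF_LIFE_MIN
        # contiguous frames whose mid-times hit hl and 2*hl exactly
        starts = np.array([0.0, hl - 0.5, hl + 0.5, 2 * hl - 0.5])
        durs = np.diff(np.concatenate([starts, [2 * hl + 0.5]]))
        sch = FrameSchedule(starts, durs)
        tac = TimeActivityCurve("s", "r", sch, [8.0, 8.0, 8.0, 8.0])
        got = decay_uncorrect(tac)
        lam = np.log(2) / hl
        np.testing.assert_allclose(got, 8.0 * np.exp(-lam * sch.mid))
        assert got[1] == pytest.approx(4.0)   # mid = one half-life
        assert got[3] == pytest.approx(2.0)   # mid = two half-lives

    def test_weights_match_direct_formula(self, schedule):
        rng = np.random.default_rng(3)
        act = np.abs(rng.normal(10, 3, schedule.n_frames))
        tac = TimeActivityCurve("s", "r", schedule, act)
        w = compute_weights(schedule, tac)
        # independent re-evaluation of the published formula
        lam = np.log(2) / C11_HALF_LIFE_MIN
        raw = np.sqrt(schedule.duration * act * np.exp(-lam * schedule.mid))
        np.testing.assert_allclose(w, raw / raw.mean(), rtol=1e-12)
        assert w.mean() == pytest.approx(1.0)

    def test_constant_uncorrected_activity_gives_equal_weights(self):
        sch = FrameSchedule([0, 1, 2, 3.0], [1, 1, 1, 1.0])
        lam = np.log(2) / C11_HALF_LIFE_MIN
        act = 5.0 * np.exp(lam * sch.mid)  # uncorrected activity constant
        w = compute_weights(sch, TimeActivityCurve("s", "r", sch, act))
        np.testing.assert_allclose(w, np.ones(4), rtol=1e-12)

    def test_longer_frame_scales_weight_by_sqrt2(self):
        sch1 = FrameSchedule([0, 1.0], [1.0, 1.0])
        sch2 = FrameSchedule([0, 1.0], [1.0, 2.0])
        lam = np.log(2) / C11_HALF_LIFE_MIN
        w1 = np.sqrt(sch1.duration * 5 * np.exp(-lam * sch1.mid) *
                     np.exp(lam * sch1.mid))
        tac1 = TimeActivityCurve("s", "r", sch1,
                                 5 * np.exp(lam * sch1.mid))
        tac2 = TimeActivityCurve("s", "r", sch2,
                                 5 * np.exp(lam * sch2.mid))
        r1 = compute_weights(sch1, tac1)
        r2 = compute_weights(sch2, tac2)
        # un-normalized ratio of frame-2 weights is sqrt(2)
        assert (r2[1] / r2[0]) / (r1[1] / r1[0]) == pytest.approx(np.sqrt(2))

    def test_all_zero_tac_warns_and_returns_uniform(self, schedule):
        tac = TimeActivityCurve("s", "r", schedule,
                                np.zeros(schedule.n_frames))
        with pytest.warns(UserWarning):
            w = compute_weights(schedule, tac)
        np.testing.assert_array_equal(w, np.ones(schedule.n_frames))


class TestBloodAndInput:
    def test_blood_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BloodData([0, 1, 1.0], [1, 2, 3.0], [1, 1, 1.0])
        with pytest.raises(ValueError):
            BloodData([0, 1.0], [1, -2.0], [1, 1.0])
        with pytest.raises(ValueError):
            BloodData([0, 1.0], [1, 2.0], [1, 1.5])

    def test_metabolite_corrected_product(self):
        bd = BloodData([0, 1, 2.0], [0, 10, 5.0], [1.0, 0.8, 0.5])
        np.testing.assert_allclose(bd.metabolite_corrected_plasma,
                                   [0, 8, 2.5])

    def test_from_blood_data_interpolates_and_extrapolates(self):
        t = np.array([0.25, 0.5, 1.0, 2.0, 5.0, 20.0, 60.0])
        wp = np.array([2.0, 40.0, 30.0, 20.0, 10.0, 4.0, 1.0])
        pf = np.array([1.0, 1.0, 0.95, 0.9, 0.7, 0.3, 0.1])
        inp = ArterialInput.from_blood_data(BloodData(t, wp, pf), fP=0.07)
        assert inp.cp_parent(0.0) == 0.0
        # log-linear after the peak: exact at samples
        assert inp.c_wholeplasma(5.0) == pytest.approx(10.0, rel=1e-6)
        # log-linear tail: the value at the segment's time midpoint is the
        # geometric mean of the endpoint values
        assert inp.c_wholeplasma(40.0) == pytest.approx(2.0, rel=1e-2)
        sch = FrameSchedule.default()
        with pytest.warns(UserWarning, match="extrapolat"):
            inp.check_covers(sch)
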