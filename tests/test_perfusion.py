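"""Facility estimation: steady-state detection, step summaries, power-law fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import curve_fit

from aqdyn import synth
from aqdyn.perfusion import (
    FacilityFailure,
    FacilityFit,
    InsufficientStepsError,
    PerfusionTrace,
    SteadyStateCriterion,
    StepSummary,
    detect_steady_window,
    facility_for_eye,
    fit_power_law,
    summarize_step,
)


def single_step_trace(t, q, pressure=8.0):
    return PerfusionTrace(
        eye_id="t",
        time=t,
        pressure=np.full_like(t, pressure),
        flow=q,
        step_slices=[(0, len(t))],
    )


def exact_steps(cr, beta, pressures=np.linspace(4.5, 16.5, 8), pr=8.0, noise=None):
    c = cr * (pressures / pr) ** beta
    if noise is not None:
        c = c * np.exp(noise)
    return [
        StepSummary(
            step_index=i, p_ss=p, q_ss=ci * p, c_step=ci,
            ci95=(ci, ci), steady_window=(0.0, 1.0),
        )
        for i, (p, ci) in enumerate(zip(pressures, c))
    ]


class TestDetectSteadyWindow:
    def test_constant_inflow_spans_step(self):
        t = np.arange(0.0, 300.0)
        win = detect_steady_window(single_step_trace(t, np.full_like(t, 40.0)), 0)
        assert win is not None
        start, end = win
        assert end == t[-1]
        # available from the first full regression window (center attribution)
        assert start <= 31.0

    def test_persistent_ramp_never_settles(self):
        t = np.arange(0.0, 300.0)
        q = 40.0 + (5.0 / 60.0) * t  # 5 nl/min per min, above threshold
        assert detect_steady_window(single_step_trace(t, q), 0) is None

    def test_exponential_crossing_matches_analytics(self):
        # slope of 30 + 20 exp(-t/60) crosses 3 nl/min/min at 60 ln(20/3)
        t = np.arange(0.0, 400.0)
        q = 30.0 + 20.0 * np.exp(-t / 60.0)
        crit = SteadyStateCriterion(slope_threshold=3.0, window=10.0, min_dwell=30.0)
        win = detect_steady_window(single_step_trace(t, q), 0, crit)
        assert win is not None
        assert win[0] == pytest.approx(60.0 * np.log(20.0 / 3.0), abs=1.0)

    def test_brute_force_scan_agrees(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 400.0)
        q = 30.0 + 20.0 * np.exp(-t / 60.0) + rng.normal(0, 0.05, t.size)
        crit = SteadyStateCriterion(slope_threshold=3.0, window=20.0, min_dwell=30.0)
        win = detect_steady_window(single_step_trace(t, q), 0, crit)
        # oracle: explicit per-window polyfit scan
        m = 21
        slopes = np.array(
            [np.polyfit(t[i : i + m], q[i : i + m], 1)[0] * 60 for i in range(t.size - m + 1)]
        )
        centers = np.array([t[i : i + m].mean() for i in range(t.size - m + 1)])
        below = np.abs(slopes) < 3.0
        ok = next(
            i for i in range(below.size)
            if below[i:][: int(np.searchsorted(centers[i:], centers[i] + 30) + 1)].all()
        )
        assert win[0] == pytest.approx(centers[ok], abs=1e-9)

    def test_smaller_threshold_never_earlier(self):
        t = np.arange(0.0, 400.0)
        q = 30.0 + 20.0 * np.exp(-t / 60.0)
        starts = []
        for thr in (6.0, 3.0, 1.5):
            win = detect_steady_window(
                single_step_trace(t, q), 0, SteadyStateCriterion(thr, 20.0, 30.0)
            )
            starts.append(win[0])
        assert starts == sorted(starts)


class TestSummarizeStep:
    def test_facility_is_flow_over_pressure(self):
        t = np.arange(0.0, 100.0)
        tr = single_step_trace(t, np.full_like(t, 40.0), pressure=8.0)
        s = summarize_step(tr, 0, (0.0, 99.0))
        assert s.c_step == pytest.approx(5.0)
        assert s.ci95 == pytest.approx((5.0, 5.0))  # zero-variance window

    def test_high_pressure_step(self):
        t = np.arange(0.0, 100.0)
        tr = single_step_trace(t, np.full_like(t, 36.3), pressure=16.5)
        assert summarize_step(tr, 0, (0.0, 99.0)).c_step == pytest.approx(2.2)

    def test_nonpositive_pressure_raises(self):
        t = np.arange(0.0, 10.0)
        tr = PerfusionTrace(
            eye_id="t", time=t, pressure=np.zeros_like(t),
            flow=np.full_like(t, 1.0), step_slices=[(0, 10)],
        )
        with pytest.raises(ValueError, match="pressure"):
            summarize_step(tr, 0, (0.0, 9.0))


class TestFitPowerLaw:
    @pytest.mark.parametrize("cr,beta", [(5.0, 0.3), (4.4, 0.0), (2.0, -0.2), (9.5, 1.0)])
    def test_exact_recovery(self, cr, beta):
        fit = fit_power_law(exact_steps(cr, beta))
        assert fit.cr == pytest.approx(cr, rel=1e-9)
        assert fit.beta == pytest.approx(beta, abs=1e-9)

    def test_flat_data(self):
        fit = fit_power_law(exact_steps(4.4, 0.0))
        assert (fit.cr, fit.beta) == (pytest.approx(4.4), pytest.approx(0.0, abs=1e-12))

    def test_too_few_steps_raises(self):
        with pytest.raises(InsufficientStepsError):
            fit_power_law(exact_steps(5.0, 0.3)[:2])

    def test_grid_search_oracle(self):
        # log-space least squares must agree with brute-force SSE minimization
        rng = np.random.default_rng(42)
        for _ in range(20):
            cr = rng.uniform(2, 10)
            beta = rng.uniform(-0.3, 1.0)
            steps = exact_steps(cr, beta, noise=rng.normal(0, 0.05, 8))
            fit = fit_power_law(steps)
            lncr_grid = np.linspace(np.log(fit.cr) - 0.3, np.log(fit.cr) + 0.3, 241)
            beta_grid = np.linspace(fit.beta - 0.5, fit.beta + 0.5, 401)
            x = np.log([s.p_ss for s in steps]) - np.log(8.0)
            y = np.log([s.c_step for s in steps])
            sse = (
                (y[None, None, :] - lncr_grid[:, None, None] - beta_grid[None, :, None] * x) ** 2
            ).sum(axis=2)
            i, j = np.unravel_index(sse.argmin(), sse.shape)
            assert np.log(fit.cr) == pytest.approx(lncr_grid[i], abs=0.3 / 120)
            assert fit.beta == pytest.approx(beta_grid[j], abs=0.5 / 200)

    def test_nonlinear_least_squares_agrees_on_multiplicative_noise(self):
        # with multiplicative residuals the log-space fit is the MLE; a
        # nonlinear fit of ln C agrees to optimizer tolerance
        rng = np.random.default_rng(7)
        steps = exact_steps(5.0, 0.3, noise=rng.normal(0, 0.05, 8))
        fit = fit_power_law(steps)
        p = np.array([s.p_ss for s in steps])
        c = np.array([s.c_step for s in steps])
        popt, _ = curve_fit(
            lambda pp, lncr, b: lncr + b * np.log(pp / 8.0), p, np.log(c), p0=(1.0, 0.0)
        )
        assert np.log(fit.cr) == pytest.approx(popt[0], abs=1e-7)
        assert fit.beta == pytest.approx(popt[1], abs=1e-7)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    k=st.floats(min_value=0.1, max_value=10.0),
    cr=st.floats(min_value=1.0, max_value=10.0),
    beta=st.floats(min_value=-0.5, max_value=1.0),
)
def test_scale_equivariance(k, cr, beta):
    """Multiplying all flows by k multiplies Cr by k and leaves beta alone."""
    steps = exact_steps(cr, beta)
    scaled = [
        StepSummary(
            step_index=s.step_index, p_ss=s.p_ss, q_ss=s.q_ss * k,
            c_step=s.c_step * k, ci95=s.ci95, steady_window=s.steady_window,
        )
        for s in steps
    ]
    f0, f1 = fit_power_law(steps), fit_power_law(scaled)
    assert f1.cr == pytest.approx(k * f0.cr, rel=1e-9)
    assert f1.beta == pytest.approx(f0.beta, abs=1e-9)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    pr_new=st.floats(min_value=2.0, max_value=20.0),
    beta=st.floats(min_value=-0.5, max_value=1.0),
)
def test_reference_pressure_relabeling(pr_new, beta):
    """Moving Pr rescales Cr by (Pr_new/Pr_old)**beta, exactly."""
    fit = fit_power_law(exact_steps(5.0, beta), pr=8.0)
    refit = fit_power_law(exact_steps(5.0, beta), pr=pr_new)
    assert refit.cr == pytest.approx(fit.cr * (pr_new / 8.0) ** beta, rel=1e-9)
    assert refit.beta == pytest.approx(fit.beta, abs=1e-9)


class TestFacilityForEye:
    def test_zero_noise_recovers_truth(self, wt_only_config, wt_eyes):
        eye = wt_eyes[0]
        trace = synth.generate_perfusion_trace(eye, wt_only_config)
        fit = facility_for_eye(trace)
        assert isinstance(fit, FacilityFit)
        assert fit.cr == pytest.approx(eye.cr_true, rel=1e-9)

    def test_unusable_trace_fails_cleanly(self, wt_only_config, wt_eyes):
        trace = synth.generate_perfusion_trace(wt_eyes[0], wt_only_config)
        trace.usable = False
        res = facility_for_eye(trace)
        assert isinstance(res, FacilityFailure)
        assert res.reason == "unusable"

    def test_exclusion_count_matches_failure_rate(self):
        # ~9 of 114 perfusions failed in the study protocol
        cfg = synth.SyntheticConfig.from_study_defaults(
            n_eyes=12, master_seed=1, failure_rate=9 / 114
        )
        eyes = synth.generate_cohort(cfg)[:114]
        n_failed = sum(
            not synth.generate_perfusion_trace(e, cfg).usable for e in eyes
        )
        assert 2 <= n_failed <= 18  # binomial(114, 0.079) central range
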