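"""Goldmann balance: Q calibration, expected IOP, error propagation, report."""

import math

import numpy as np
import pytest

from aqdyn.goldmann import (
    ExpectedIOPResult,
    GoldmannParams,
    adjusted_facility,
    calibrate_q,
    crossval_report,
    expected_iop,
    propagate_expected_iop_ci,
)
from aqdyn.perfusion import FacilityFit
from aqdyn.summaries import GroupSummary


def make_summary(iop, facility, beta=0.0, logcr_se=0.0):
    return GroupSummary(
        group="WT", timepoint="baseline", n_eyes=10,
        iop_mean=iop, iop_ci=(iop, iop),
        facility_geomean=facility, facility_ci=(facility, facility),
        facility_beta=beta, facility_logcr_se=logcr_se,
    )


class TestCalibrateQ:
    def test_published_wt_numbers(self):
        # Q = C * (IOP - Pe) = 4.4 * (15.6 - 7) at beta = 0
        params = calibrate_q(make_summary(15.6, 4.4), pe=7.0)
        assert params.q == pytest.approx(37.84)

    def test_unit_case(self):
        assert calibrate_q(make_summary(8.0, 1.0), pe=7.0).q == pytest.approx(1.0)

    def test_iop_at_pe_degenerate(self):
        with pytest.raises(ValueError, match="exceed"):
            calibrate_q(make_summary(7.0, 4.4), pe=7.0)


class TestAdjustedFacility:
    @pytest.mark.parametrize(
        "cr,beta,dp,expected",
        [
            (4.4, 0.0, 5.0, 4.4),
            (4.4, 0.0, 30.0, 4.4),
            (4.4, 1.0, 16.0, 8.8),
            (5.0, 0.3, 10.0, 5.0 * 1.25**0.3),
        ],
    )
    def test_power_law_values(self, cr, beta, dp, expected):
        fit = FacilityFit(cr=cr, beta=beta, pr=8.0)
        assert adjusted_facility(fit, dp) == pytest.approx(expected, rel=1e-12)
        if beta == 0.3:
            assert adjusted_facility(fit, dp) == pytest.approx(5.346, abs=1e-3)

    def test_nonpositive_drop_raises(self):
        with pytest.raises(ValueError):
            adjusted_facility(FacilityFit(cr=4.4, beta=0.0), 0.0)


class TestExpectedIOP:
    def test_beta_zero_closed_form(self):
        params = GoldmannParams(q=37.84, pe=7.0)
        iop = expected_iop(params, FacilityFit(cr=8.4, beta=0.0))
        assert iop == pytest.approx(7.0 + 37.84 / 8.4, abs=1e-9)
        assert iop == pytest.approx(11.504, abs=1e-3)

    def test_reference_round_trip(self):
        params = calibrate_q(make_summary(15.6, 4.4), pe=7.0)
        iop = expected_iop(params, FacilityFit(cr=4.4, beta=0.0))
        assert iop == pytest.approx(15.6, abs=1e-9)

    def test_beta_one_quadratic_closed_form(self):
        # Q = Cr dp^2 / Pr  =>  dp = sqrt(Q Pr / Cr)
        params = GoldmannParams(q=37.84, pe=7.0)
        iop = expected_iop(params, FacilityFit(cr=4.4, beta=1.0, pr=8.0))
        dp = math.sqrt(37.84 * 8.0 / 4.4)
        assert iop == pytest.approx(7.0 + dp, abs=1e-9)
        assert iop == pytest.approx(15.294, abs=1e-3)

    def test_bisection_oracle_general_beta(self):
        from scipy.optimize import bisect

        params = GoldmannParams(q=37.84, pe=7.0)
        for beta in (-0.5, 0.3, 0.7, 2.0):
            fit = FacilityFit(cr=4.4, beta=beta, pr=8.0)
            f = lambda iop: 4.4 * ((iop - 7.0) / 8.0) ** beta * (iop - 7.0) - 37.84
            oracle = bisect(f, 7.0 + 1e-9, 100.0, xtol=1e-10)
            assert expected_iop(params, fit) == pytest.approx(oracle, abs=1e-6)

    def test_monotone_in_cr_and_q(self):
        pe = 7.0
        for beta in (0.0, 0.5):
            iops_cr = [
                expected_iop(GoldmannParams(q=37.84, pe=pe), FacilityFit(cr=c, beta=beta))
                for c in np.linspace(2, 10, 9)
            ]
            assert all(a > b for a, b in zip(iops_cr, iops_cr[1:]))
            iops_q = [
                expected_iop(GoldmannParams(q=q, pe=pe), FacilityFit(cr=4.4, beta=beta))
                for q in np.linspace(10, 80, 8)
            ]
            assert all(a < b for a, b in zip(iops_q, iops_q[1:]))

    def test_invalid_beta_raises(self):
        with pytest.raises(ValueError, match="monotone"):
            expected_iop(GoldmannParams(q=37.84), FacilityFit(cr=4.4, beta=-1.5))


class TestPropagation:
    def test_zero_variance_zero_width(self):
        lo, hi, se = propagate_expected_iop_ci(
            GoldmannParams(q=37.84), FacilityFit(cr=8.4, beta=0.0)
        )
        assert se == 0.0 and lo == hi

    def test_beta_zero_closed_form_se(self):
        # var(IOP) = (Q/Cr)^2 var(lnCr) + var(Q)/Cr^2
        fit = FacilityFit(cr=8.4, beta=0.0, logcr_se=0.1)
        _, _, se = propagate_expected_iop_ci(GoldmannParams(q=37.84), fit, q_se=0.0)
        assert se == pytest.approx(37.84 / 8.4 * 0.1, rel=1e-9)
        assert se == pytest.approx(0.4505, abs=1e-4)

    def test_monte_carlo_agrees_with_delta_method(self):
        # at published-scale uncertainties the first-order SE is accurate
        rng = np.random.default_rng(0)
        fit = FacilityFit(cr=4.4, beta=0.3, logcr_se=0.08, beta_se=0.05)
        params = GoldmannParams(q=37.84, q_se=1.5)
        lo, hi, se = propagate_expected_iop_ci(params, fit)
        n = 40000
        draws = []
        lncr = math.log(4.4) + rng.normal(0, 0.08, n)
        beta = 0.3 + rng.normal(0, 0.05, n)
        q = 37.84 + rng.normal(0, 1.5, n)
        for lc, b, qi in zip(lncr[:5000], beta[:5000], q[:5000]):
            draws.append(
                expected_iop(
                    GoldmannParams(q=qi), FacilityFit(cr=math.exp(lc), beta=b)
                )
            )
        mc_se = np.std(draws, ddof=1)
        assert se == pytest.approx(mc_se, rel=0.05)


class TestCrossvalReport:
    @staticmethod
    def result(label, expected, experimental, facility=4.4, beta=0.0):
        return ExpectedIOPResult(
            label=label, expected_iop=expected, expected_ci=(expected, expected),
            experimental_iop=experimental, experimental_ci=(experimental, experimental),
            facility_used=facility, beta_used=beta,
        )

    def test_constant_residuals(self):
        results = [self.result(f"g{i}", 14.0 + i, 15.0 + i) for i in range(3)]
        rep = crossval_report(results)
        assert rep.mean_residual == pytest.approx(1.0)
        assert rep.residual_ci == pytest.approx((1.0, 1.0))

    def test_perfect_agreement(self):
        results = [self.result(f"g{i}", 12.0 + i, 12.0 + i) for i in range(4)]
        rep = crossval_report(results)
        assert rep.regression_slope == pytest.approx(1.0)
        assert rep.regression_intercept == pytest.approx(0.0, abs=1e-12)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.mean_residual == pytest.approx(0.0, abs=1e-12)
        assert rep.slope_vs_unity_p == pytest.approx(1.0)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        exp = rng.uniform(11, 18, 6)
        meas = exp + rng.normal(0, 0.5, 6)
        base = crossval_report(
            [self.result(f"g{i}", e, m) for i, (e, m) in enumerate(zip(exp, meas))]
        )
        shifted = crossval_report(
            [self.result(f"g{i}", e, m + 2.0) for i, (e, m) in enumerate(zip(exp, meas))]
        )
        assert shifted.mean_residual == pytest.approx(base.mean_residual + 2.0)
        assert shifted.regression_slope == pytest.approx(base.regression_slope)

    def test_too_few_groups(self):
        with pytest.raises(ValueError, match="3"):
            crossval_report([self.result("a", 12, 12), self.result("b", 13, 13)])

    def test_bland_altman_coordinates(self):
        results = [self.result("a", 12.0, 14.0), self.result("b", 15.0, 15.0),
                   self.result("c", 16.0, 17.0)]
        rep = crossval_report(results)
        row = rep.bland_altman.set_index("label").loc["a"]
        assert row["mean_iop"] == pytest.approx(13.0)
        assert row["difference"] == pytest.approx(2.0)
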