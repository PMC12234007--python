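"""Cross-validation of measured IOP against facility via the Goldmann balance.

At steady state the net pressure-independent aqueous flow Q (humor formation
minus uveoscleral outflow; the two are never separated) balances conventional
outflow:

    Q = C * (IOP - Pe)

with Pe the episcleral venous pressure (7 mmHg here).  Q is calibrated once
from a reference cohort (wild-type) and assumed identical across cohorts.
Because facility itself depends on pressure through the power law
C(P) = Cr * (P/Pr)**beta, with the pressure drop taken as P = IOP - Pe, the
expected IOP for a cohort solves the implicit equation

    Q = Cr * ((IOP - Pe) / Pr)**beta * (IOP - Pe)

whose left-over residual is strictly monotone in IOP for beta > -1, so a
bracketed root finder suffices.  Residuals are experimental minus expected
IOP (the sign convention of the published Bland-Altman panel; the methods
text orders the difference the other way).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .perfusion import FacilityFit
from .summaries import GroupSummary

__all__ = [
    "GoldmannParams",
    "ExpectedIOPResult",
    "CrossValReport",
    "calibrate_q",
    "adjusted_facility",
    "expected_iop",
    "propagate_expected_iop_ci",
    "crossval_report",
]

IOP_BRACKET_MAX = 100.0  # mmHg; physiologically absurd upper bound
SOLVER_TOL = 1e-9


@dataclass(frozen=True)
class GoldmannParams:
    """Calibrated pressure-independent flow and the venous back-pressure."""

    q: float                       # nl/min
    pe: float = 7.0                # mmHg
    reference_group: str = "WT"
    q_se: float = 0.0              # nl/min, from the reference cohort

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("Q must be positive")
        if self.pe < 0:
            raise ValueError("Pe must be non-negative")


def calibrate_q(
    reference: GroupSummary,
    pe: float = 7.0,
    beta: float | None = None,
) -> GoldmannParams:
    """Back out Q from the reference cohort's mean facility and mean IOP.

    The reference facility is evaluated at the cohort's own pressure drop
    (IOP - Pe) through the power law before applying the Goldmann balance.
    ``beta`` defaults to the cohort-mean exponent stored on the summary.
    """
    if reference.facility_geomean is None:
        raise ValueError("reference group has no facility summary")
    iop = reference.iop_mean
    if iop <= pe:
        raise ValueError(f"reference IOP {iop} must exceed Pe {pe}")
    b = reference.facility_beta if beta is None else beta
    dp = iop - pe
    c_at_dp = reference.facility_geomean * (dp / 8.0) ** b
    q = c_at_dp * dp
    # delta-method SE of Q from the SE of ln Cr: dQ/dlnCr = Q
    q_se = q * reference.facility_logcr_se
    return GoldmannParams(q=q, pe=pe, reference_group=reference.label, q_se=q_se)


def adjusted_facility(fit: FacilityFit, delta_p: float) -> float:
    """Facility at a pressure drop delta_p via the fitted power law."""
    if delta_p <= 0:
        raise ValueError("pressure drop must be positive")
    return fit.cr * (delta_p / fit.pr) ** fit.beta


def expected_iop(
    params: GoldmannParams, fit: FacilityFit, tol: float = 1e-6
) -> float:
    """IOP consistent with a cohort's facility under the Goldmann balance.

    Solves Q = Cr * ((IOP-Pe)/Pr)**beta * (IOP-Pe) for the unique root above
    Pe; closed form Pe + Q/Cr when beta = 0.
    """
    q, pe = params.q, params.pe
    cr, beta, pr = fit.cr, fit.beta, fit.pr
    if beta <= -1:
        raise ValueError("beta <= -1: outflow no longer monotone in IOP")
    if beta == 0:
        return pe + q / cr
    # monotone in dp for beta > -1: solve on the log of the pressure drop
    def resid(iop: float) -> float:
        dp = iop - pe
        return cr * (dp / pr) ** beta * dp - q

    hi = IOP_BRACKET_MAX
    if resid(hi) < 0:
        raise ValueError("expected IOP exceeds 100 mmHg; cannot bracket root")
    return float(optimize.brentq(resid, pe + 1e-9, hi, xtol=min(tol, 1e-7)))


def _iop_partials(
    params: GoldmannParams, fit: FacilityFit
) -> tuple[float, float, float, float]:
    """(iop, d/dlnCr, d/dbeta, d/dQ) of the implicit expected-IOP solution.

    From ln Q = ln Cr + (1+beta) ln(dp) - beta ln Pr, implicit differentiation
    gives d(dp)/dx = -dp/(1+beta) * dF/dx for each parameter x.
    """
    iop = expected_iop(params, fit, tol=SOLVER_TOL)
    dp = iop - params.pe
    denom = 1.0 + fit.beta
    d_lncr = -dp / denom
    d_beta = -dp * math.log(dp / fit.pr) / denom
    d_q = dp / (denom * params.q)
    return iop, d_lncr, d_beta, d_q


def propagate_expected_iop_ci(
    params: GoldmannParams,
    fit: FacilityFit,
    q_se: float | None = None,
    check_mc: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """First-order (delta-method) 95% CI on the expected IOP.

    Propagates var(ln Cr), var(beta) and var(Q) through the implicit solution
    using analytic partial derivatives; the interval assumes normality.
    Returns (lo, hi, se).  With ``check_mc`` a Monte-Carlo resampling check is
    run and the SE is flagged (ValueError) if the first-order approximation is
    off by more than 10%.
    """
    q_se = params.q_se if q_se is None else q_se
    iop, d_lncr, d_beta, d_q = _iop_partials(params, fit)
    var = (
        d_lncr**2 * fit.logcr_se**2
        + d_beta**2 * fit.beta_se**2
        + d_q**2 * q_se**2
    )
    se = math.sqrt(var)
    if check_mc and se > 0:
        rng = rng or np.random.default_rng(0)
        n = 20000
        lncr = math.log(fit.cr) + rng.normal(0, fit.logcr_se, n)
        beta = fit.beta + rng.normal(0, fit.beta_se, n)
        qs = params.q + rng.normal(0, q_se, n)
        keep = qs > 0
        sims = [
            expected_iop(
                GoldmannParams(q=qi, pe=params.pe),
                FacilityFit(cr=math.exp(lc), beta=b, pr=fit.pr),
            )
            for lc, b, qi in zip(lncr[keep], beta[keep], qs[keep])
        ]
        mc_se = float(np.std(sims, ddof=1))
        if abs(mc_se - se) > 0.10 * mc_se:
            raise ValueError(
                f"delta-method SE {se:.4g} deviates >10% from Monte-Carlo {mc_se:.4g}"
            )
    half = 1.959963984540054 * se
    return (iop - half, iop + half, se)


@dataclass
class ExpectedIOPResult:
    """Per-cohort comparison of measured and Goldmann-expected IOP."""

    label: str
    expected_iop: float
    expected_ci: tuple[float, float]
    experimental_iop: float
    experimental_ci: tuple[float, float]
    facility_used: float
    beta_used: float

    @property
    def residual(self) -> float:
        """Experimental minus expected IOP, mmHg."""
        return self.experimental_iop - self.expected_iop


@dataclass
class CrossValReport:
    mean_residual: float
    residual_ci: tuple[float, float]
    residual_t_test_p: float
    regression_slope: float
    slope_ci: tuple[float, float]
    regression_intercept: float
    r_squared: float
    slope_vs_unity_p: float
    bland_altman: pd.DataFrame = field(repr=False, default=None)
    per_group: pd.DataFrame = field(repr=False, default=None)


def crossval_report(results: list[ExpectedIOPResult]) -> CrossValReport:
    """Residual t-test, experimental-on-expected regression and Bland-Altman.

    The regression is ordinary least squares of experimental on expected IOP
    (as plotted in the study); the slope is additionally tested against unity.
    """
    if len(results) < 3:
        raise ValueError("cross-validation needs at least 3 cohorts")
    expd = np.array([r.expected_iop for r in results])
    meas = np.array([r.experimental_iop for r in results])
    resid = meas - expd
    n = len(results)
    mean_res = float(resid.mean())
    sd = float(resid.std(ddof=1))
    tcrit = sps.t.ppf(0.975, n - 1)
    ci = (mean_res - tcrit * sd / math.sqrt(n), mean_res + tcrit * sd / math.sqrt(n))
    if sd > 0:
        t_p = float(sps.ttest_1samp(resid, 0.0).pvalue)
    else:
        t_p = 0.0 if mean_res != 0 else 1.0
    lr = sps.linregress(expd, meas)
    dof = n - 2
    if lr.stderr > 0:
        slope_p = 2 * sps.t.sf(abs((lr.slope - 1.0) / lr.stderr), dof)
    else:
        slope_p = 1.0 if lr.slope == 1.0 else 0.0
    tcrit2 = sps.t.ppf(0.975, dof)
    ba = pd.DataFrame(
        {
            "label": [r.label for r in results],
            "mean_iop": (expd + meas) / 2.0,
            "difference": resid,
        }
    )
    per_group = pd.DataFrame(
        {
            "label": [r.label for r in results],
            "expected_iop": expd,
            "experimental_iop": meas,
            "residual": resid,
            "facility_used": [r.facility_used for r in results],
            "beta_used": [r.beta_used for r in results],
        }
    )
    return CrossValReport(
        mean_residual=mean_res,
        residual_ci=ci,
        residual_t_test_p=t_p,
        regression_slope=float(lr.slope),
        slope_ci=(lr.slope - tcrit2 * lr.stderr, lr.slope + tcrit2 * lr.stderr),
        regression_intercept=float(lr.intercept),
        r_squared=float(lr.rvalue**2),
        slope_vs_unity_p=float(slope_p),
        bland_altman=ba,
        per_group=per_group,
    )
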