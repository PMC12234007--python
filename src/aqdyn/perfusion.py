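"""Outflow facility estimation from multi-step pressure-controlled perfusion.

An enucleated eye is perfused at eight pressure steps (4.5-16.5 mmHg).  At
each step the inflow rate relaxes toward the steady outflow; once the rate of
change of inflow falls below a threshold (3 nl/min/min by protocol) the step
is considered steady and the per-step facility is the ratio of steady inflow
to steady pressure (the downstream pressure of a submerged enucleated eye is
zero).  The per-step facilities C are then fit with the empirical power law

    C(P) = C_r * (P / P_r) ** beta

with reference pressure P_r = 8 mmHg, the physiologic pressure difference
across the conventional outflow pathway.  Fitting is performed in log space,
which linearizes the model and matches the log-normal error structure of
facility data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

__all__ = [
    "PerfusionTrace",
    "SteadyStateCriterion",
    "StepSummary",
    "FacilityFit",
    "FacilityFailure",
    "detect_steady_window",
    "summarize_step",
    "fit_power_law",
    "facility_for_eye",
    "read_trace",
    "write_trace",
]


@dataclass
class PerfusionTrace:
    """Per-eye pressure/flow time series partitioned into pressure steps.

    ``step_slices`` holds (start, stop) sample indices for each pressure step;
    samples before the first step are the acclimatization phase (the eye is
    stabilized at 8 mmHg before stepping; preparatory phases are trimmed).
    """

    eye_id: str
    time: np.ndarray      # s, strictly increasing
    pressure: np.ndarray  # mmHg
    flow: np.ndarray      # nl/min
    step_slices: list[tuple[int, int]]
    usable: bool = True

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if not (len(self.time) == len(self.pressure) == len(self.flow)):
            raise ValueError("time, pressure and flow must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for start, stop in self.step_slices:
            if stop - start < 2:
                raise ValueError("each pressure step needs at least 2 samples")

    @property
    def n_steps(self) -> int:
        return len(self.step_slices)

    def step_arrays(self, step_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        start, stop = self.step_slices[step_index]
        return self.time[start:stop], self.pressure[start:stop], self.flow[start:stop]

    def to_frame(self) -> pd.DataFrame:
        step_index = np.full(len(self.time), -1, dtype=int)
        for k, (start, stop) in enumerate(self.step_slices):
            step_index[start:stop] = k
        return pd.DataFrame(
            {
                "time_s": self.time,
                "pressure_mmHg": self.pressure,
                "flow_nl_min": self.flow,
                "step_index": step_index,
            }
        )


def write_trace(trace: PerfusionTrace, path) -> None:
    trace.to_frame().to_csv(path, sep="\t", index=False)


def read_trace(path, eye_id: str | None = None, usable: bool = True) -> PerfusionTrace:
    df = pd.read_csv(path, sep="\t")
    steps = []
    idx = df["step_index"].to_numpy()
    for k in range(int(idx.max()) + 1):
        where = np.flatnonzero(idx == k)
        steps.append((int(where[0]), int(where[-1]) + 1))
    return PerfusionTrace(
        eye_id=eye_id or str(path),
        time=df["time_s"].to_numpy(),
        pressure=df["pressure_mmHg"].to_numpy(),
        flow=df["flow_nl_min"].to_numpy(),
        step_slices=steps,
        usable=usable,
    )


@dataclass(frozen=True)
class SteadyStateCriterion:
    """Protocol rule for declaring a pressure step steady.

    The inflow slope (nl/min per min) is estimated by linear regression over a
    sliding window and attributed to the window center; the step is steady
    from the first time the |slope| stays below ``slope_threshold`` for at
    least ``min_dwell`` seconds.
    """

    slope_threshold: float = 3.0  # nl/min per min
    window: float = 60.0          # s
    min_dwell: float = 30.0       # s

    def __post_init__(self) -> None:
        if self.slope_threshold <= 0:
            raise ValueError("slope_threshold must be positive")
        if self.window <= 0 or self.min_dwell < 0:
            raise ValueError("window must be positive, min_dwell non-negative")


def _sliding_slopes(t: np.ndarray, q: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope of q vs t over every length-m window.

    Returns (center_times, slopes) with slope in units of q per unit t.
    """
    tw = sliding_window_view(t, m)
    qw = sliding_window_view(q, m)
    t_mean = tw.mean(axis=1)
    q_mean = qw.mean(axis=1)
    cov = (tw * qw).mean(axis=1) - t_mean * q_mean
    var = (tw * tw).mean(axis=1) - t_mean * t_mean
    return t_mean, cov / var


def detect_steady_window(
    trace: PerfusionTrace,
    step_index: int,
    criterion: SteadyStateCriterion = SteadyStateCriterion(),
) -> tuple[float, float] | None:
    """Earliest steady interval of a step, or None if the step never settles.

    The returned interval starts at the first window-center time from which
    the slope magnitude remains below threshold for ``min_dwell`` seconds and
    extends to the end of the step.
    """
    t, _, q = trace.step_arrays(step_index)
    dt = float(np.median(np.diff(t)))
    m = max(2, int(round(criterion.window / dt)) + 1)
    if m > len(t):
        return None
    centers, slopes = _sliding_slopes(t, q, m)
    below = np.abs(slopes) * 60.0 < criterion.slope_threshold  # per-min units
    if not below.any():
        return None
    # runs of consecutive below-threshold windows
    padded = np.diff(np.concatenate(([0], below.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)  # exclusive
    t_end = float(t[-1])
    for s, e in zip(starts, ends):
        run_end = centers[e - 1]
        # the dwell must be satisfied within the run unless it reaches the
        # end of the step (nothing left to contradict steadiness)
        if run_end - centers[s] >= criterion.min_dwell or e == len(below):
            return float(centers[s]), t_end
    return None


@dataclass(frozen=True)
class StepSummary:
    """Steady-state summary of one pressure step."""

    step_index: int
    p_ss: float                     # mmHg
    q_ss: float                     # nl/min
    c_step: float                   # nl/min/mmHg
    ci95: tuple[float, float]
    steady_window: tuple[float, float]
    n_samples: int = 0

    @property
    def se_c(self) -> float:
        return (self.ci95[1] - self.ci95[0]) / 2.0


def summarize_step(
    trace: PerfusionTrace, step_index: int, steady_window: tuple[float, float]
) -> StepSummary:
    """Mean pressure/flow over the steady window and the per-step facility."""
    t, p, q = trace.step_arrays(step_index)
    mask = (t >= steady_window[0]) & (t <= steady_window[1])
    if mask.sum() < 2:
        raise ValueError("steady window contains fewer than 2 samples")
    p_ss = float(p[mask].mean())
    q_ss = float(q[mask].mean())
    if p_ss <= 0:
        raise ValueError(f"non-positive steady pressure in step {step_index}")
    n = int(mask.sum())
    se_q = float(q[mask].std(ddof=1)) / math.sqrt(n)
    half = sps.t.ppf(0.975, n - 1) * se_q / p_ss
    c = q_ss / p_ss
    return StepSummary(
        step_index=step_index,
        p_ss=p_ss,
        q_ss=q_ss,
        c_step=c,
        ci95=(c - half, c + half),
        steady_window=steady_window,
        n_samples=n,
    )


@dataclass
class FacilityFit:
    """Power-law facility model C(P) = Cr * (P/Pr)**beta for one eye."""

    cr: float                      # nl/min/mmHg at the reference pressure
    beta: float                    # dimensionless nonlinearity
    pr: float = 8.0                # mmHg
    eye_id: str | None = None
    logcr_se: float = 0.0
    beta_se: float = 0.0
    ci95_cr: tuple[float, float] = (float("nan"), float("nan"))
    n_steps_used: int = 0
    fit_residual_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.cr <= 0:
            raise ValueError("Cr must be positive")
        if self.pr <= 0:
            raise ValueError("Pr must be positive")

    def facility_at(self, pressure: float) -> float:
        """C(P) evaluated from the fitted power law."""
        return self.cr * (pressure / self.pr) ** self.beta

    def with_reference(self, pr_new: float) -> "FacilityFit":
        """Re-express the same fitted curve at a different reference pressure."""
        return FacilityFit(
            cr=self.facility_at(pr_new),
            beta=self.beta,
            pr=pr_new,
            eye_id=self.eye_id,
            logcr_se=self.logcr_se,
            beta_se=self.beta_se,
            n_steps_used=self.n_steps_used,
            fit_residual_variance=self.fit_residual_variance,
        )


@dataclass(frozen=True)
class FacilityFailure:
    """Marker for an eye whose perfusion could not be analyzed."""

    eye_id: str
    reason: str


class InsufficientStepsError(ValueError):
    pass


def fit_power_law(
    steps: list[StepSummary],
    pr: float = 8.0,
    weights: np.ndarray | None = None,
) -> FacilityFit:
    """Log-space least-squares fit of the facility power law.

    ln C = ln Cr + beta * (ln P - ln Pr).  Unweighted by default; pass
    ``weights`` (e.g. inverse per-step variances) for a weighted fit.
    Requires at least 3 usable steps with positive facility.
    """
    usable = [s for s in steps if s.c_step > 0 and s.p_ss > 0]
    if len(usable) < 3:
        raise InsufficientStepsError(
            f"power-law fit needs >= 3 usable steps, got {len(usable)}"
        )
    x = np.log([s.p_ss for s in usable]) - math.log(pr)
    y = np.log([s.c_step for s in usable])
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    n, k = len(x), 2
    dof = n - k
    s2 = float(w @ resid**2) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
    logcr_se = math.sqrt(max(cov[0, 0], 0.0))
    beta_se = math.sqrt(max(cov[1, 1], 0.0))
    tcrit = sps.t.ppf(0.975, dof) if dof > 0 else float("nan")
    cr = math.exp(coef[0])
    ci = (cr * math.exp(-tcrit * logcr_se), cr * math.exp(tcrit * logcr_se))
    return FacilityFit(
        cr=cr,
        beta=float(coef[1]),
        pr=pr,
        logcr_se=logcr_se,
        beta_se=beta_se,
        ci95_cr=ci,
        n_steps_used=n,
        fit_residual_variance=s2,
    )


def facility_for_eye(
    trace: PerfusionTrace,
    criterion: SteadyStateCriterion = SteadyStateCriterion(),
    pr: float = 8.0,
) -> FacilityFit | FacilityFailure:
    """Full per-eye analysis: steady-state detection, step summary, model fit.

    Steps that never settle are dropped; eyes with fewer than 3 settled steps
    (or flagged unusable) yield a ``FacilityFailure`` so cohort pipelines can
    count exclusions instead of aborting.
    """
    if not trace.usable:
        return FacilityFailure(trace.eye_id, "unusable")
    summaries = []
    for k in range(trace.n_steps):
        win = detect_steady_window(trace, k, criterion)
        if win is None:
            continue
        try:
            summaries.append(summarize_step(trace, k, win))
        except ValueError:
            continue
    try:
        fit = fit_power_law(summaries, pr=pr)
    except InsufficientStepsError:
        return FacilityFailure(trace.eye_id, "failed_perfusion")
    fit.eye_id = trace.eye_id
    return fit
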