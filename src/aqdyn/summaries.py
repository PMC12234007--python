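"""Per-eye IOP reduction and per-cohort outcome summaries.

IOP per eye is the arithmetic mean of all eight rebound-tonometer readings
(no trimming of extremes).  Cohort summaries report the arithmetic mean with
a t-based 95% CI for IOP and cellularity, and the geometric mean with a
log-scale t-based CI for outflow facility (facility is log-normally
distributed, so all facility statistics are computed on ln values and
back-transformed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

N_READINGS = 8


@dataclass(frozen=True)
class EyeIOP:
    eye_id: str
    readings: tuple[float, ...]
    iop: float  # mmHg, mean of all readings


def eye_iop(readings, eye_id: str = "") -> EyeIOP:
    """Average all eight tonometer readings into one per-eye IOP."""
    r = np.asarray(readings, dtype=float)
    if r.size != N_READINGS:
        raise ValueError(f"expected {N_READINGS} readings, got {r.size}")
    if np.any(r <= 0):
        raise ValueError("tonometer readings must be positive")
    return EyeIOP(eye_id=eye_id, readings=tuple(r), iop=float(r.mean()))


def t_ci(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """t-based CI on the mean (degenerate when the sample variance is zero)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    m = float(v.mean())
    if n < 2:
        return (m, m)
    half = sps.t.ppf(1 - alpha / 2, n - 1) * float(v.std(ddof=1)) / math.sqrt(n)
    return (m - half, m + half)


@dataclass
class GroupSummary:
    """Cohort-level outcome summary (the shape of the published table)."""

    group: str
    timepoint: str
    n_eyes: int
    iop_mean: float
    iop_ci: tuple[float, float]
    facility_geomean: float | None = None
    facility_ci: tuple[float, float] | None = None
    cellularity_mean: float | None = None
    cellularity_ci: tuple[float, float] | None = None
    n_facility: int = 0
    facility_beta: float = 0.0      # cohort-mean power-law exponent
    facility_logcr_se: float = 0.0  # SE of the mean ln facility

    @property
    def label(self) -> str:
        from .tables import group_label

        return group_label(self.group, self.timepoint)


def summarize_group(
    group: str,
    timepoint: str,
    iops,
    facilities=None,
    cellularities=None,
    betas=None,
) -> GroupSummary:
    """Summarize one cohort.

    Eyes with failed perfusion contribute to the IOP summary but are absent
    from ``facilities``, so the facility n may be smaller than the IOP n.
    """
    iops = np.asarray(iops, dtype=float)
    if iops.size == 0:
        raise ValueError(f"empty group {group}/{timepoint}")
    out = GroupSummary(
        group=group,
        timepoint=timepoint,
        n_eyes=int(iops.size),
        iop_mean=float(iops.mean()),
        iop_ci=t_ci(iops),
    )
    if facilities is not None and len(facilities) > 0:
        fac = np.asarray(facilities, dtype=float)
        if np.any(fac <= 0):
            raise ValueError("facility values must be positive")
        logs = np.log(fac)
        lo, hi = t_ci(logs)
        out.facility_geomean = float(np.exp(logs.mean()))
        out.facility_ci = (float(np.exp(lo)), float(np.exp(hi)))
        out.n_facility = int(fac.size)
        out.facility_logcr_se = (
            float(logs.std(ddof=1)) / math.sqrt(fac.size) if fac.size > 1 else 0.0
        )
        if betas is not None and len(betas) > 0:
            out.facility_beta = float(np.mean(betas))
    if cellularities is not None and len(cellularities) > 0:
        cell = np.asarray(cellularities, dtype=float)
        out.cellularity_mean = float(cell.mean())
        out.cellularity_ci = t_ci(cell)
    return out


def summary_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Flatten cohort summaries into the published-table shape."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "group": s.group,
                "timepoint": s.timepoint,
                "n": s.n_eyes,
                "iop": s.iop_mean,
                "iop_lo": s.iop_ci[0],
                "iop_hi": s.iop_ci[1],
                "facility": s.facility_geomean,
                "fac_lo": s.facility_ci[0] if s.facility_ci else None,
                "fac_hi": s.facility_ci[1] if s.facility_ci else None,
                "cellularity": s.cellularity_mean,
                "cell_lo": s.cellularity_ci[0] if s.cellularity_ci else None,
                "cell_hi": s.cellularity_ci[1] if s.cellularity_ci else None,
            }
        )
    return pd.DataFrame(rows)
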