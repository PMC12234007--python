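"""Published cohort summaries used to calibrate and cross-check the pipeline.

The study measured three outcomes (IOP by rebound tonometry, conventional
outflow facility by ex vivo perfusion, and trabecular-meshwork cellular
density) in ten mouse cohorts: naive wild-type (WT), transgenic MYOC-Y437H
(Tg), saline-injected controls (sham) and two stem-cell treatment arms
(hAMSC, iPSC-TM) followed at short / mid / long time points.  The printed
group means and 95% confidence intervals below are treated as *inputs*: they
calibrate the synthetic cohort generator and feed the desk-arithmetic effect
calculations (treatment differences, fold-ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Canonical (group, timepoint) labels, in study order.
STUDY_GROUPS: list[tuple[str, str]] = [
    ("WT", "baseline"),
    ("Tg", "baseline"),
    ("sham", "short"),
    ("hAMSC", "short"),
    ("sham", "mid"),
    ("hAMSC", "mid"),
    ("sham", "long"),
    ("hAMSC", "long"),
    ("iPSC-TM", "short"),
    ("iPSC-TM", "mid"),
]


def group_label(group: str, timepoint: str) -> str:
    """Single-string cohort label, e.g. ``hAMSC_mid`` (``WT`` for baseline)."""
    if timepoint == "baseline":
        return group
    return f"{group}_{timepoint}"


# Outcome means and 95% CI bounds per cohort:
# IOP (mmHg), outflow facility (nl/min/mmHg), cellular density (nuclei/um).
_TABLE1_ROWS = [
    # group, timepoint, iop, lo, hi, facility, lo, hi, cellularity, lo, hi
    ("WT", "baseline", 15.6, 14.8, 16.3, 4.4, 3.7, 5.2, 0.24, 0.15, 0.33),
    ("Tg", "baseline", 15.4, 14.7, 16.1, 3.8, 3.3, 4.4, 0.28, 0.23, 0.32),
    ("sham", "short", 17.1, 16.0, 18.1, 3.2, 2.3, 4.3, 0.27, 0.20, 0.34),
    ("hAMSC", "short", 12.8, 11.9, 13.8, 8.4, 6.3, 11.2, 0.58, 0.42, 0.73),
    ("sham", "mid", 16.9, 15.5, 18.2, 3.0, 2.1, 4.3, 0.24, 0.18, 0.31),
    ("hAMSC", "mid", 12.4, 11.6, 13.2, 8.4, 7.1, 9.9, 0.40, 0.34, 0.47),
    ("sham", "long", 16.7, 16.0, 17.5, 3.4, 2.8, 4.2, 0.23, 0.17, 0.28),
    ("hAMSC", "long", 12.2, 11.0, 13.3, 8.0, 5.9, 10.9, 0.37, 0.31, 0.43),
    ("iPSC-TM", "short", 14.8, 14.0, 15.6, 4.3, 3.0, 6.2, 0.36, 0.27, 0.45),
    ("iPSC-TM", "mid", 15.0, 14.3, 15.7, 4.3, 3.6, 5.1, 0.34, 0.21, 0.47),
]

OUTCOME_TABLE: pd.DataFrame = pd.DataFrame(
    _TABLE1_ROWS,
    columns=[
        "group", "timepoint",
        "iop", "iop_lo", "iop_hi",
        "facility", "fac_lo", "fac_hi",
        "cellularity", "cell_lo", "cell_hi",
    ],
)
OUTCOME_TABLE.insert(
    0, "label",
    [group_label(g, t) for g, t in zip(OUTCOME_TABLE["group"], OUTCOME_TABLE["timepoint"])],
)

# Basement-membrane-material normalized length (fraction of Schlemm's canal
# inner wall in contact with BMM), quantified for the mid-term arms only.
BMM_TABLE: pd.DataFrame = pd.DataFrame(
    [
        ("sham_mid", 0.52, 0.34, 0.70),
        ("hAMSC_mid", 0.34, 0.22, 0.47),
    ],
    columns=["label", "bmm", "bmm_lo", "bmm_hi"],
)

# The 20 pre-specified pairwise comparisons (family alpha 0.05, Bonferroni
# critical p 0.05/20 = 0.0025).  Row 7 of the published table repeats the
# "Tg vs hAMSC mid" pair of row 6; it is shipped here as the otherwise-missing
# Tg vs hAMSC long comparison.
PLANNED_PAIRS: list[tuple[str, str]] = [
    ("WT", "Tg"),
    ("Tg", "sham_short"),
    ("Tg", "sham_mid"),
    ("Tg", "sham_long"),
    ("Tg", "hAMSC_short"),
    ("Tg", "hAMSC_mid"),
    ("Tg", "hAMSC_long"),
    ("Tg", "iPSC-TM_short"),
    ("Tg", "iPSC-TM_mid"),
    ("sham_short", "hAMSC_short"),
    ("sham_short", "iPSC-TM_short"),
    ("hAMSC_short", "hAMSC_mid"),
    ("hAMSC_short", "hAMSC_long"),
    ("hAMSC_short", "iPSC-TM_short"),
    ("sham_mid", "hAMSC_mid"),
    ("sham_mid", "iPSC-TM_mid"),
    ("hAMSC_mid", "hAMSC_long"),
    ("hAMSC_mid", "iPSC-TM_mid"),
    ("sham_long", "hAMSC_long"),
    ("iPSC-TM_short", "iPSC-TM_mid"),
]


@dataclass(frozen=True)
class PublishedGroup:
    """Printed outcome means for one cohort, with CI-implied eye-level SDs."""

    label: str
    group: str
    timepoint: str
    iop: float
    iop_sd: float
    facility: float          # geometric mean, nl/min/mmHg
    facility_log_sd: float   # SD of ln facility implied by the CI
    cellularity: float
    cellularity_sd: float


def _ci_to_sd(half_width: float, n: int) -> float:
    """Eye-level SD implied by a t-based 95% CI half-width at sample size n."""
    return half_width * np.sqrt(n) / sps.t.ppf(0.975, n - 1)


def published_groups(n_eyes: int = 10) -> dict[str, PublishedGroup]:
    """Printed means with SDs back-calculated from the CI half-widths.

    The per-panel sample sizes are not in the running text; ``n_eyes``
    defaults to 10 eyes per cohort (10 cohorts against the 114 eyes randomly
    chosen for perfusion).
    """
    out: dict[str, PublishedGroup] = {}
    for row in OUTCOME_TABLE.itertuples(index=False):
        iop_hw = (row.iop_hi - row.iop_lo) / 2.0
        # facility CI is symmetric on the log scale
        fac_log_hw = (np.log(row.fac_hi) - np.log(row.fac_lo)) / 2.0
        cell_hw = (row.cell_hi - row.cell_lo) / 2.0
        out[row.label] = PublishedGroup(
            label=row.label,
            group=row.group,
            timepoint=row.timepoint,
            iop=row.iop,
            iop_sd=_ci_to_sd(iop_hw, n_eyes),
            facility=row.facility,
            facility_log_sd=_ci_to_sd(fac_log_hw, n_eyes),
            cellularity=row.cellularity,
            cellularity_sd=_ci_to_sd(cell_hw, n_eyes),
        )
    return out
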