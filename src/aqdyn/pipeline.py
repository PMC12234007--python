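"""End-to-end study pipeline over a synthetic (or same-shaped real) cohort.

Order of stages: cohort generation -> per-eye facility fitting (with
exclusion of failed perfusions) -> tonometry reduction -> cohort summaries ->
Goldmann Q calibration from the reference group -> expected-IOP
cross-validation -> morphometry indices and mixed models -> the planned
comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import goldmann, morphometry, stats, summaries, synth, tables
from .perfusion import FacilityFailure, FacilityFit, SteadyStateCriterion, facility_for_eye


@dataclass
class StudyResult:
    config: synth.SyntheticConfig
    eyes: list[synth.TrueEyeState]
    facility: dict[str, FacilityFit | FacilityFailure]
    eye_iops: dict[str, float]
    morpho_records: list
    group_summaries: dict[str, summaries.GroupSummary]
    params: goldmann.GoldmannParams
    crossval: goldmann.CrossValReport
    beta_mode: str
    eye_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_excluded(self) -> int:
        return sum(1 for f in self.facility.values() if isinstance(f, FacilityFailure))


def run_study(
    config: synth.SyntheticConfig,
    beta_mode: str = "fitted",
    reference: str = "WT",
    criterion: SteadyStateCriterion = SteadyStateCriterion(),
) -> StudyResult:
    """Run every stage of the analysis on one synthetic study.

    ``beta_mode`` selects the group-level power-law exponent used in the
    Goldmann cross-validation: "fitted" (cohort mean of per-eye fitted betas)
    or "zero" (constant facility, the printed-table arithmetic).
    """
    if beta_mode not in ("fitted", "zero"):
        raise ValueError("beta_mode must be 'fitted' or 'zero'")
    eyes = synth.generate_cohort(config)
    facility: dict[str, FacilityFit | FacilityFailure] = {}
    eye_iops: dict[str, float] = {}
    morpho_records = []
    rows = []
    for eye in eyes:
        trace = synth.generate_perfusion_trace(eye, config)
        fit = facility_for_eye(trace, criterion=criterion, pr=config.pr)
        facility[eye.eye_id] = fit
        iop = summaries.eye_iop(synth.generate_tonometry(eye, config), eye.eye_id).iop
        eye_iops[eye.eye_id] = iop
        morpho_records.extend(synth.generate_morphometry(eye, config))
        ok = isinstance(fit, FacilityFit)
        rows.append(
            {
                "eye_id": eye.eye_id,
                "label": eye.label,
                "group": eye.group,
                "time_point": eye.timepoint,
                "iop": iop,
                "cr": fit.cr if ok else np.nan,
                "beta": fit.beta if ok else np.nan,
                "status": "ok" if ok else fit.reason,
                "cr_true": eye.cr_true,
                "iop_true": eye.iop_true,
            }
        )
    eye_table = pd.DataFrame(rows)

    cell_by_eye = _eye_level_cellularity(morpho_records)
    group_summaries: dict[str, summaries.GroupSummary] = {}
    for spec in config.groups:
        lbl = spec.label
        sub = eye_table[eye_table["label"] == lbl]
        fits = sub[sub["status"] == "ok"]
        group_summaries[lbl] = summaries.summarize_group(
            spec.group,
            spec.timepoint,
            sub["iop"].to_numpy(),
            facilities=fits["cr"].to_numpy(),
            cellularities=[cell_by_eye[e] for e in sub["eye_id"] if e in cell_by_eye],
            betas=fits["beta"].to_numpy(),
        )

    params = goldmann.calibrate_q(
        group_summaries[reference],
        pe=config.pe,
        beta=0.0 if beta_mode == "zero" else None,
    )
    results = []
    for lbl, gs in group_summaries.items():
        if gs.facility_geomean is None:
            continue
        beta = 0.0 if beta_mode == "zero" else gs.facility_beta
        fit = FacilityFit(cr=gs.facility_geomean, beta=beta, pr=config.pr)
        fit.logcr_se = gs.facility_logcr_se
        exp_iop = goldmann.expected_iop(params, fit)
        lo, hi, _ = goldmann.propagate_expected_iop_ci(params, fit)
        results.append(
            goldmann.ExpectedIOPResult(
                label=lbl,
                expected_iop=exp_iop,
                expected_ci=(lo, hi),
                experimental_iop=gs.iop_mean,
                experimental_ci=gs.iop_ci,
                facility_used=gs.facility_geomean,
                beta_used=beta,
            )
        )
    report = goldmann.crossval_report(results)
    return StudyResult(
        config=config,
        eyes=eyes,
        facility=facility,
        eye_iops=eye_iops,
        morpho_records=morpho_records,
        group_summaries=group_summaries,
        params=params,
        crossval=report,
        beta_mode=beta_mode,
        eye_table=eye_table,
    )


def _eye_level_cellularity(records) -> dict[str, float]:
    """Mean section density per eye (the unit used for pooled correlations)."""
    per_eye: dict[str, list[float]] = {}
    for r in records:
        if r.nuclei_count is not None:
            per_eye.setdefault(r.eye_id, []).append(morphometry.cellularity_density(r))
    return {e: float(np.mean(v)) for e, v in per_eye.items()}


def cellularity_iop_pairs(result: StudyResult) -> np.ndarray:
    """Pooled per-eye (cellularity, IOP) pairs across all cohorts."""
    cell = _eye_level_cellularity(result.morpho_records)
    pairs = [
        (cell[e], result.eye_iops[e]) for e in result.eye_iops if e in cell
    ]
    return np.asarray(pairs)


def planned_comparisons(result: StudyResult) -> pd.DataFrame:
    """The 20-comparison table for IOP and facility (Welch contrasts after
    ANOVA, facility on the log scale), Bonferroni critical p = 0.0025."""
    frames = []
    et = result.eye_table
    iop_by_group = {
        lbl: et[et["label"] == lbl]["iop"].to_numpy()
        for lbl in et["label"].unique()
    }
    ok = et[et["status"] == "ok"]
    fac_by_group = {
        lbl: ok[ok["label"] == lbl]["cr"].to_numpy()
        for lbl in ok["label"].unique()
    }
    res_iop = stats.anova_with_posthoc(iop_by_group, stats.default_plan("iop"))
    res_fac = stats.anova_with_posthoc(
        fac_by_group, stats.default_plan("facility"), log_scale=True
    )
    frames = [res_iop.effects, res_fac.effects]
    return pd.concat(frames, ignore_index=True)
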