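"""Trabecular-meshwork morphometry indices and nested mixed-effects inference.

Two indices are computed from sectioned tissue:

* cellular density — DAPI-stained nuclei counted in the TM, normalized by the
  length of the inner wall (IW) of Schlemm's canal adjacent to the counted
  region (nuclei/um);
* BMM normalized length — the summed length of basement-membrane-material
  segments in direct contact with the IW divided by the total IW length
  (dimensionless, in [0, 1]); measured by two masked annotators.

Group comparisons use a linear mixed model with the cohort as fixed effect
and random intercepts for eye (and annotator for BMM; section-within-eye when
identifiable, i.e. when sections are measured more than once).  Estimation is
REML through statsmodels MixedLM with variance components, which also
supports the crossed annotator effect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "MorphometryRecord",
    "MixedModelResult",
    "cellularity_density",
    "bmm_normalized_length",
    "records_to_frame",
    "mixed_effects_compare",
    "annotator_agreement_lrt",
]


@dataclass(frozen=True)
class MorphometryRecord:
    """One section-level observation (per annotator for BMM)."""

    eye_id: str
    section_id: str
    group: str | None = None
    annotator_id: str | None = None
    nuclei_count: int | None = None
    iw_length: float | None = None                 # um, cellularity normalizer
    bmm_contact_lengths: tuple[float, ...] | None = None  # um
    iw_total: float | None = None                  # um, BMM normalizer

    def __post_init__(self) -> None:
        if self.nuclei_count is not None and self.nuclei_count < 0:
            raise ValueError("nuclei_count must be non-negative")
        if self.iw_length is not None and self.iw_length <= 0:
            raise ValueError("iw_length must be positive")
        if self.bmm_contact_lengths is not None:
            if any(s < 0 for s in self.bmm_contact_lengths):
                raise ValueError("BMM segment lengths must be non-negative")
            if self.iw_total is None or self.iw_total <= 0:
                raise ValueError("BMM records need a positive iw_total")
            if sum(self.bmm_contact_lengths) > self.iw_total * (1 + 1e-9):
                raise ValueError("BMM contact exceeds total inner-wall length")


def cellularity_density(record: MorphometryRecord) -> float:
    """Nuclei per micron of Schlemm's canal inner wall."""
    if record.nuclei_count is None or record.iw_length is None:
        raise ValueError("record carries no cellularity measurement")
    return record.nuclei_count / record.iw_length


def bmm_normalized_length(record: MorphometryRecord) -> float:
    """Fraction of the inner wall in direct contact with BMM, in [0, 1]."""
    if record.bmm_contact_lengths is None:
        raise ValueError("record carries no BMM measurement")
    return min(sum(record.bmm_contact_lengths) / record.iw_total, 1.0)


def records_to_frame(records: list[MorphometryRecord], index_kind: str) -> pd.DataFrame:
    """Long-format observation table for one index ('cellularity' or 'bmm')."""
    rows = []
    for r in records:
        if index_kind == "cellularity" and r.nuclei_count is not None:
            rows.append((r.group, r.eye_id, r.section_id, "", cellularity_density(r)))
        elif index_kind == "bmm" and r.bmm_contact_lengths is not None:
            rows.append(
                (r.group, r.eye_id, r.section_id, r.annotator_id or "", bmm_normalized_length(r))
            )
    df = pd.DataFrame(rows, columns=["group", "eye", "section", "annotator", "value"])
    df["eye_section"] = df["eye"] + ":" + df["section"]
    return df


@dataclass
class MixedModelResult:
    index_kind: str
    group_means: dict[str, float]
    contrasts: pd.DataFrame = field(repr=False)
    variance_components: dict[str, float] = field(default_factory=dict)
    residual_variance: float = 0.0
    corrected_alpha: float = 0.05
    converged: bool = True


def _vc_formulas(df: pd.DataFrame, index_kind: str) -> dict[str, str]:
    vc = {"eye": "0 + C(eye)"}
    # section-within-eye is identifiable only when a section is observed more
    # than once (as with two annotators); otherwise it is the residual
    if df.groupby("eye_section").size().max() > 1:
        vc["section"] = "0 + C(eye_section)"
    if index_kind == "bmm" and df["annotator"].nunique() > 1:
        # identical annotations pin the annotator variance at exactly zero;
        # keeping the component would only let the optimizer wander the
        # singular boundary
        spread = df.groupby("eye_section")["value"].agg(lambda v: v.max() - v.min())
        if float(spread.max()) > 0.0:
            vc["annotator"] = "0 + C(annotator)"
    return vc


def _fit_mixed(df: pd.DataFrame, vc: dict[str, str]):
    df = df.assign(_one=1.0)
    model = sm.MixedLM.from_formula(
        "value ~ 0 + C(group)", groups="_one", vc_formula=vc, data=df
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=True, method=["lbfgs", "powell"])


def mixed_effects_compare(
    records: list[MorphometryRecord],
    index_kind: str,
    contrasts: list[tuple[str, str]],
    family_alpha: float = 0.05,
) -> MixedModelResult:
    """Fixed-effect group comparison with nested/crossed random effects.

    Returns contrast estimates with Wald 95% CIs, p-values against the
    Bonferroni-corrected alpha (family_alpha / number of contrasts), and the
    estimated variance components (clipped at zero by the optimizer).
    """
    df = records_to_frame(records, index_kind)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 cohorts to compare")
    if df.groupby("group")["eye"].nunique().min() < 2:
        raise ValueError(
            "unidentifiable design: a cohort with a single eye confounds the "
            "eye random effect with the cohort fixed effect"
        )
    corrected = family_alpha / len(contrasts)

    if float(df["value"].var(ddof=0)) == 0.0:
        # degenerate data: all variance components and contrasts are zero
        means = {g: float(df[df.group == g]["value"].iloc[0]) for g in groups}
        rows = [
            {"a": a, "b": b, "estimate": means[a] - means[b], "se": 0.0,
             "ci_lo": means[a] - means[b], "ci_hi": means[a] - means[b],
             "p": 1.0 if means[a] == means[b] else 0.0,
             "significant": means[a] != means[b]}
            for a, b in contrasts
        ]
        return MixedModelResult(
            index_kind=index_kind,
            group_means=means,
            contrasts=pd.DataFrame(rows),
            variance_components={k: 0.0 for k in _vc_formulas(df, index_kind)},
            residual_variance=0.0,
            corrected_alpha=corrected,
        )

    vc = _vc_formulas(df, index_kind)
    res = _fit_mixed(df, vc)
    names = list(res.model.exog_names)
    params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(names), : len(names)]
    means = {g: float(params[names.index(f"C(group)[{g}]")]) for g in groups}

    rows = []
    for a, b in contrasts:
        vec = np.zeros(len(names))
        vec[names.index(f"C(group)[{a}]")] = 1.0
        vec[names.index(f"C(group)[{b}]")] = -1.0
        est = float(vec @ params)
        se = float(math.sqrt(max(vec @ cov @ vec, 0.0)))
        z = est / se if se > 0 else (0.0 if est == 0 else math.inf)
        p = 2 * sps.norm.sf(abs(z))
        rows.append(
            {
                "a": a, "b": b, "estimate": est, "se": se,
                "ci_lo": est - 1.96 * se, "ci_hi": est + 1.96 * se,
                "p": p, "significant": p < corrected,
            }
        )
    vcomp = {k: max(float(v), 0.0) for k, v in zip(vc, res.vcomp)}
    if index_kind == "bmm" and df["annotator"].nunique() > 1:
        vcomp.setdefault("annotator", 0.0)
    return MixedModelResult(
        index_kind=index_kind,
        group_means=means,
        contrasts=pd.DataFrame(rows),
        variance_components=vcomp,
        residual_variance=float(res.scale),
        corrected_alpha=corrected,
        converged=bool(res.converged),
    )


def annotator_agreement_lrt(records: list[MorphometryRecord]) -> tuple[float, float]:
    """Likelihood-ratio test of the annotator variance component (BMM).

    Compares the REML likelihood of the model with vs. without the annotator
    random effect (identical fixed effects).  Because the null puts the
    variance on the boundary, p comes from the 0.5*chi2(0) + 0.5*chi2(1)
    mixture.  Returns (statistic, p).
    """
    df = records_to_frame(records, "bmm")
    if df["annotator"].nunique() < 2:
        raise ValueError("annotator agreement needs at least 2 annotators")
    # identical annotations leave literally nothing for the annotator effect
    spread = df.groupby("eye_section")["value"].agg(lambda v: v.max() - v.min())
    if float(spread.max()) == 0.0:
        return 0.0, 1.0
    vc_full = _vc_formulas(df, "bmm")
    vc_null = {k: v for k, v in vc_full.items() if k != "annotator"}
    full = _fit_mixed(df, vc_full)
    null = _fit_mixed(df, vc_null)
    stat = max(2.0 * (full.llf - null.llf), 0.0)
    p = 1.0 if stat == 0.0 else 0.5 * float(sps.chi2.sf(stat, 1))
    return stat, p
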