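"""The cohort statistics plan on the synthetic study.

Normality screening (Shapiro-Wilk; facility after log transform), one-way
ANOVA with the 20 pre-specified Bonferroni comparisons (critical p 0.0025),
treatment effects against the matching injection controls (differences for
IOP, fold-ratios for facility), and the pooled cellularity-IOP correlation.
Closes with the headline arithmetic recomputed from the published table.
"""

import sys
from pathlib import Path

import pandas as pd

from aqdyn import pipeline, stats, synth

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    cfg = synth.SyntheticConfig.from_study_defaults(
        n_eyes=6, master_seed=SEED, failure_rate=9 / 114
    )
    cfg.step_duration = 180.0
    res = pipeline.run_study(cfg)
    et = res.eye_table
    ok = et[et["status"] == "ok"]

    fac_by_group = {l: g["cr"].to_numpy() for l, g in ok.groupby("label")}
    normality = stats.normality_screen(fac_by_group, log_transform=True)
    print("Shapiro-Wilk on ln facility (p-values):")
    print("  " + ", ".join(f"{k}={v:.2f}" for k, v in normality.items()))

    comparisons = pipeline.planned_comparisons(res)
    RESULTS.mkdir(exist_ok=True)
    comparisons.to_csv(RESULTS / "planned_comparisons.tsv", sep="\t", index=False)
    n_sig = int(comparisons["significant"].sum())
    print(f"\n{len(comparisons)} planned contrasts (IOP + facility), "
          f"{n_sig} significant at the corrected alpha 0.0025")

    effects = []
    for treated, control, tp in (
        ("hAMSC_short", "sham_short", "short"),
        ("hAMSC_mid", "sham_mid", "mid"),
        ("hAMSC_long", "sham_long", "long"),
        ("iPSC-TM_short", "sham_short", "short"),
        ("iPSC-TM_mid", "sham_mid", "mid"),
    ):
        iop = stats.treatment_effect(
            et[et.label == treated]["iop"], et[et.label == control]["iop"],
            "iop", treated, control,
        )
        fac = stats.treatment_effect(
            ok[ok.label == treated]["cr"], ok[ok.label == control]["cr"],
            "facility", treated, control,
        )
        effects.append(
            {
                "treated": treated, "control": control, "timepoint": tp,
                "iop_diff_mmHg": iop.effect, "iop_lo": iop.ci95[0], "iop_hi": iop.ci95[1],
                "facility_fold": fac.effect, "fac_lo": fac.ci95[0], "fac_hi": fac.ci95[1],
            }
        )
    eff = pd.DataFrame(effects)
    eff.to_csv(RESULTS / "treatment_effects.tsv", sep="\t", index=False)
    print("\ntreatment effects vs. injection controls:")
    print(eff.round(2).to_string(index=False))

    r, p = stats.cellularity_iop_correlation(pipeline.cellularity_iop_pairs(res))
    print(f"\npooled cellularity-IOP Pearson r = {r:.2f} (p = {p:.2g})")

    print("\nheadline arithmetic from the published table:")
    for k, v in stats.published_headline_effects().items():
        print(f"  {k}: {v:.3g}")


if __name__ == "__main__":
    main()
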