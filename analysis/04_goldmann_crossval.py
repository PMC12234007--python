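"""Cross-validate measured IOP against outflow facility via the Goldmann balance.

The pressure-independent inflow Q is calibrated from the WT cohort's summary
(Q = C * (IOP - Pe), Pe = 7 mmHg, facility adjusted to the cohort's own
pressure drop via the power law), then an expected IOP is solved for every
cohort from its facility.  Residuals (experimental minus expected), the
experimental-on-expected regression and Bland-Altman coordinates quantify
the agreement.  Both exponent modes are reported: beta = 0 (constant
facility) and the cohort-mean fitted beta.
"""

import json
import subprocess
import sys
from pathlib import Path

from aqdyn import pipeline, synth

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    cfg = synth.SyntheticConfig.from_study_defaults(
        n_eyes=6, master_seed=SEED, failure_rate=9 / 114
    )
    cfg.step_duration = 180.0
    RESULTS.mkdir(exist_ok=True)
    report = {}
    for mode in ("zero", "fitted"):
        res = pipeline.run_study(cfg, beta_mode=mode)
        cv = res.crossval
        cv.per_group.to_csv(RESULTS / f"crossval_{mode}.tsv", sep="\t", index=False)
        report[mode] = {
            "Q_nl_min": res.params.q,
            "mean_residual_mmHg": cv.mean_residual,
            "residual_ci": list(cv.residual_ci),
            "residual_p": cv.residual_t_test_p,
            "slope": cv.regression_slope,
            "intercept": cv.regression_intercept,
            "r_squared": cv.r_squared,
            "slope_vs_unity_p": cv.slope_vs_unity_p,
        }
        print(f"beta mode '{mode}': Q = {res.params.q:.2f} nl/min, "
              f"mean residual {cv.mean_residual:+.2f} "
              f"[{cv.residual_ci[0]:+.2f}, {cv.residual_ci[1]:+.2f}] mmHg, "
              f"slope {cv.regression_slope:.2f}, R^2 {cv.r_squared:.3f}")
    (RESULTS / "crossval_report.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {RESULTS / 'crossval_report.json'}")


if __name__ == "__main__":
    main()
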