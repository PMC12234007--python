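"""Reduce tonometry and facility fits to the cohort summary table.

Per-eye IOP is the mean of all eight tonometer readings; cohort IOP and
cellularity are arithmetic means with t-based 95% CIs; facility is the
geometric mean with a log-scale CI.  Eyes excluded from perfusion still
contribute to the IOP column, so facility n can be smaller.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from aqdyn import summaries
from aqdyn.tables import OUTCOME_TABLE, group_label

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    if not (RESULTS / "facility_fits.tsv").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "02_fit_facility.py")], check=True)
    manifest = pd.read_csv(COHORT / "manifest.tsv", sep="\t")
    tono = pd.read_csv(COHORT / "tonometry.tsv", sep="\t")
    fits = pd.read_csv(RESULTS / "facility_fits.tsv", sep="\t")
    morpho = pd.read_csv(COHORT / "morphometry.tsv", sep="\t")

    reading_cols = [c for c in tono.columns if c.startswith("reading_")]
    iops = {
        r.eye_id: summaries.eye_iop([getattr(r, c) for c in reading_cols], r.eye_id).iop
        for r in tono.itertuples(index=False)
    }
    cell = (
        morpho[morpho["nuclei_count"].notna()]
        .assign(density=lambda d: d["nuclei_count"] / d["iw_length_um"])
        .groupby("eye_id")["density"].mean()
    )
    ok = fits[fits["status"] == "ok"].set_index("eye_id")

    out = []
    for (group, tp), sub in manifest.groupby(["group", "time_point"], sort=False):
        eyes = sub["eye_id"]
        out.append(
            summaries.summarize_group(
                group, tp,
                [iops[e] for e in eyes],
                facilities=ok.loc[ok.index.intersection(eyes), "Cr"].to_numpy(),
                cellularities=cell.loc[cell.index.intersection(eyes)].to_numpy(),
                betas=ok.loc[ok.index.intersection(eyes), "beta"].to_numpy(),
            )
        )
    table = summaries.summary_table(out)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "group_summaries.tsv", sep="\t", index=False)
    print(table.round(2).to_string(index=False))
    print("\ncalibration check (synthetic mean vs published mean):")
    pub = OUTCOME_TABLE.set_index("label")
    for s in out:
        row = pub.loc[group_label(s.group, s.timepoint)]
        print(f"  {s.label:>14}: IOP {s.iop_mean:5.1f} vs {row.iop:5.1f}  "
              f"facility {s.facility_geomean:4.1f} vs {row.facility:4.1f}")


if __name__ == "__main__":
    main()
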