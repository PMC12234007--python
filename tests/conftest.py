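import numpy as np
import pytest

from aqdyn import synth


@pytest.fixture(scope="session")
def wt_only_config():
    """Single noiseless wild-type cohort calibrated to the published row."""
    return synth.SyntheticConfig(
        groups=[synth.GroupSpec("WT", "baseline", 5)],
        facility_geomean={"WT": 4.4},
        facility_log_sd=0.0,
        beta_mean=0.0,
        beta_sd=0.0,
        q=37.84,
        pe=7.0,
        tonometer_sd=0.0,
        flow_noise_sd=0.0,
        transient_tau=0.0,
        cellularity_mean={"WT": 0.24},
        cellularity_sd=0.0,
        cellularity_section_sd=0.0,
        step_duration=120.0,
        master_seed=0,
    )


@pytest.fixture(scope="session")
def wt_eyes(wt_only_config):
    return synth.generate_cohort(wt_only_config)


def make_bmm_records(
    rng,
    n_eyes: int = 8,
    group_means=(("sham", 0.52), ("hAMSC", 0.34)),
    eye_sd: float = 0.08,
    section_sd: float = 0.05,
    annotator_sd: float = 0.0,
    residual_sd: float = 0.02,
    n_sections: int = 3,
    duplicate_annotators: bool = False,
):
    """Hand-rolled nested BMM records with known variance components."""
    from aqdyn.morphometry import MorphometryRecord

    records = []
    offsets = {"A1": rng.normal(0, annotator_sd), "A2": rng.normal(0, annotator_sd)}
    for group, mu in group_means:
        for e in range(n_eyes):
            eye = f"{group}_{e}"
            eye_level = mu + rng.normal(0, eye_sd)
            for s in range(n_sections):
                section_level = eye_level + rng.normal(0, section_sd)
                values = {
                    a: float(np.clip(section_level + offsets[a] + rng.normal(0, residual_sd), 0, 1))
                    for a in ("A1", "A2")
                }
                if duplicate_annotators:
                    values["A2"] = values["A1"]
                for a in ("A1", "A2"):
                    records.append(
                        MorphometryRecord(
                            eye_id=eye,
                            section_id=f"s{s}",
                            group=group,
                            annotator_id=a,
                            bmm_contact_lengths=(values[a] * 40.0,),
                            iw_total=40.0,
                        )
                    )
    return records
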