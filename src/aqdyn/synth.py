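"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator states a world in which every downstream stage of the pipeline
has a known ground truth:

* per-eye reference facility Cr is log-normal around the cohort geometric
  mean (facility in mice is log-normally distributed);
* the power-law exponent beta is Gaussian;
* true IOP is *derived* from true facility through the Goldmann balance
  (shared pressure-independent flow Q, episcleral venous pressure Pe), then
  shifted by a per-cohort offset that emulates the experimentally observed
  shift between measured and expected IOP;
* perfusion traces approach each step's steady inflow Cr*(P/Pr)**beta * P
  through a single-exponential transient with configurable time constant,
  plus Gaussian flow noise; a configurable fraction of perfusions fails;
* tonometry is 8 i.i.d. Gaussian readings around the true IOP;
* morphometry provides per-section nuclei counts / inner-wall lengths around
  the eye's true cellular density and per-section x annotator BMM contact
  ratios with annotator random offsets.

Randomness policy: one master seed; every eye (and every annotator offset)
draws from an independent substream keyed by a stable hash of its identifier,
so enlarging a cohort never perturbs previously generated eyes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tables
from .goldmann import GoldmannParams, expected_iop
from .morphometry import MorphometryRecord
from .perfusion import FacilityFit, PerfusionTrace, write_trace

__all__ = [
    "GroupSpec",
    "SyntheticConfig",
    "TrueEyeState",
    "generate_cohort",
    "generate_perfusion_trace",
    "generate_tonometry",
    "generate_morphometry",
    "write_cohort",
]

DEFAULT_STEP_PRESSURES = tuple(np.linspace(4.5, 16.5, 8))  # mmHg


def _stable_hash(label: str) -> int:
    """Deterministic 32-bit hash of an identifier (independent of PYTHONHASHSEED)."""
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")


def _substream(master_seed: int, label: str, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), _stable_hash(label), purpose])
    )


@dataclass(frozen=True)
class GroupSpec:
    group: str
    timepoint: str
    n_eyes: int

    @property
    def label(self) -> str:
        return tables.group_label(self.group, self.timepoint)


@dataclass
class SyntheticConfig:
    """Stated world for one synthetic study.

    Per-cohort dictionaries are keyed by the cohort label (e.g. ``hAMSC_mid``).
    ``iop_offset`` is the systematic experimental-minus-expected IOP shift
    added after the Goldmann-consistent true IOP is solved.
    """

    groups: list[GroupSpec]
    facility_geomean: dict[str, float]                 # nl/min/mmHg
    facility_log_sd: float = 0.3                       # SD of ln facility
    beta_mean: float = 0.3                             # power-law exponent
    beta_sd: float = 0.0
    pe: float = 7.0                                    # mmHg
    pr: float = 8.0                                    # mmHg
    q: float = 37.84                                   # nl/min, shared inflow
    iop_offset: dict[str, float] = field(default_factory=dict)   # mmHg
    tonometer_sd: float = 1.0                          # mmHg
    flow_noise_sd: float = 0.5                         # nl/min
    transient_tau: float = 60.0                        # s; 0 = instant settling
    step_pressures: tuple[float, ...] = DEFAULT_STEP_PRESSURES
    step_duration: float = 360.0                       # s per pressure step
    acclimatization: float = 60.0                      # s recorded at 8 mmHg
    sample_rate: float = 1.0                           # Hz
    cellularity_mean: dict[str, float] = field(default_factory=dict)  # nuclei/um
    cellularity_sd: float = 0.08                       # between-eye, nuclei/um
    cellularity_section_sd: float = 0.04               # within-eye, nuclei/um
    sections_per_eye: int = 4
    iw_length: float = 50.0                            # um per section
    bmm_ratio_mean: dict[str, float] = field(default_factory=dict)
    bmm_ratio_sd: float = 0.08                         # between-eye
    bmm_section_sd: float = 0.05                       # within-eye
    annotator_sd: float = 0.02
    annotators: tuple[str, ...] = ("A1", "A2")
    iw_total: float = 40.0                             # um per BMM section
    failure_rate: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for sd in (
            self.facility_log_sd, self.beta_sd, self.tonometer_sd,
            self.flow_noise_sd, self.cellularity_sd, self.cellularity_section_sd,
            self.bmm_ratio_sd, self.bmm_section_sd, self.annotator_sd,
        ):
            if sd < 0:
                raise ValueError("noise SDs must be non-negative")
        for label, gm in self.facility_geomean.items():
            if gm <= 0:
                raise ValueError(f"facility geometric mean for {label} must be positive")
        for label, m in self.bmm_ratio_mean.items():
            if not 0 <= m <= 1:
                raise ValueError(f"BMM ratio mean for {label} must lie in [0, 1]")
        steps = np.asarray(self.step_pressures)
        if np.any(np.diff(steps) <= 0):
            raise ValueError("step pressures must be strictly increasing")
        if any(g.n_eyes < 1 for g in self.groups):
            raise ValueError("each cohort needs at least one eye")
        if not 0 <= self.failure_rate < 1:
            raise ValueError("failure_rate must lie in [0, 1)")

    # -- (de)serialization ---------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["groups"] = [[s.group, s.timepoint, s.n_eyes] for s in self.groups]
        d["step_pressures"] = [float(p) for p in self.step_pressures]
        d["annotators"] = list(self.annotators)

        def pyify(x):
            if isinstance(x, dict):
                return {k: pyify(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [pyify(v) for v in x]
            if isinstance(x, np.floating):
                return float(x)
            if isinstance(x, np.integer):
                return int(x)
            return x

        Path(path).write_text(yaml.safe_dump(pyify(d), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["groups"] = [GroupSpec(g, t, int(n)) for g, t, n in d["groups"]]
        d["step_pressures"] = tuple(d["step_pressures"])
        d["annotators"] = tuple(d["annotators"])
        return cls(**d)

    # -- study-calibrated default world --------------------------------------

    @classmethod
    def from_study_defaults(
        cls,
        n_eyes: int = 10,
        master_seed: int = 0,
        zero_noise: bool = False,
        zero_offsets: bool = False,
        failure_rate: float = 0.0,
    ) -> "SyntheticConfig":
        """World calibrated to the published cohort summary table.

        Q is calibrated from the wild-type row (beta = 0): Q = C*(IOP - Pe);
        each cohort's IOP offset is whatever reconciles its printed IOP with
        the Goldmann-expected IOP implied by its printed facility, so the
        published measured-vs-expected shift is reproduced by construction.
        Noise SDs are back-calculated from the printed CI half-widths.
        ``zero_noise`` collapses every random component (for closure checks).
        """
        # eye-level SDs are implied by the printed CIs at the *study's* group
        # size (~10 eyes), independent of how many eyes are simulated
        pub = tables.published_groups(n_eyes=10)
        pe, pr = 7.0, 8.0
        beta_mean = 0.3
        wt = pub["WT"]
        # Q from the reference (wild-type) row, facility evaluated at the
        # cohort's own pressure drop through the power law
        dp_wt = wt.iop - pe
        q = wt.facility * (dp_wt / pr) ** beta_mean * dp_wt
        groups = [GroupSpec(g, t, n_eyes) for g, t in tables.STUDY_GROUPS]
        params = GoldmannParams(q=q, pe=pe)
        offsets = {
            lbl: p.iop
            - expected_iop(params, FacilityFit(cr=p.facility, beta=beta_mean, pr=pr))
            for lbl, p in pub.items()
        }
        if zero_offsets:
            offsets = {lbl: 0.0 for lbl in offsets}
        bmm = {row.label: row.bmm for row in tables.BMM_TABLE.itertuples(index=False)}
        fac_log_sd = float(np.mean([p.facility_log_sd for p in pub.values()]))
        cell_sd = float(np.mean([p.cellularity_sd for p in pub.values()]))
        return cls(
            groups=groups,
            facility_geomean={lbl: p.facility for lbl, p in pub.items()},
            facility_log_sd=0.0 if zero_noise else fac_log_sd,
            beta_mean=beta_mean,
            beta_sd=0.0,
            pe=pe,
            pr=pr,
            q=q,
            iop_offset=offsets,
            tonometer_sd=0.0 if zero_noise else 1.0,
            flow_noise_sd=0.0 if zero_noise else 0.5,
            transient_tau=0.0 if zero_noise else 60.0,
            cellularity_mean={lbl: p.cellularity for lbl, p in pub.items()},
            cellularity_sd=0.0 if zero_noise else cell_sd,
            cellularity_section_sd=0.0 if zero_noise else 0.04,
            bmm_ratio_mean=bmm,
            bmm_ratio_sd=0.0 if zero_noise else 0.08,
            bmm_section_sd=0.0 if zero_noise else 0.05,
            annotator_sd=0.0 if zero_noise else 0.02,
            failure_rate=failure_rate,
            master_seed=master_seed,
        )


@dataclass(frozen=True)
class TrueEyeState:
    """Latent ground truth for one synthetic eye (for recovery tests)."""

    eye_id: str
    label: str           # cohort label
    group: str
    timepoint: str
    cr_true: float       # nl/min/mmHg
    beta_true: float
    iop_true: float      # mmHg
    cellularity_true: float
    bmm_true: float | None


def generate_cohort(config: SyntheticConfig) -> list[TrueEyeState]:
    """Draw the latent state of every eye in the configured cohorts."""
    eyes: list[TrueEyeState] = []
    params = GoldmannParams(q=config.q, pe=config.pe)
    for spec in config.groups:
        label = spec.label
        geomean = config.facility_geomean[label]
        cell_mean = config.cellularity_mean.get(label, 0.25)
        bmm_mean = config.bmm_ratio_mean.get(label)
        offset = config.iop_offset.get(label, 0.0)
        for i in range(spec.n_eyes):
            eye_id = f"{label}_{i:02d}"
            rng = _substream(config.master_seed, eye_id, purpose=0)
            cr = geomean * float(np.exp(rng.normal(0.0, config.facility_log_sd)))
            beta = float(rng.normal(config.beta_mean, config.beta_sd))
            iop = expected_iop(
                params, FacilityFit(cr=cr, beta=beta, pr=config.pr), tol=1e-9
            ) + offset
            cell = float(np.clip(rng.normal(cell_mean, config.cellularity_sd), 0.0, None))
            bmm = None
            if bmm_mean is not None:
                bmm = float(np.clip(rng.normal(bmm_mean, config.bmm_ratio_sd), 0.0, 1.0))
            eyes.append(
                TrueEyeState(
                    eye_id=eye_id,
                    label=label,
                    group=spec.group,
                    timepoint=spec.timepoint,
                    cr_true=cr,
                    beta_true=beta,
                    iop_true=iop,
                    cellularity_true=cell,
                    bmm_true=bmm,
                )
            )
    return eyes


def _steady_flow(eye: TrueEyeState, pressure: float, pr: float) -> float:
    return eye.cr_true * (pressure / pr) ** eye.beta_true * pressure


def generate_perfusion_trace(
    eye: TrueEyeState, config: SyntheticConfig
) -> PerfusionTrace:
    """Pressure-step perfusion trace for one eye.

    Flow relaxes exponentially (time constant ``transient_tau``; 0 means
    instant settling) from the previous steady level to the new step's steady
    level Cr*(P/Pr)**beta * P, with additive Gaussian noise.  With probability
    ``failure_rate`` the trace is flagged unusable.
    """
    rng = _substream(config.master_seed, eye.eye_id, purpose=1)
    dt = 1.0 / config.sample_rate
    tau = config.transient_tau

    times, pressures, flows, slices = [], [], [], []
    t0 = 0.0
    # acclimatization at the reference pressure (preparatory phases trimmed)
    n_acc = int(round(config.acclimatization * config.sample_rate))
    q_prev = _steady_flow(eye, 8.0, config.pr)
    if n_acc > 0:
        t = t0 + dt * np.arange(n_acc)
        times.append(t)
        pressures.append(np.full(n_acc, 8.0))
        flows.append(np.full(n_acc, q_prev))
        t0 = t[-1] + dt
    n_step = int(round(config.step_duration * config.sample_rate))
    start = n_acc
    for p_step in config.step_pressures:
        t = t0 + dt * np.arange(n_step)
        q_ss = _steady_flow(eye, p_step, config.pr)
        if tau > 0:
            q = q_ss + (q_prev - q_ss) * np.exp(-(t - t0) / tau)
        else:
            q = np.full(n_step, q_ss)
        times.append(t)
        pressures.append(np.full(n_step, p_step))
        flows.append(q)
        slices.append((start, start + n_step))
        start += n_step
        t0 = t[-1] + dt
        q_prev = float(q[-1])
    flow = np.concatenate(flows)
    if config.flow_noise_sd > 0:
        flow = flow + rng.normal(0.0, config.flow_noise_sd, size=flow.size)
    usable = bool(rng.random() >= config.failure_rate)
    return PerfusionTrace(
        eye_id=eye.eye_id,
        time=np.concatenate(times),
        pressure=np.concatenate(pressures),
        flow=flow,
        step_slices=slices,
        usable=usable,
    )


def generate_tonometry(eye: TrueEyeState, config: SyntheticConfig) -> np.ndarray:
    """Eight i.i.d. Gaussian rebound-tonometer readings around the true IOP."""
    rng = _substream(config.master_seed, eye.eye_id, purpose=2)
    return eye.iop_true + rng.normal(0.0, config.tonometer_sd, size=8)


def _annotator_offsets(config: SyntheticConfig) -> dict[str, float]:
    # one global offset per annotator, stable across eyes
    return {
        a: float(
            _substream(config.master_seed, f"annotator:{a}", purpose=3).normal(
                0.0, config.annotator_sd
            )
        )
        for a in config.annotators
    }


def generate_morphometry(
    eye: TrueEyeState, config: SyntheticConfig
) -> list[MorphometryRecord]:
    """Section-level cellularity and (where applicable) BMM observations.

    Cellularity: the per-section density is Gaussian around the eye's true
    density; the nuclei count is the nearest integer to density x IW length
    and the recorded IW length is adjusted so count / length reproduces the
    drawn density exactly.  BMM: a per-section true ratio plus a per-annotator
    global offset, clipped to [0, 1], expressed as contact-segment lengths.
    """
    rng = _substream(config.master_seed, eye.eye_id, purpose=4)
    offsets = _annotator_offsets(config)
    records: list[MorphometryRecord] = []
    for s in range(config.sections_per_eye):
        sec = f"s{s}"
        density = float(
            np.clip(rng.normal(eye.cellularity_true, config.cellularity_section_sd), 0.0, None)
        )
        count = int(round(density * config.iw_length))
        iw = count / density if density > 0 and count > 0 else config.iw_length
        records.append(
            MorphometryRecord(
                eye_id=eye.eye_id,
                section_id=sec,
                group=eye.label,
                nuclei_count=count,
                iw_length=iw,
            )
        )
        if eye.bmm_true is not None:
            sec_true = float(np.clip(rng.normal(eye.bmm_true, config.bmm_section_sd), 0.0, 1.0))
            for a in config.annotators:
                ratio = float(np.clip(sec_true + offsets[a], 0.0, 1.0))
                # split the contact length into a few segments
                parts = rng.dirichlet(np.ones(3)) if ratio > 0 else np.zeros(3)
                segs = tuple(float(x) for x in parts * ratio * config.iw_total)
                records.append(
                    MorphometryRecord(
                        eye_id=eye.eye_id,
                        section_id=sec,
                        group=eye.label,
                        annotator_id=a,
                        bmm_contact_lengths=segs,
                        iw_total=config.iw_total,
                    )
                )
    return records


def write_cohort(config: SyntheticConfig, out_dir) -> pd.DataFrame:
    """Materialize a full synthetic study as delimited text files.

    Writes per-eye trace files under ``traces/``, a tonometry table, a
    morphometry table and a cohort manifest; returns the manifest.
    """
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    eyes = generate_cohort(config)
    manifest_rows, tono_rows, morpho_rows = [], [], []
    for eye in eyes:
        trace = generate_perfusion_trace(eye, config)
        write_trace(trace, out / "traces" / f"{eye.eye_id}.tsv")
        readings = generate_tonometry(eye, config)
        tono_rows.append([eye.eye_id] + list(readings))
        for r in generate_morphometry(eye, config):
            morpho_rows.append(
                {
                    "eye_id": r.eye_id,
                    "section_id": r.section_id,
                    "annotator_id": r.annotator_id or "",
                    "nuclei_count": r.nuclei_count if r.nuclei_count is not None else "",
                    "iw_length_um": r.iw_length if r.iw_length is not None else "",
                    "bmm_contact_um": (
                        sum(r.bmm_contact_lengths) if r.bmm_contact_lengths else ""
                    ),
                    "iw_total_um": r.iw_total if r.iw_total is not None else "",
                }
            )
        manifest_rows.append(
            {
                "eye_id": eye.eye_id,
                "group": eye.group,
                "time_point": eye.timepoint,
                "usable_flag": trace.usable,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(
        tono_rows, columns=["eye_id"] + [f"reading_{i+1}" for i in range(8)]
    ).to_csv(out / "tonometry.tsv", sep="\t", index=False)
    pd.DataFrame(morpho_rows).to_csv(out / "morphometry.tsv", sep="\t", index=False)
    config.to_yaml(out / "config.yaml")
    return manifest
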