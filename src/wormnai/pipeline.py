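"""End-to-end orchestration: simulate -> extract -> call -> indices ->
discriminate, driven by a single YAML config.

The imaging chain (stack -> traces -> activation calls -> session NAI)
runs per recorded scene; the cohort chain (session counts + plate counts
-> subject records -> discrimination report) runs on tables. Each stage
reads and writes CSV files under the dataset directory, so stages can be
run individually or composed. Every excluded trace is logged with its
reason (motion, zero baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .cohortstats import DiscriminationReport, discriminate
from .eventcall import call_activation_trace
from .indices import PlateCount, SessionResult, aggregate_subject
from .protocol import StimulusProtocol
from .stackproc import extract_traces
from .synth import (
    SyntheticSceneSpec,
    generate_stack,
    generate_study,
    seeds_from_ground_truth,
)

log = logging.getLogger("wormnai")


@dataclass
class PipelineConfig:
    """All knobs of a simulation + analysis run."""

    output_dir: Path = Path("scratch/run")
    rng_seed: int = 0
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    # imaging scenes: per-subject-per-session recorded stacks
    imaging_subjects_per_group: int = 4
    imaging_sessions: int = 2
    n_animals: int = 6
    arena_size: tuple[int, int] = (192, 192)
    neuron_amplitude: float = 1.0
    noise_sd: float = 0.0
    background_level: float = 200.0
    motion_fraction: float = 0.1
    p_act_cancer: float = 0.8
    p_act_control: float = 0.2
    # count-level study (no imaging)
    cohort_subjects_per_group: int = 36
    worms_per_session: int = 25
    sessions: int = 2
    attraction_cancer: float = 0.35
    attraction_control: float = -0.35
    # algorithm knobs
    kernel_size: int = 3
    motion_window: int = 20
    # exclude a fixed disk around the seeded neuron from the motion
    # statistic, so the calcium transient is not mistaken for motion;
    # must cover the rendered blob plus the smoothing halo
    motion_mask_radius: int = 14
    activation_window_s: float = 10.0
    sigma_factor: float = 3.0
    roi_half: int = 24

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        proto = StimulusProtocol(**raw.pop("protocol", {}))
        if "arena_size" in raw:
            raw["arena_size"] = tuple(raw["arena_size"])
        if "output_dir" in raw:
            raw["output_dir"] = Path(raw["output_dir"])
        return cls(protocol=proto, **raw)

    def validate(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.motion_window < 1:
            raise ValueError("motion_window must be >= 1")
        for name in ("p_act_cancer", "p_act_control"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.motion_fraction <= 1.0:
            raise ValueError("motion_fraction must lie in [0, 1]")


def _scene_ids(config: PipelineConfig) -> list[tuple[str, str, int]]:
    out = []
    for group in ("cancer", "control"):
        for s in range(config.imaging_subjects_per_group):
            for sess in range(config.imaging_sessions):
                out.append((f"{group[:2]}{s:02d}", group, sess))
    return out


def run_simulate(config: PipelineConfig, force: bool = False) -> Path:
    """Write a complete synthetic dataset: per-session image stacks with
    seed and ground-truth sidecars, plus count-level cohort and plate
    tables. Idempotent given the seed; refuses to overwrite without
    ``force``."""
    config.validate()
    out = Path(config.output_dir)
    marker = out / "cohort.csv"
    if marker.exists() and not force:
        raise FileExistsError(
            f"{out} already holds a dataset; pass force=True / --force to regenerate"
        )
    stacks_dir = out / "stacks"
    stacks_dir.mkdir(parents=True, exist_ok=True)

    scenes = []
    for idx, (sid, group, sess) in enumerate(_scene_ids(config)):
        name = f"{sid}_s{sess}"
        p_act = config.p_act_cancer if group == "cancer" else config.p_act_control
        spec = SyntheticSceneSpec(
            arena_size=config.arena_size,
            n_animals=config.n_animals,
            protocol=config.protocol,
            neuron_amplitude=config.neuron_amplitude,
            noise_sd=config.noise_sd,
            background_level=config.background_level,
            motion_fraction=config.motion_fraction,
            p_responder=p_act,
            rng_seed=config.rng_seed * 10007 + idx,
        )
        stack, gt = generate_stack(spec)
        wio.write_stack(stack, stacks_dir, name)
        wio.write_seeds(
            seeds_from_ground_truth(gt, roi_half=config.roi_half),
            stacks_dir / f"{name}_seeds.csv",
        )
        gt.to_frame().to_csv(stacks_dir / f"{name}_truth.csv", index=False)
        scenes.append({"scene": name, "subject_id": sid, "group": group, "session": sess})
        log.info("simulated scene %s (%s, session %d)", name, group, sess)
    pd.DataFrame(scenes).to_csv(out / "scenes.csv", index=False)

    cohort, plates, truth = generate_study(
        n_per_group=config.cohort_subjects_per_group,
        p_act_cancer=config.p_act_cancer,
        p_act_control=config.p_act_control,
        worms_per_session=config.worms_per_session,
        sessions=config.sessions,
        attraction_cancer=config.attraction_cancer,
        attraction_control=config.attraction_control,
        rng_seed=config.rng_seed,
    )
    cohort.to_csv(out / "cohort.csv", index=False)
    plates.to_csv(out / "plates.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return out


def run_extract(config: PipelineConfig) -> pd.DataFrame:
    """Trace extraction for every simulated scene: background
    subtraction, smoothing, tracking, dF/F0, motion check. Writes one
    tidy trace CSV per scene and returns the scene table."""
    config.validate()
    out = Path(config.output_dir)
    stacks_dir = out / "stacks"
    scenes = pd.read_csv(out / "scenes.csv")
    for row in scenes.itertuples():
        try:
            stack = wio.read_stack(stacks_dir, row.scene)
            seeds = wio.read_seeds(stacks_dir / f"{row.scene}_seeds.csv")
            tracks = extract_traces(
                stack,
                seeds,
                kernel_size=config.kernel_size,
                motion_window=config.motion_window,
                motion_mask_radius=config.motion_mask_radius,
            )
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(f"stage extract failed on scene {row.scene}") from exc
        wio.write_traces(tracks, stack.frame_rate, stacks_dir / f"{row.scene}_traces.csv")
        for t in tracks:
            if t.viable:
                log.info("scene %s: %s viable", row.scene, t.animal_id)
            else:
                log.info("scene %s: %s excluded (%s)", row.scene, t.animal_id, t.reject_reason)
        n_viable = sum(t.viable for t in tracks)
        log.info("scene %s: %d/%d traces viable", row.scene, n_viable, len(tracks))
    return scenes


def run_call(config: PipelineConfig) -> pd.DataFrame:
    """Activation calling on extracted traces; writes calls.csv and
    sessions.csv (per-scene N_act / N_tot counts)."""
    config.validate()
    out = Path(config.output_dir)
    stacks_dir = out / "stacks"
    scenes = pd.read_csv(out / "scenes.csv")
    call_rows, session_rows = [], []
    for row in scenes.itertuples():
        traces = pd.read_csv(stacks_dir / f"{row.scene}_traces.csv")
        n_act = n_tot = 0
        for animal_id, tr in traces.groupby("animal_id", sort=True):
            if not bool(tr["viable"].iloc[0]):
                call_rows.append(
                    {"scene": row.scene, "animal_id": animal_id, "viable": False,
                     "i_on": np.nan, "i_off": np.nan, "sigma_on": np.nan,
                     "responded": np.nan}
                )
                continue
            try:
                call = call_activation_trace(
                    animal_id,
                    tr.sort_values("frame")["dff"].to_numpy(),
                    config.protocol,
                    window_s=config.activation_window_s,
                    sigma_factor=config.sigma_factor,
                )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"stage call failed on scene {row.scene}, animal {animal_id}"
                ) from exc
            n_tot += 1
            n_act += int(call.responded)
            call_rows.append(
                {"scene": row.scene, "animal_id": animal_id, "viable": True,
                 "i_on": call.i_on, "i_off": call.i_off,
                 "sigma_on": call.sigma_on, "responded": call.responded}
            )
        if n_tot > 0:
            session_rows.append(
                {"scene": row.scene, "subject_id": row.subject_id,
                 "group": row.group, "session": row.session,
                 "n_act": n_act, "n_tot": n_tot}
            )
        else:
            log.warning("scene %s: no viable traces, session dropped", row.scene)
    calls = pd.DataFrame(call_rows)
    calls.to_csv(out / "calls.csv", index=False)
    sessions = pd.DataFrame(session_rows)
    sessions.to_csv(out / "sessions.csv", index=False)
    return sessions


def run_indices(config: PipelineConfig, use_imaging: bool = False) -> pd.DataFrame:
    """Aggregate session counts and plate counts into per-subject
    records (mean/sd NAI and CI); writes subjects.csv.

    With ``use_imaging`` the session counts come from sessions.csv (the
    imaging chain); otherwise from the count-level cohort table, which
    scales to the full study size."""
    config.validate()
    out = Path(config.output_dir)
    source = "sessions.csv" if use_imaging else "cohort.csv"
    counts = pd.read_csv(out / source)
    plates_df = pd.read_csv(out / "plates.csv")
    records = []
    for (sid, group), sub in counts.groupby(["subject_id", "group"], sort=False):
        sessions = [
            SessionResult(sample_id=f"{sid}_s{r.session}", n_act=int(r.n_act), n_tot=int(r.n_tot))
            for r in sub.itertuples()
        ]
        psub = plates_df[plates_df["subject_id"] == sid]
        plates = [
            PlateCount(r.plate_id, int(r.n_odorant), int(r.n_control), int(r.n_total))
            for r in psub.itertuples()
        ]
        records.append(
            aggregate_subject(sid, group, sessions, plates, enforce_policy=not use_imaging)
        )
    log.info("aggregated %d subjects from %s", len(records), source)
    df = pd.DataFrame([r.__dict__ for r in records])
    df.to_csv(out / "subjects.csv", index=False)
    return df


def run_discriminate(config: PipelineConfig) -> DiscriminationReport:
    """Cohort discrimination on subjects.csv; writes report.csv and
    per-subject predictions.csv."""
    out = Path(config.output_dir)
    df = pd.read_csv(out / "subjects.csv")
    from .indices import SubjectRecord

    records = [SubjectRecord(**row) for row in df.to_dict("records")]
    report = discriminate(records)
    report.to_series().to_csv(out / "report.csv", header=["value"])
    report.predictions.to_csv(out / "predictions.csv", index=False)
    return report


def run_pipeline(config: PipelineConfig, use_imaging: bool = False) -> DiscriminationReport:
    """Compose extract -> call -> indices -> discriminate.

    The imaging stages are only run when ``use_imaging`` is set; the
    count-level path reproduces the full-cohort analysis without
    rendering 72 subjects' worth of video."""
    if use_imaging:
        run_extract(config)
        run_call(config)
    run_indices(config, use_imaging=use_imaging)
    return run_discriminate(config)
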