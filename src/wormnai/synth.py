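"""Synthetic calcium-imaging scenes, cohorts, and chemotaxis plates.

Everything downstream of the microscope is testable against this module:
it renders multi-animal fluorescence stacks with known neuron positions,
responder flags and motion events, draws per-subject activation counts
from binomial laws, and allocates worms to plate regions with a known
attraction parameter. Every stochastic choice is recorded in a
ground-truth sidecar, so pipeline outputs can be compared to the truth
position-for-position and count-for-count.

The default scene emulates the study conditions of the wide-field
pulse-arena assay: a 60-s acquisition at 10 frames/s (10 s buffer, 20 s
odor, 30 s buffer), ~15-20 immobilized worm heads per field of view,
GCaMP-like odor-OFF transients in responding neurons, 20 separate
background frames, and occasional animal motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import PlateCount
from .protocol import StimulusProtocol
from .stackproc import ImageStack, RoiSeed, default_reference_frame


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one synthetic imaging scene.

    neuron_amplitude is the peak dF/F0 of a responder transient (GCaMP3
    in AWC gives order-1 transients); noise_sd is additive pixel noise in
    camera counts; background_level a constant offset emulating stray
    light; motion_fraction the fraction of animals given a positional
    jump during the acquisition.
    """

    arena_size: tuple[int, int] = (192, 192)
    n_animals: int = 9
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    neuron_amplitude: float = 1.0
    noise_sd: float = 0.0
    background_level: float = 200.0
    motion_fraction: float = 0.0
    rng_seed: int = 0
    # rendering knobs
    blob_sigma: float = 3.0
    blob_peak: float = 2000.0
    rise_tau_s: float = 0.5
    decay_tau_s: float = 5.0
    p_responder: float = 0.5
    responders: tuple[bool, ...] | None = None  # explicit override
    motion_jump_px: int = 12
    motion_mode: str = "jump"  # or "drift"
    drift_px_per_frame: float = 0.0
    hyperpolarization: float = 0.0  # on-stimulus dip depth in dF/F0 units
    n_background_frames: int = 20
    grid_spacing: int = 56

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.protocol.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0.0 <= self.motion_fraction <= 1.0:
            raise ValueError("motion_fraction must lie in [0, 1]")
        if self.responders is not None and len(self.responders) != self.n_animals:
            raise ValueError("responders override must have n_animals entries")
        if self.motion_mode not in ("jump", "drift"):
            raise ValueError("motion_mode must be 'jump' or 'drift'")


@dataclass
class GroundTruth:
    """Sidecar recording every stochastic draw of a generated scene."""

    positions: np.ndarray  # (n_animals, T, 2) int
    responder: np.ndarray  # (n_animals,) bool
    onset_frame: int  # transient onset (odor removal)
    jump_frame: np.ndarray  # (n_animals,) int, -1 if no jump
    jump_vector: np.ndarray  # (n_animals, 2) int
    spec: SyntheticSceneSpec

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-animal summary for the CSV sidecar."""
        n = self.positions.shape[0]
        return pd.DataFrame(
            {
                "animal_id": [f"a{i:02d}" for i in range(n)],
                "responder": self.responder,
                "onset_frame": self.onset_frame,
                "row0": self.positions[:, 0, 0],
                "col0": self.positions[:, 0, 1],
                "jump_frame": self.jump_frame,
                "jump_drow": self.jump_vector[:, 0],
                "jump_dcol": self.jump_vector[:, 1],
            }
        )


def _transient(spec: SyntheticSceneSpec) -> np.ndarray:
    """dF/F0 time course shared by all responders: zero until odor
    removal, then a difference of exponentials normalized so that its
    sampled peak equals neuron_amplitude."""
    p = spec.protocol
    t = np.arange(p.n_frames) / p.frame_rate
    t0 = p.t_buffer_pre + p.t_odor
    g = np.zeros(p.n_frames)
    post = t >= t0
    dt = t[post] - t0
    shape = np.exp(-dt / spec.decay_tau_s) - np.exp(-dt / spec.rise_tau_s)
    peak = shape.max()
    if peak > 0:
        g[post] = shape / peak
    if spec.hyperpolarization > 0:
        on = (t >= p.t_buffer_pre) & (t < t0)
        g[on] = -spec.hyperpolarization / max(spec.neuron_amplitude, 1e-12)
    return spec.neuron_amplitude * g


def _layout(spec: SyntheticSceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Initial integer positions on a jittered grid; raises if the arena
    cannot host n_animals at the configured spacing."""
    H, W = spec.arena_size
    s = spec.grid_spacing
    margin = s // 2
    rows = max((H - 2 * margin) // s + 1, 0)
    cols = max((W - 2 * margin) // s + 1, 0)
    if rows * cols < spec.n_animals:
        raise ValueError(
            f"arena {H}x{W} too small for {spec.n_animals} animals at "
            f"spacing {s}: fits at most {rows * cols}; enlarge the arena "
            "or reduce grid_spacing"
        )
    pts = []
    for i in range(spec.n_animals):
        r, c = divmod(i, cols)
        jr = int(rng.integers(-s // 8, s // 8 + 1))
        jc = int(rng.integers(-s // 8, s // 8 + 1))
        pts.append((margin + r * s + jr, margin + c * s + jc))
    return np.array(pts, dtype=np.int64)


def _gauss_patch(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    return np.outer(g, g)


def generate_stack(spec: SyntheticSceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic scene.

    Each animal is a bright isotropic Gaussian blob; responders modulate
    their brightness by a transient beginning at odor removal, so the
    peak dF/F0 at the blob center equals ``neuron_amplitude`` exactly in
    the noise-free case. Animals flagged for motion jump by
    ``motion_jump_px`` (Chebyshev) at a recorded frame, or drift smoothly
    in ``drift`` mode. Frames are quantized to 16-bit camera counts.
    """
    rng = np.random.default_rng(spec.rng_seed)
    p = spec.protocol
    T = p.n_frames
    H, W = spec.arena_size

    pos0 = _layout(spec, rng)
    if spec.responders is not None:
        responder = np.asarray(spec.responders, dtype=bool)
    else:
        responder = rng.random(spec.n_animals) < spec.p_responder

    moving = rng.random(spec.n_animals) < spec.motion_fraction
    jump_frame = np.full(spec.n_animals, -1, dtype=np.int64)
    jump_vec = np.zeros((spec.n_animals, 2), dtype=np.int64)

    positions = np.repeat(pos0[:, None, :], T, axis=1)
    radius = int(np.ceil(4 * spec.blob_sigma))
    for a in range(spec.n_animals):
        if not moving[a]:
            continue
        if spec.motion_mode == "jump":
            f = int(rng.integers(T // 4, 3 * T // 4))
            theta = rng.random() * 2 * np.pi
            d = np.array(
                [
                    int(round(spec.motion_jump_px * np.sin(theta))),
                    int(round(spec.motion_jump_px * np.cos(theta))),
                ]
            )
            # keep the Chebyshev magnitude even when an axis rounds down
            if np.abs(d).max() < spec.motion_jump_px:
                d[np.argmax(np.abs(d))] = np.sign(d[np.argmax(np.abs(d))] or 1) * spec.motion_jump_px
            jump_frame[a] = f
            jump_vec[a] = d
            new = np.clip(
                pos0[a] + d, radius + 1, [H - radius - 2, W - radius - 2]
            )
            positions[a, f:] = new
        else:
            theta = rng.random() * 2 * np.pi
            v = spec.drift_px_per_frame * np.array([np.sin(theta), np.cos(theta)])
            path = pos0[a] + np.round(np.arange(T)[:, None] * v).astype(np.int64)
            positions[a] = np.clip(
                path, radius + 1, [H - radius - 2, W - radius - 2]
            )

    amp = _transient(spec)  # (T,) dF/F0 course, peak == neuron_amplitude
    patch = _gauss_patch(spec.blob_sigma, radius)

    frames = np.full((T, H, W), spec.background_level, dtype=np.float64)
    for a in range(spec.n_animals):
        gain = spec.blob_peak * (1.0 + (amp if responder[a] else 0.0))
        gain = np.broadcast_to(np.atleast_1d(gain), (T,))
        # animals are static between motion events: paste per unique position
        change = np.flatnonzero(
            np.any(np.diff(positions[a], axis=0) != 0, axis=1)
        )
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [T]))
        for s0, s1 in zip(starts, ends):
            r, c = positions[a, s0]
            frames[s0:s1, r - radius : r + radius + 1, c - radius : c + radius + 1] += (
                gain[s0:s1, None, None] * patch[None, :, :]
            )

    background = np.full(
        (spec.n_background_frames, H, W), spec.background_level, dtype=np.float64
    )
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, frames.shape)
        background += rng.normal(0.0, spec.noise_sd, background.shape)

    frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    background = np.clip(np.round(background), 0, 65535).astype(np.uint16)

    stack = ImageStack(frames, background, p)
    gt = GroundTruth(
        positions=positions,
        responder=responder,
        onset_frame=p.odor_offset_frame,
        jump_frame=jump_frame,
        jump_vector=jump_vec,
        spec=spec,
    )
    return stack, gt


def seeds_from_ground_truth(
    gt: GroundTruth, roi_half: int = 24, reference_frame: int | None = None
) -> list[RoiSeed]:
    """Build ROI seeds at the true positions, as a user would by clicking
    neuron centers at the reference frame (~2 s after odor removal)."""
    spec = gt.spec
    H, W = spec.arena_size
    if reference_frame is None:
        reference_frame = default_reference_frame(spec.protocol)
    seeds = []
    for a in range(gt.positions.shape[0]):
        r, c = gt.positions[a, reference_frame]
        seeds.append(
            RoiSeed(
                animal_id=f"a{a:02d}",
                row_min=max(int(r) - roi_half, 0),
                row_max=min(int(r) + roi_half + 1, H),
                col_min=max(int(c) - roi_half, 0),
                col_max=min(int(c) + roi_half + 1, W),
                seed_row=int(r),
                seed_col=int(c),
                reference_frame=reference_frame,
            )
        )
    return seeds


def generate_cohort(
    n_per_group: int = 36,
    p_act_cancer: float = 0.8,
    p_act_control: float = 0.2,
    worms_per_session: int = 25,
    sessions: int = 2,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject, per-session activation counts for a two-group study.

    Each session exposes ``worms_per_session`` viable worms and the
    number of responders is binomial with the group's activation
    probability. Defaults follow the study design: 36 subjects per group,
    at least two sessions of at least 25 worms each (so every subject
    contributes at least 50 worms).

    Returns (cohort table, ground-truth table); the cohort table has one
    row per subject x session with columns subject_id, group, session,
    n_act, n_tot.
    """
    for name, p in (("p_act_cancer", p_act_cancer), ("p_act_control", p_act_control)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if sessions < 1:
        raise ValueError("sessions must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rows, truth = [], []
    for group, p_act in (("cancer", p_act_cancer), ("control", p_act_control)):
        for s_idx in range(n_per_group):
            sid = f"{group[:2]}{s_idx:02d}"
            truth.append({"subject_id": sid, "group": group, "p_act": p_act})
            for sess in range(sessions):
                n_act = int(rng.binomial(worms_per_session, p_act))
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "session": sess,
                        "n_act": n_act,
                        "n_tot": worms_per_session,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def generate_plate_counts(
    n_worms: int,
    attraction: float,
    rng_seed: int = 0,
    neutral_fraction: float = 0.0,
    plate_id: str = "plate0",
) -> PlateCount:
    """Allocate worms to odorant/control/neutral plate regions.

    The multinomial cell probabilities are chosen so the expected
    chemotaxis index equals ``attraction``: p_odorant - p_control =
    attraction with p_odorant + p_control = 1 - neutral_fraction.
    """
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    if not -1.0 <= attraction <= 1.0:
        raise ValueError("attraction must lie in [-1, 1]")
    if not 0.0 <= neutral_fraction < 1.0:
        raise ValueError("neutral_fraction must lie in [0, 1)")
    if abs(attraction) > 1.0 - neutral_fraction:
        raise ValueError(
            "attraction magnitude cannot exceed the scored fraction "
            f"1 - neutral_fraction = {1.0 - neutral_fraction}"
        )
    p_odor = (1.0 - neutral_fraction + attraction) / 2.0
    p_ctrl = (1.0 - neutral_fraction - attraction) / 2.0
    rng = np.random.default_rng(rng_seed)
    n_o, n_c, _ = rng.multinomial(n_worms, [p_odor, p_ctrl, neutral_fraction])
    return PlateCount(
        plate_id=plate_id, n_odorant=int(n_o), n_control=int(n_c), n_total=n_worms
    )


def generate_study(
    n_per_group: int = 36,
    p_act_cancer: float = 0.8,
    p_act_control: float = 0.2,
    worms_per_session: int = 25,
    sessions: int = 2,
    attraction_cancer: float = 0.35,
    attraction_control: float = -0.35,
    worms_per_plate: int = 60,
    plates_per_subject: int = 3,
    neutral_fraction: float = 0.1,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full two-assay study: activation counts plus triplicate chemotaxis
    plates per subject, for the cohort-level discrimination analysis.

    Returns (cohort table, plate table, ground truth).
    """
    cohort, truth = generate_cohort(
        n_per_group,
        p_act_cancer,
        p_act_control,
        worms_per_session,
        sessions,
        rng_seed,
    )
    rng = np.random.default_rng(np.random.default_rng(rng_seed).integers(2**31))
    plate_rows = []
    for _, subj in truth.iterrows():
        a = attraction_cancer if subj["group"] == "cancer" else attraction_control
        for k in range(plates_per_subject):
            pc = generate_plate_counts(
                worms_per_plate,
                a,
                rng_seed=int(rng.integers(2**31)),
                neutral_fraction=neutral_fraction,
                plate_id=f"{subj['subject_id']}_p{k}",
            )
            plate_rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "group": subj["group"],
                    "plate_id": pc.plate_id,
                    "n_odorant": pc.n_odorant,
                    "n_control": pc.n_control,
                    "n_total": pc.n_total,
                }
            )
    truth = truth.assign(
        attraction=np.where(
            truth["group"] == "cancer", attraction_cancer, attraction_control
        )
    )
    return cohort, pd.DataFrame(plate_rows), truth
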