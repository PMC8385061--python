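"""Per-neuron fluorescence trace extraction from wide-field image stacks.

The imaging geometry is a microfluidic "pulse arena": 15-20 immobilized
worm heads in one field of view, each expressing GCaMP in a single
olfactory neuron. Processing follows the classical wide-field recipe:

1. subtract the pixel-wise mean of stimulus-free background frames;
2. smooth each frame with a small averaging filter;
3. from a user-supplied seed position at a reference frame, track the
   neuron in both temporal directions by maximizing the mean intensity of
   a 5x5 patch, constrained to move at most 30 px between frames;
4. normalize the raw intensity F_i to dF/F0 with F0 the mean of the first
   ten (pre-stimulus) frames;
5. reject traces of animals that moved, using a frame-difference
   statistic over the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .protocol import StimulusProtocol

#: maximum allowed displacement (Chebyshev) between consecutive frames
MAX_STEP_PX = 30
#: side of the square patch whose mean intensity is maximized and measured
PATCH = 5
#: half-width of the patch (margin needed around any candidate center)
PATCH_MARGIN = PATCH // 2


@dataclass
class ImageStack:
    """Time-ordered grayscale frames plus background frames and metadata.

    ``frames`` has shape (T, H, W); ``background_frames`` shape (B, H, W)
    with B >= 1 (20 by convention). Pixel dtype may be integer (camera
    counts) or float (after processing).
    """

    frames: np.ndarray
    background_frames: np.ndarray
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.background_frames = np.asarray(self.background_frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.background_frames.ndim != 3:
            raise ValueError("background_frames must be a (B, H, W) array")
        if self.background_frames.shape[0] < 1:
            raise ValueError("at least one background frame is required")
        if self.frames.shape[1:] != self.background_frames.shape[1:]:
            raise ValueError(
                "background frame shape "
                f"{self.background_frames.shape[1:]} does not match frame "
                f"shape {self.frames.shape[1:]}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_rate(self) -> float:
        return self.protocol.frame_rate


@dataclass(frozen=True)
class RoiSeed:
    """Seed for one animal: ROI rectangle and the neuron position at a
    reference frame (by default ~2 s after odor removal, where an active
    neuron is most visible)."""

    animal_id: str
    row_min: int
    row_max: int  # exclusive
    col_min: int
    col_max: int  # exclusive
    seed_row: int
    seed_col: int
    reference_frame: int

    def __post_init__(self) -> None:
        if not (self.row_min <= self.seed_row < self.row_max):
            raise ValueError(f"{self.animal_id}: seed row outside ROI bounds")
        if not (self.col_min <= self.seed_col < self.col_max):
            raise ValueError(f"{self.animal_id}: seed col outside ROI bounds")
        if (self.row_max - self.row_min) < PATCH or (
            self.col_max - self.col_min
        ) < PATCH:
            raise ValueError(
                f"{self.animal_id}: ROI smaller than {PATCH}x{PATCH}"
            )


def default_reference_frame(protocol: StimulusProtocol, delay_s: float = 2.0) -> int:
    """Frame index ``delay_s`` seconds after odor removal."""
    return protocol.odor_offset_frame + protocol.frame_at(delay_s)


@dataclass
class NeuronTrack:
    """Tracked positions and fluorescence of one neuron.

    ``F`` holds the raw per-frame intensity (mean of the tracked patch),
    ``dff`` the normalized trace (F - F0)/F0, ``id_series`` the
    frame-difference statistic used by the motion check.
    """

    animal_id: str
    positions: np.ndarray  # (T, 2) int, (row, col)
    F: np.ndarray  # (T,)
    seed: RoiSeed
    F0: float | None = None
    dff: np.ndarray | None = None
    viable: bool = True
    reject_reason: str | None = None
    id_series: np.ndarray | None = None  # (T-1,)
    id_mean: np.ndarray | None = None  # running window mean, (T-1,)
    id_sd: np.ndarray | None = None  # running window sd, (T-1,)

    def __post_init__(self) -> None:
        steps = np.abs(np.diff(self.positions, axis=0)).max(axis=1)
        if steps.size and steps.max() > MAX_STEP_PX:
            raise ValueError(
                f"{self.animal_id}: consecutive positions exceed the "
                f"{MAX_STEP_PX}-px constraint"
            )


def subtract_background(stack: ImageStack, clip: bool = True) -> ImageStack:
    """Subtract the pixel-wise mean of the background frames.

    With ``clip`` (default, unsigned-camera dialect) negative residuals
    are set to 0; ``clip=False`` keeps signed floats.
    """
    bg = stack.background_frames.astype(np.float64).mean(axis=0)
    out = stack.frames.astype(np.float64) - bg
    if clip:
        np.clip(out, 0.0, None, out=out)
    new = ImageStack(out, stack.background_frames, stack.protocol)
    new.background_mean = bg  # cached for reporting
    return new


def smooth_frames(stack: ImageStack, kernel_size: int = 3) -> ImageStack:
    """Per-frame uniform (averaging) filter; ``kernel_size`` must be odd.

    Kernel size 1 is the identity. Borders use reflected padding.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd and >= 1")
    if kernel_size == 1:
        return ImageStack(
            stack.frames.astype(np.float64),
            stack.background_frames,
            stack.protocol,
        )
    out = ndimage.uniform_filter(
        stack.frames.astype(np.float64),
        size=(1, kernel_size, kernel_size),
        mode="reflect",
    )
    return ImageStack(out, stack.background_frames, stack.protocol)


def _patch_mean_map(frame: np.ndarray) -> np.ndarray:
    """Mean of the centered PATCH x PATCH window at every pixel."""
    return ndimage.uniform_filter(frame, size=PATCH, mode="constant", cval=0.0)


def _candidate_bounds(prev: tuple[int, int], seed: RoiSeed) -> tuple[int, int, int, int]:
    """Candidate-center window: Chebyshev ball of MAX_STEP_PX around the
    previous position, intersected with the ROI shrunk by the patch margin
    (a candidate must admit a full 5x5 patch inside the ROI)."""
    r0 = max(prev[0] - MAX_STEP_PX, seed.row_min + PATCH_MARGIN)
    r1 = min(prev[0] + MAX_STEP_PX, seed.row_max - 1 - PATCH_MARGIN)
    c0 = max(prev[1] - MAX_STEP_PX, seed.col_min + PATCH_MARGIN)
    c1 = min(prev[1] + MAX_STEP_PX, seed.col_max - 1 - PATCH_MARGIN)
    return r0, r1, c0, c1


def _best_position(
    frame: np.ndarray, prev: tuple[int, int], seed: RoiSeed
) -> tuple[int, int]:
    r0, r1, c0, c1 = _candidate_bounds(prev, seed)
    if r1 < r0 or c1 < c0:
        # previous position pinned against the ROI border; stay put
        return prev
    pr0 = max(r0 - PATCH_MARGIN, 0)
    pc0 = max(c0 - PATCH_MARGIN, 0)
    sub = frame[pr0 : r1 + PATCH_MARGIN + 1, pc0 : c1 + PATCH_MARGIN + 1]
    means = _patch_mean_map(sub)
    window = means[
        r0 - pr0 : r0 - pr0 + (r1 - r0 + 1),
        c0 - pc0 : c0 - pc0 + (c1 - c0 + 1),
    ]
    # argmax returns the smallest row-major index on ties
    flat = int(np.argmax(window))
    dr, dc = divmod(flat, window.shape[1])
    return r0 + dr, c0 + dc


def track_neuron(stack: ImageStack, seed: RoiSeed) -> NeuronTrack:
    """Constrained max-intensity tracking from the seed position.

    Starting at ``seed.reference_frame`` the position is propagated in
    both temporal directions; at each step the next position maximizes
    the 5x5-patch mean over candidates within Chebyshev distance 30 of the
    previous position, restricted to the ROI. F at each frame is the mean
    intensity of the 5x5 patch at the tracked position.
    """
    T, H, W = stack.frames.shape
    if not (0 <= seed.reference_frame < T):
        raise ValueError(
            f"{seed.animal_id}: reference frame {seed.reference_frame} "
            f"outside stack of {T} frames"
        )
    if not (0 <= seed.seed_row < H and 0 <= seed.seed_col < W):
        raise ValueError(f"{seed.animal_id}: seed position outside stack")
    if seed.row_max > H or seed.col_max > W:
        raise ValueError(f"{seed.animal_id}: ROI exceeds stack bounds")

    frames = stack.frames.astype(np.float64, copy=False)
    positions = np.empty((T, 2), dtype=np.int64)

    # lock onto the local maximum at the reference frame itself
    start = _best_position(
        frames[seed.reference_frame], (seed.seed_row, seed.seed_col), seed
    )
    positions[seed.reference_frame] = start

    prev = start
    for i in range(seed.reference_frame + 1, T):
        prev = _best_position(frames[i], tuple(prev), seed)
        positions[i] = prev
    prev = start
    for i in range(seed.reference_frame - 1, -1, -1):
        prev = _best_position(frames[i], tuple(prev), seed)
        positions[i] = prev

    F = np.empty(T, dtype=np.float64)
    for i in range(T):
        r, c = positions[i]
        F[i] = frames[
            i,
            r - PATCH_MARGIN : r + PATCH_MARGIN + 1,
            c - PATCH_MARGIN : c + PATCH_MARGIN + 1,
        ].mean()

    return NeuronTrack(animal_id=seed.animal_id, positions=positions, F=F, seed=seed)


def compute_dff(track: NeuronTrack, n_baseline_frames: int = 10) -> NeuronTrack:
    """Normalize F to dF/F0 with F0 the mean over the first baseline
    frames (a stimulus-free window in which the neuron is quiescent).

    A non-positive baseline marks the track non-viable ("zero baseline")
    instead of producing an undefined trace.
    """
    if track.F.size < n_baseline_frames:
        raise ValueError(
            f"{track.animal_id}: trace shorter than {n_baseline_frames} "
            "baseline frames"
        )
    F0 = float(track.F[:n_baseline_frames].mean())
    if F0 <= 0:
        return replace(
            track, F0=F0, dff=None, viable=False, reject_reason="zero baseline"
        )
    dff = (track.F - F0) / F0
    return replace(track, F0=F0, dff=dff)


def roi_id_series(
    stack: ImageStack,
    seed: RoiSeed,
    signed: bool = False,
    mask_radius: int = 0,
) -> np.ndarray:
    """Frame-difference statistic ID_{i,i+1}: element-wise sum over the
    ROI of the intensity difference between consecutive frames.

    Absolute differences by default; ``signed=True`` reproduces the naive
    signed sum (which cancels symmetric motion). With ``mask_radius`` > 0
    a fixed disk of that radius around the seed position is excluded, so
    the neuron's own calcium transient does not register as motion; any
    displacement that carries fluorescence past the disk edge still does.
    """
    roi = stack.frames[
        :, seed.row_min : seed.row_max, seed.col_min : seed.col_max
    ].astype(np.float64)
    diffs = np.diff(roi, axis=0)
    if not signed:
        diffs = np.abs(diffs)
    if mask_radius > 0:
        rr = np.arange(seed.row_min, seed.row_max) - seed.seed_row
        cc = np.arange(seed.col_min, seed.col_max) - seed.seed_col
        keep = rr[:, None] ** 2 + cc[None, :] ** 2 > mask_radius**2
        return (diffs * keep[None, :, :]).sum(axis=(1, 2))
    return diffs.sum(axis=(1, 2))


def motion_viability(
    id_series: np.ndarray, window: int = 20, atol: float = 1e-6
) -> tuple[bool, np.ndarray, np.ndarray]:
    """Apply the motion criterion to an ID series.

    A trace is viable only if every ID_{i,i+1} < mean + sd, where mean and
    sd (ddof=1) are taken over the IDs with index in i-window..i+window,
    clipped at the series edges. A window with zero dispersion (all IDs
    equal) carries no motion signal and passes. IDs below ``atol`` (in
    summed camera counts; sub-count values are floating-point residue of
    the smoothing filter, orders of magnitude below one count) are
    floored to zero. Returns (viable, means, sds).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ids = np.asarray(id_series, dtype=np.float64).copy()
    ids[np.abs(ids) < atol] = 0.0
    n = ids.size
    means = np.empty(n)
    sds = np.empty(n)
    viable = True
    for i in range(n):
        lo = max(0, i - window)
        hi = min(n, i + window + 1)
        seg = ids[lo:hi]
        means[i] = seg.mean()
        sds[i] = seg.std(ddof=1) if seg.size > 1 else 0.0
        if sds[i] == 0.0:
            continue
        if not (ids[i] < means[i] + sds[i]):
            viable = False
    return viable, means, sds


def motion_check(
    stack: ImageStack,
    track: NeuronTrack,
    window: int = 20,
    signed: bool = False,
    mask_radius: int = 0,
) -> NeuronTrack:
    """Reject tracks of animals that moved during the acquisition.

    The ROI frame-difference series varies much more in a moving scene
    than in a still one; a single frame pair violating the mean+sd
    criterion anywhere voids the whole trace. ``mask_radius`` excludes a
    fixed disk around the seed from the statistic (see
    :func:`roi_id_series`).
    """
    ids = roi_id_series(stack, track.seed, signed=signed, mask_radius=mask_radius)
    viable, means, sds = motion_viability(ids, window=window)
    ok = track.viable and viable
    reason = None if ok else ("motion" if not viable else track.reject_reason)
    return replace(
        track,
        viable=ok,
        reject_reason=reason,
        id_series=ids,
        id_mean=means,
        id_sd=sds,
    )


def extract_traces(
    stack: ImageStack,
    seeds: list[RoiSeed],
    kernel_size: int = 3,
    motion_window: int = 20,
    motion_mask_radius: int = 0,
    clip_background: bool = True,
) -> list[NeuronTrack]:
    """Full stack-processing chain for a list of seeded animals:
    background subtraction, smoothing, tracking, dF/F0, motion check."""
    sub = subtract_background(stack, clip=clip_background)
    smooth = smooth_frames(sub, kernel_size=kernel_size)
    tracks = []
    for seed in seeds:
        track = track_neuron(smooth, seed)
        track = compute_dff(track)
        track = motion_check(
            smooth, track, window=motion_window, mask_radius=motion_mask_radius
        )
        tracks.append(track)
    return tracks
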