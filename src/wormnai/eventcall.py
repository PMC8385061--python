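"""Activation event calling on normalized fluorescence traces.

AWC-class neurons are odor-OFF cells: a responding neuron fires a calcium
transient when the odor is removed. A trace is called "activated" when
the mean signal in a 10-s post-stimulus window exceeds the mean in a 10-s
on-stimulus window by more than three on-stimulus standard deviations:

    I_off - I_on > 3 * sigma_on

The on-stimulus window is the last 10 s of the odor interval and the
post-stimulus window the first 10 s after removal, bracketing the event.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from .protocol import StimulusProtocol
from .stackproc import NeuronTrack

#: activation threshold in on-stimulus standard deviations
SIGMA_FACTOR = 3.0
#: length of the on- and post-stimulus comparison windows, seconds
WINDOW_S = 10.0


@dataclass(frozen=True)
class ActivationCall:
    """Outcome of the activation test for one animal."""

    animal_id: str
    i_on: float
    i_off: float
    sigma_on: float
    responded: bool


def _window_means(
    dff: np.ndarray, protocol: StimulusProtocol, window_s: float
) -> tuple[np.ndarray, np.ndarray]:
    w = protocol.frame_at(window_s)
    off_frame = protocol.odor_offset_frame
    on_start = off_frame - w
    off_end = off_frame + w
    if on_start < protocol.odor_onset_frame:
        raise ValueError(
            f"on-stimulus window of {window_s} s does not fit in the "
            f"{protocol.t_odor} s odor interval"
        )
    if off_end > dff.size:
        raise ValueError(
            f"post-stimulus window of {window_s} s exceeds the trace "
            f"({dff.size} frames)"
        )
    return dff[on_start:off_frame], dff[off_frame:off_end]


def call_activation(
    track: NeuronTrack,
    protocol: StimulusProtocol,
    window_s: float = WINDOW_S,
    sigma_factor: float = SIGMA_FACTOR,
) -> ActivationCall:
    """Apply the 3-sigma activation rule to one viable trace.

    Non-viable tracks must be excluded upstream; calling one is an error,
    as is a trace with missing dF/F0 values inside either window.
    """
    if not track.viable:
        raise ValueError(
            f"{track.animal_id}: non-viable track "
            f"({track.reject_reason}) must not be called"
        )
    if track.dff is None:
        raise ValueError(f"{track.animal_id}: dff not computed")
    on, off = _window_means(np.asarray(track.dff, dtype=float), protocol, window_s)
    if np.isnan(on).any() or np.isnan(off).any():
        raise ValueError(
            f"{track.animal_id}: activation windows contain missing frames"
        )
    i_on = float(on.mean())
    i_off = float(off.mean())
    sigma_on = float(on.std(ddof=1)) if on.size > 1 else 0.0
    responded = (i_off - i_on) > sigma_factor * sigma_on
    return ActivationCall(
        animal_id=track.animal_id,
        i_on=i_on,
        i_off=i_off,
        sigma_on=sigma_on,
        responded=bool(responded),
    )


def call_activation_trace(
    animal_id: str,
    dff: np.ndarray,
    protocol: StimulusProtocol,
    window_s: float = WINDOW_S,
    sigma_factor: float = SIGMA_FACTOR,
) -> ActivationCall:
    """Activation call directly on a dF/F0 array (convenience for traces
    that did not come from image tracking)."""
    on, off = _window_means(np.asarray(dff, dtype=float), protocol, window_s)
    i_on = float(on.mean())
    i_off = float(off.mean())
    sigma_on = float(on.std(ddof=1)) if on.size > 1 else 0.0
    return ActivationCall(
        animal_id=animal_id,
        i_on=i_on,
        i_off=i_off,
        sigma_on=sigma_on,
        responded=bool((i_off - i_on) > sigma_factor * sigma_on),
    )


def activation_rate(calls: Sequence[ActivationCall]) -> float:
    """Fraction of calls that responded, in [0, 1]."""
    if len(calls) == 0:
        raise ValueError("activation rate of an empty call list is undefined")
    return sum(c.responded for c in calls) / len(calls)


def dose_contrast(
    rates_positive: Sequence[float],
    rates_control: Sequence[float],
    mode: str = "difference",
) -> np.ndarray:
    """Per-concentration contrast between positive- and control-sample
    activation rates; the concentration maximizing it is the working
    dilution. Difference of rates by default; ``mode='ratio'`` divides
    instead (undefined where the control rate is 0).
    """
    pos = np.asarray(rates_positive, dtype=float)
    ctl = np.asarray(rates_control, dtype=float)
    if pos.shape != ctl.shape:
        raise ValueError(
            f"concentration grids differ: {pos.shape} vs {ctl.shape}"
        )
    if mode == "difference":
        return pos - ctl
    if mode == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            return pos / ctl
    raise ValueError("mode must be 'difference' or 'ratio'")
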