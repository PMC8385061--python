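"""Stimulus protocol for pulsed-odor calcium imaging.

A recording is a buffer / odor / buffer sequence: buffer flows for a
pre-stimulus window, the odor (diluted urine sample) is switched in for a
fixed stimulation window, then buffer returns for a post-stimulus window.
AWC-class olfactory neurons are odor-OFF cells: the calcium transient of a
responding neuron begins at odor *removal*.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StimulusProtocol:
    """Buffer/odor/buffer interval boundaries and the acquisition rate.

    Parameters
    ----------
    t_buffer_pre : float
        Pre-stimulus buffer interval in seconds (default 10).
    t_odor : float
        Odor stimulation interval in seconds (default 20).
    t_buffer_post : float
        Post-stimulus buffer interval in seconds (default 30).
    frame_rate : float
        Acquisition rate in frames per second (default 10, consistent
        with a 100 ms exposure).
    """

    t_buffer_pre: float = 10.0
    t_odor: float = 20.0
    t_buffer_post: float = 30.0
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        for name in ("t_buffer_pre", "t_odor", "t_buffer_post", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def t_total(self) -> float:
        return self.t_buffer_pre + self.t_odor + self.t_buffer_post

    @property
    def n_frames(self) -> int:
        """Total frames; the three intervals tile the acquisition."""
        return int(round(self.t_total * self.frame_rate))

    @property
    def odor_onset_frame(self) -> int:
        """First frame with odor flowing."""
        return int(round(self.t_buffer_pre * self.frame_rate))

    @property
    def odor_offset_frame(self) -> int:
        """First frame after odor removal."""
        return int(round((self.t_buffer_pre + self.t_odor) * self.frame_rate))

    def frame_at(self, t: float) -> int:
        return int(round(t * self.frame_rate))
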