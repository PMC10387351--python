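"""Pacing protocols.

The study protocol is a constant pacing–pause provocation: pace at a fixed
frequency, then stop and watch the unpaced period for spontaneous activity
(DADs and triggered APs).  The full-length protocol paces single cells at
2 Hz for 290 s before a 10 s pause; the desk-scale default shortens the
pre-pacing to a configurable beat count, which is sufficient to reach a
quasi-steady state (beat-to-beat APD drift < 1%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class PacingProtocol:
    """Pacing–pause stimulation protocol for a single cell.

    Attributes
    ----------
    frequency_hz
        Pacing frequency (Hz).
    n_prebeats
        Number of conditioning beats before the recorded window.
    pause_s
        Unpaced period appended after the last stimulus (s).
    recorded_beats
        Number of final paced beats included in the recorded window.
    stim_amplitude
        Stimulus current (A/F); negative is depolarizing.
    stim_duration_ms
        Stimulus pulse width (ms).
    sample_ms
        Output sampling interval (ms).
    dt_ms
        Fixed integrator step (ms).
    """

    frequency_hz: float = 2.0
    n_prebeats: int = 50
    pause_s: float = 10.0
    recorded_beats: int = 4
    stim_amplitude: float = -12.0
    stim_duration_ms: float = 2.0
    sample_ms: float = 1.0
    dt_ms: float = 0.025

    def __post_init__(self) -> None:
        if not self.frequency_hz > 0:
            raise ValueError("frequency_hz must be > 0")
        if not self.stim_duration_ms < self.cycle_length_ms:
            raise ValueError("stimulus duration must be shorter than the cycle length")
        if self.pause_s < 0:
            raise ValueError("pause_s must be >= 0")
        if not self.sample_ms > 0:
            raise ValueError("sample_ms must be > 0")
        if not self.dt_ms > 0:
            raise ValueError("dt_ms must be > 0")
        if self.n_prebeats < 0 or self.recorded_beats < 1:
            raise ValueError("beat counts must be non-negative (>=1 recorded)")
        if self.recorded_beats > self.n_prebeats + self.recorded_beats:
            raise ValueError("recorded_beats inconsistent")

    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    @property
    def n_beats(self) -> int:
        """Total paced beats (conditioning + recorded)."""
        return self.n_prebeats + self.recorded_beats

    @property
    def total_ms(self) -> float:
        return self.n_beats * self.cycle_length_ms + self.pause_s * 1000.0

    @property
    def recorded_start_ms(self) -> float:
        """Start of the recorded window (first of the final paced beats)."""
        return self.n_prebeats * self.cycle_length_ms

    @property
    def pause_start_ms(self) -> float:
        return self.n_beats * self.cycle_length_ms

    def stimulus_times_ms(self) -> list[float]:
        return [i * self.cycle_length_ms for i in range(self.n_beats)]

    def paper_scale(self) -> "PacingProtocol":
        """The full-length protocol: 290 s of 2 Hz pacing, 10 s pause."""
        return dataclasses.replace(
            self,
            n_prebeats=int(round(290.0 * self.frequency_hz)) - self.recorded_beats,
            pause_s=10.0,
        )
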