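"""Stimulation schedules for the two frequency-tagging paradigms.

Electrophysiology: a 70 s sequence of images at a 6 Hz base rate with a
face inserted every fifth image (1.2 Hz oddball), sinusoidal contrast
modulation within each image cycle, and 2 s linear fade-in/out.

fMRI: a 405 s run in which a 2.167 s burst of face images interrupts the
6 Hz object stream every 9 s (0.111 Hz), with a 4.5 s baseline pad at both
ends of the 44-cycle block.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "SpikeStimulusSchedule",
    "BoldStimulusSchedule",
    "make_spike_schedule",
    "make_bold_schedule",
]


@dataclass
class SpikeStimulusSchedule:
    base_rate_hz: float = 6.0
    oddball_rate_hz: float = 1.2
    duration_s: float = 70.0
    fade_s: float = 2.0
    face_onsets_s: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.face_onsets_s is None:
            n = int(np.floor(self.duration_s * self.oddball_rate_hz + 1e-6))
            self.face_onsets_s = np.arange(n) / self.oddball_rate_hz
        self.face_onsets_s = np.asarray(self.face_onsets_s, dtype=float)

    @property
    def n_face_onsets(self) -> int:
        return int(self.face_onsets_s.size)

    def contrast(self, t) -> np.ndarray:
        """Stimulus contrast in [0, 1] at time(s) ``t``.

        Sinusoidal within each base-rate cycle (zero at image onsets, one at
        mid-cycle) multiplied by a linear fade envelope over the first and
        last ``fade_s`` seconds.
        """
        t = np.asarray(t, dtype=float)
        cyc = np.sin(np.pi * self.base_rate_hz * t) ** 2
        env = np.ones_like(t)
        if self.fade_s > 0:
            env = np.minimum(t / self.fade_s, (self.duration_s - t) / self.fade_s)
            env = np.clip(env, 0.0, 1.0)
        return cyc * env


@dataclass
class BoldStimulusSchedule:
    burst_rate_hz: float = 1.0 / 9.0
    burst_duration_s: float = 13.0 / 6.0  # 13 images (7 faces + 6 objects) at 6 Hz
    n_cycles: int = 44
    baseline_pad_s: float = 4.5
    tr_s: float = 1.5

    @property
    def cycle_s(self) -> float:
        return 1.0 / self.burst_rate_hz

    @property
    def run_duration_s(self) -> float:
        return self.n_cycles * self.cycle_s + 2.0 * self.baseline_pad_s

    @property
    def n_volumes(self) -> int:
        n = self.run_duration_s / self.tr_s
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                f"tr_s={self.tr_s} does not divide run duration {self.run_duration_s} s"
            )
        return int(round(n))

    @property
    def burst_onsets_s(self) -> np.ndarray:
        return self.baseline_pad_s + np.arange(self.n_cycles) * self.cycle_s


def make_spike_schedule(
    duration_s: float = 70.0,
    base_rate_hz: float = 6.0,
    oddball_divisor: int = 5,
    fade_s: float = 2.0,
) -> SpikeStimulusSchedule:
    """Build the oddball schedule: a face every ``oddball_divisor``-th image.

    With the defaults the face (oddball) rate is 6/5 = 1.2 Hz and a 70 s
    sequence contains 84 face onsets spaced exactly 1/1.2 s apart.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be positive")
    if base_rate_hz <= 0:
        raise InvalidParameterError("base_rate_hz must be positive")
    if oddball_divisor != int(oddball_divisor) or int(oddball_divisor) < 2:
        raise InvalidParameterError(
            f"oddball_divisor must be an integer >= 2, got {oddball_divisor!r}"
        )
    if fade_s < 0 or 2 * fade_s > duration_s:
        raise InvalidParameterError("fade_s must satisfy 0 <= 2*fade_s <= duration_s")
    return SpikeStimulusSchedule(
        base_rate_hz=float(base_rate_hz),
        oddball_rate_hz=float(base_rate_hz) / int(oddball_divisor),
        duration_s=float(duration_s),
        fade_s=float(fade_s),
    )


def make_bold_schedule(
    n_cycles: int = 44,
    burst_rate_hz: float = 1.0 / 9.0,
    burst_duration_s: float = 13.0 / 6.0,
    baseline_pad_s: float = 4.5,
    tr_s: float = 1.5,
) -> BoldStimulusSchedule:
    """Build the burst schedule for the fMRI paradigm (defaults: 405 s run)."""
    if n_cycles < 1 or burst_rate_hz <= 0 or burst_duration_s <= 0 or tr_s <= 0:
        raise InvalidParameterError("schedule parameters must be positive")
    sched = BoldStimulusSchedule(
        burst_rate_hz=burst_rate_hz,
        burst_duration_s=burst_duration_s,
        n_cycles=int(n_cycles),
        baseline_pad_s=baseline_pad_s,
        tr_s=tr_s,
    )
    sched.n_volumes  # validates divisibility
    return sched
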