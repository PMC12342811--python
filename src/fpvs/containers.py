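"""Shared data containers for the frequency-tagging pipeline.

These are deliberately plain dataclasses holding numpy arrays: every
analysis stage consumes and produces one of them, so the whole pipeline can
be driven either from the model classes in :mod:`fpvs.models` or from the
functional layer directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class SpikeTrain:
    """Event times (seconds) for one unit during one stimulation sequence."""

    times_s: np.ndarray
    duration_s: float
    unit_id: str = "u0"
    sequence_id: int = 0

    def __post_init__(self) -> None:
        self.times_s = np.sort(np.asarray(self.times_s, dtype=float))

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)


@dataclass
class BinnedTrain:
    """Spike counts on a regular time grid.

    ``counts[k]`` is the number of spikes in ``[k/bin_rate_hz, (k+1)/bin_rate_hz)``.
    """

    counts: np.ndarray
    bin_rate_hz: float
    duration_s: float

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    def rate_hz(self) -> np.ndarray:
        """Instantaneous firing rate (spikes/s) per bin."""
        return np.asarray(self.counts, dtype=float) * self.bin_rate_hz


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude/phase spectrum with resolution ``df_hz = 1/duration``.

    Phase follows the *delay-positive* convention: a cosine whose peak lags
    the origin by ``tau`` seconds has phase ``+2*pi*f*tau`` (wrapped to
    ``(-pi, pi]``).  The DC bin is retained but never used as a target or a
    noise neighbour by any statistic in this package.
    """

    freqs_hz: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    df_hz: float

    @property
    def n_bins(self) -> int:
        return int(self.freqs_hz.size)

    def bin_index(self, freq_hz: float, tol_frac: float = 0.25) -> int:
        """Index of the bin at ``freq_hz``; raises if misaligned by > tol_frac*df."""
        from .exceptions import MisalignedFrequencyError

        idx = int(round(freq_hz / self.df_hz))
        if idx < 0 or idx >= self.n_bins or abs(idx * self.df_hz - freq_hz) > tol_frac * self.df_hz + 1e-12:
            raise MisalignedFrequencyError(
                f"frequency {freq_hz} Hz is not on a spectral bin "
                f"(df = {self.df_hz} Hz, nearest bin at {idx * self.df_hz} Hz)"
            )
        return idx


@dataclass
class FrequencyStats:
    """Harmonic-summed spectral statistics at a set of target frequencies."""

    target_freqs_hz: tuple
    summed_amplitude: float
    z_score: float
    snr: float


@dataclass
class UnitClassification:
    """Per-unit decision record from the spectral branch."""

    unit_id: str
    unit_kind: str  # "SU" | "MU"
    base_z: float
    face_z: float
    visually_responsive: bool
    face_selective_p05: bool
    face_selective_p01: bool
    response_sign: str = "undetermined"  # increase | decrease | undetermined
    face_exclusive: bool = False
    base_stats: Optional[FrequencyStats] = None
    face_stats: Optional[FrequencyStats] = None


@dataclass
class PeriFaceResponse:
    """Notch-filtered, smoothed, baseline-subtracted response around face onset."""

    time_s: np.ndarray
    net_rate_hz: np.ndarray
    baseline_sd_hz: float
    latency_ms: Optional[float]
    amplitude_hz: float
    sign: str  # increase | decrease | undetermined
    n_epochs: int = 0
    n_dropped: int = 0


@dataclass
class BoldRunData:
    """Preprocessed BOLD volumes-over-time (dummy scans already trimmed)."""

    data: np.ndarray  # (x, y, z, t)
    tr_s: float

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[-1])

    @property
    def df_hz(self) -> float:
        return 1.0 / (self.n_volumes * self.tr_s)


@dataclass
class SignedZMap:
    """Per-voxel Z at the stimulation frequency with phase-derived sign."""

    z: np.ndarray
    phase: np.ndarray
    center_phase_phi: float
    sign: np.ndarray  # +1 / -1
    signed_z: np.ndarray
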