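"""Frequency-domain statistics on spike trains.

The chain is: bin spikes on a regular grid, take an unwindowed FFT, then
standardise the amplitude at the tagged frequencies against the surrounding
noise bins.  Face selectivity is tested on the amplitude summed over the
oddball frequency and its harmonics (1.2, 2.4, 3.6, 4.8 Hz); the general
visual response on the base frequency and harmonic (6, 12 Hz).

Z-score: the noise reference is the 20 surrounding bins, 10 on each side of
the target bin; when harmonics are summed, the neighbour amplitudes are
summed position-wise across harmonics first, so the reference has the same
distribution as the summed target.

SNR spectrum: amplitude divided by the mean of 22 surrounding bins (11 per
side, excluding the bin directly adjacent on each side).
"""
from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np

from .containers import (
    AmplitudeSpectrum,
    BinnedTrain,
    FrequencyStats,
    SpikeTrain,
    UnitClassification,
)
from .exceptions import (
    DegenerateSpectrumError,
    InvalidParameterError,
    MisalignedFrequencyError,
)
from .schedules import SpikeStimulusSchedule

__all__ = [
    "bin_spikes",
    "amplitude_spectrum",
    "harmonic_z",
    "snr_spectrum",
    "classify_unit",
    "FACE_HARMONICS",
    "BASE_HARMONICS",
]

#: Oddball frequency and harmonics used for the face-selectivity statistic.
FACE_HARMONICS = (1.2, 2.4, 3.6, 4.8)
#: Base frequency and harmonic used for the general visual response statistic.
BASE_HARMONICS = (6.0, 12.0)

#: One-tailed normal thresholds as printed: p < .05, p < .01, p < .001.
Z_P05, Z_P01, Z_P001 = 1.64, 2.32, 3.1


def bin_spikes(train: SpikeTrain, bin_rate_hz: float = 1000.0) -> BinnedTrain:
    """Count spikes in contiguous ``1/bin_rate_hz`` bins over the sequence."""
    if bin_rate_hz <= 0:
        raise InvalidParameterError("bin_rate_hz must be positive")
    n_bins = int(round(train.duration_s * bin_rate_hz))
    if abs(n_bins - train.duration_s * bin_rate_hz) > 1e-6:
        raise InvalidParameterError(
            f"bin_rate_hz={bin_rate_hz} does not divide duration {train.duration_s} s"
        )
    t = train.times_s
    bad = (t < 0) | (t >= train.duration_s)
    if np.any(bad):
        raise InvalidParameterError(
            f"spike time {t[bad][0]:.6f} s outside sequence [0, {train.duration_s}) s"
        )
    idx = np.minimum((t * bin_rate_hz).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return BinnedTrain(counts=counts, bin_rate_hz=float(bin_rate_hz), duration_s=float(train.duration_s))


def amplitude_spectrum(series, sample_rate_hz: Optional[float] = None) -> AmplitudeSpectrum:
    """One-sided amplitude/phase spectrum of a binned train or raw series.

    No window, no detrend.  Amplitudes use the one-sided convention (interior
    bins scaled by 2/N) so a unit cosine at a bin frequency has amplitude 1.
    """
    if isinstance(series, BinnedTrain):
        x = np.asarray(series.counts, dtype=float)
        fs = series.bin_rate_hz
    else:
        x = np.asarray(series, dtype=float)
        if sample_rate_hz is None:
            raise InvalidParameterError("sample_rate_hz required for a raw series")
        fs = float(sample_rate_hz)
    n = x.size
    if n < 2:
        raise InvalidParameterError("series must have at least 2 samples")
    coef = np.fft.rfft(x)
    amp = np.abs(coef) * (2.0 / n)
    amp[0] *= 0.5
    if n % 2 == 0:
        amp[-1] *= 0.5
    phase = -np.angle(coef)  # delay-positive convention
    phase[phase <= -np.pi] += 2 * np.pi
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return AmplitudeSpectrum(freqs_hz=freqs, amplitudes=amp, phases=phase, df_hz=fs / n)


def _neighbor_bins(idx: int, n_side: int, blocked: set, n_bins: int) -> tuple:
    """n_side usable noise bins on each side of ``idx``, nearest first.

    Blocked bins (other targets, harmonics of the other tagged frequency)
    are skipped and replaced by the next bin outward.  DC is never used.
    """
    left, right = [], []
    b = idx
    while len(left) < n_side:
        b -= 1
        if b < 1:
            raise DegenerateSpectrumError(
                f"not enough noise bins below target bin {idx} (need {n_side})"
            )
        if b in blocked:
            continue
        left.append(b)
    b = idx
    while len(right) < n_side:
        b += 1
        if b >= n_bins:
            raise DegenerateSpectrumError(
                f"not enough noise bins above target bin {idx} (need {n_side})"
            )
        if b in blocked:
            continue
        right.append(b)
    return left, right


def harmonic_z(
    spectrum: AmplitudeSpectrum,
    target_freqs_hz: Sequence[float],
    n_side: int = 10,
    exclude_freqs_hz: Iterable[float] = (),
) -> FrequencyStats:
    """Harmonic-summed Z-score and SNR at the target frequencies.

    Amplitudes at the target bins are summed; neighbour amplitudes are summed
    position-wise across harmonics (offset +k of harmonic 1 with offset +k of
    harmonic 2, ...), giving ``2*n_side`` summed noise values.  Then
    ``Z = (summed target - mean) / sd`` with the population (ddof=0) standard
    deviation, and ``SNR = summed target / mean``.
    """
    if n_side < 2:
        raise InvalidParameterError("n_side must be >= 2")
    amps = spectrum.amplitudes
    target_bins = [spectrum.bin_index(f) for f in target_freqs_hz]
    blocked = set(target_bins)
    for f in exclude_freqs_hz:
        b = int(round(f / spectrum.df_hz))
        if abs(b * spectrum.df_hz - f) <= 0.5 * spectrum.df_hz and 0 < b < spectrum.n_bins:
            blocked.add(b)

    target_sum = float(sum(amps[b] for b in target_bins))
    neigh = np.zeros(2 * n_side)
    for b in target_bins:
        left, right = _neighbor_bins(b, n_side, blocked, spectrum.n_bins)
        neigh[:n_side] += amps[left]
        neigh[n_side:] += amps[right]
    mean = float(neigh.mean())
    sd = float(neigh.std(ddof=0))
    if sd <= 1e-12 * max(mean, abs(target_sum)):
        raise DegenerateSpectrumError("zero spread in neighbouring bins; Z undefined")
    z = (target_sum - mean) / sd
    snr = target_sum / mean if mean > 0 else np.nan
    return FrequencyStats(
        target_freqs_hz=tuple(float(f) for f in target_freqs_hz),
        summed_amplitude=target_sum,
        z_score=float(z),
        snr=float(snr),
    )


def snr_spectrum(spectrum: AmplitudeSpectrum, n_side: int = 12) -> np.ndarray:
    """Per-bin SNR: amplitude over the mean of offsets ±2..±n_side.

    Bins whose neighbourhood would run past the spectrum edges (or into the
    DC bin) are returned as NaN; a zero neighbour mean gives NaN with a
    warning rather than an error.
    """
    if n_side < 3:
        raise InvalidParameterError("n_side must be >= 3")
    amps = spectrum.amplitudes
    n = amps.size
    out = np.full(n, np.nan)
    lo, hi = n_side + 1, n - n_side  # lowest neighbour must stay above DC
    if hi <= lo:
        return out
    idx = np.arange(lo, hi)
    acc = np.zeros(idx.size)
    n_off = 0
    for off in range(2, n_side + 1):
        acc += amps[idx - off] + amps[idx + off]
        n_off += 2
    mean = acc / n_off
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = amps[idx] / mean
    if np.any(mean == 0):
        warnings.warn("zero neighbour mean in SNR spectrum; affected bins set to NaN")
        snr[mean == 0] = np.nan
    out[idx] = snr
    return out


def _unit_spectrum(
    trains: Sequence[SpikeTrain],
    bin_rate_hz: float,
    aggregate: str,
) -> AmplitudeSpectrum:
    """Average (default) or concatenate spectra across stimulation sequences."""
    if aggregate == "average":
        spectra = [amplitude_spectrum(bin_spikes(t, bin_rate_hz)) for t in trains]
        amps = np.mean([s.amplitudes for s in spectra], axis=0)
        s0 = spectra[0]
        return AmplitudeSpectrum(s0.freqs_hz, amps, s0.phases, s0.df_hz)
    if aggregate == "concatenate":
        counts = np.concatenate([bin_spikes(t, bin_rate_hz).counts for t in trains])
        return amplitude_spectrum(counts, bin_rate_hz)
    raise InvalidParameterError(f"unknown aggregate mode {aggregate!r}")


def classify_unit(
    trains,
    schedule: SpikeStimulusSchedule,
    bin_rate_hz: float = 1000.0,
    n_side: int = 10,
    aggregate: str = "average",
    base_mode: str = "6+12",
    response_sign: str = "undetermined",
    unit_id: Optional[str] = None,
    unit_kind: str = "SU",
) -> UnitClassification:
    """Classify one unit from its stimulation sequences.

    ``base_mode`` selects whether the general visual response statistic sums
    the base frequency and its first harmonic ("6+12", default) or the base
    frequency alone ("6"); both readings are used when counting
    face-exclusive units.  ``response_sign`` is carried over from the
    time-domain analysis (see :mod:`fpvs.temporal`).
    """
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    if len(trains) == 0:
        raise InvalidParameterError("at least one spike train is required")
    spec = _unit_spectrum(trains, bin_rate_hz, aggregate)

    base = schedule.base_rate_hz
    odd = schedule.oddball_rate_hz
    face_targets = tuple(odd * k for k in range(1, 5))
    if base_mode == "6+12":
        base_targets = (base, 2 * base)
    elif base_mode == "6":
        base_targets = (base,)
    else:
        raise InvalidParameterError(f"unknown base_mode {base_mode!r}")

    nyq = spec.freqs_hz[-1]
    base_harmonics = [base * k for k in range(1, int(nyq / base) + 1)]
    odd_harmonics = [odd * k for k in range(1, int(nyq / odd) + 1)]

    face_stats = harmonic_z(spec, face_targets, n_side, exclude_freqs_hz=base_harmonics)
    base_stats = harmonic_z(spec, base_targets, n_side, exclude_freqs_hz=odd_harmonics)

    visually_responsive = base_stats.z_score > Z_P05
    p05 = face_stats.z_score > Z_P05
    p01 = face_stats.z_score > Z_P01
    return UnitClassification(
        unit_id=unit_id if unit_id is not None else trains[0].unit_id,
        unit_kind=unit_kind,
        base_z=base_stats.z_score,
        face_z=face_stats.z_score,
        visually_responsive=bool(visually_responsive),
        face_selective_p05=bool(p05),
        face_selective_p01=bool(p01),
        response_sign=response_sign,
        face_exclusive=bool(p05 and not visually_responsive),
        base_stats=base_stats,
        face_stats=face_stats,
    )
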