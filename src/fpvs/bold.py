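"""Voxel-wise Fourier analysis of BOLD runs at the face-burst frequency.

The unwindowed FFT of each voxel's full time course gives an amplitude and a
phase at every frequency bin; the amplitude at the stimulation frequency
(1/9 Hz) is standardised against neighbouring bins into a Z-score, and the
response sign (activation vs deactivation) is read off the phase: the modal
phase bin of strongly responding voxels defines a centre phase phi, voxels
within phi +/- pi/2 are activations (+), all others deactivations (-).

Phase follows the delay-positive convention of
:class:`fpvs.containers.AmplitudeSpectrum`: a burst-locked response peaking
after stimulus onset has positive phase, so genuine responses land in
(0, pi) and a sign-flipped (deactivated) response sits pi away.
"""
from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np

from .containers import BoldRunData, SignedZMap
from .exceptions import (
    InvalidParameterError,
    MisalignedFrequencyError,
    NoReferencePhaseError,
)

__all__ = ["voxel_fourier", "voxel_z", "assign_signs", "analyze_bold_run", "STIM_FREQ_HZ"]

logger = logging.getLogger(__name__)

#: Face-burst stimulation frequency of the fMRI paradigm.
STIM_FREQ_HZ = 1.0 / 9.0


def voxel_fourier(run: BoldRunData) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided amplitude and phase per voxel per frequency bin.

    Returns ``(freqs_hz, amplitudes, phases)`` where the spectral axis is
    last.  No window, no detrend.
    """
    data = np.asarray(run.data, dtype=float)
    n = data.shape[-1]
    if n < 20:
        raise InvalidParameterError("need at least 20 volumes")
    coef = np.fft.rfft(data, axis=-1)
    amp = np.abs(coef) * (2.0 / n)
    amp[..., 0] *= 0.5
    if n % 2 == 0:
        amp[..., -1] *= 0.5
    phase = -np.angle(coef)
    phase[phase <= -np.pi] += 2 * np.pi
    freqs = np.fft.rfftfreq(n, d=run.tr_s)
    return freqs, amp, phase


def _stim_bin(freqs: np.ndarray, stim_freq_hz: float) -> int:
    df = freqs[1] - freqs[0]
    idx = int(round(stim_freq_hz / df))
    if idx < 1 or idx >= freqs.size or abs(idx * df - stim_freq_hz) > 0.25 * df:
        raise MisalignedFrequencyError(
            f"stimulation frequency {stim_freq_hz} Hz is not on a bin "
            f"(df = {df} Hz, nearest bin at {idx * df} Hz)"
        )
    return idx


def voxel_z(
    freqs: np.ndarray,
    amplitudes: np.ndarray,
    stim_freq_hz: float = STIM_FREQ_HZ,
    n_side: int = 10,
) -> np.ndarray:
    """Per-voxel Z at the stimulation bin against ``n_side`` neighbours per side.

    ``Z = (amp(stim) - mean(neighbours)) / sd(neighbours)`` (ddof=0).
    Voxels with zero neighbour spread (e.g. constant time courses) get NaN.
    """
    idx = _stim_bin(freqs, stim_freq_hz)
    if idx - n_side < 1 or idx + n_side >= freqs.size:
        raise InvalidParameterError("not enough neighbouring bins around the stimulation bin")
    offsets = np.r_[np.arange(-n_side, 0), np.arange(1, n_side + 1)]
    neigh = amplitudes[..., idx + offsets]
    mean = neigh.mean(axis=-1)
    sd = neigh.std(axis=-1, ddof=0)
    # a spread at floating-point residue level (constant voxels) is degenerate
    scale = np.maximum(amplitudes[..., 0], amplitudes[..., idx])
    degenerate = sd <= 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (amplitudes[..., idx] - mean) / sd
    n_bad = int(np.sum(degenerate))
    if n_bad:
        logger.info("%d voxel(s) with zero neighbour spread set to NaN", n_bad)
        z = np.where(degenerate, np.nan, z)
    return z


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.mod(np.asarray(angle, dtype=float) + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def assign_signs(
    z: np.ndarray,
    phase: np.ndarray,
    z_thr: float = 3.1,
    n_phase_bins: int = 20,
) -> SignedZMap:
    """Split voxels into activations (+) and deactivations (-) by phase.

    The reference phase phi is the centre of the modal bin of the phase
    histogram (``n_phase_bins`` bins over (0, pi]) of voxels with
    ``Z > z_thr`` and positive phase; ties go to the bin whose members carry
    the larger summed Z.  A voxel is an activation iff its circular distance
    to phi is strictly below pi/2 (a voxel exactly at phi + pi/2 is signed
    negative).
    """
    z = np.asarray(z, dtype=float)
    phase = np.asarray(phase, dtype=float)
    mask = np.isfinite(z) & (z > z_thr) & (phase > 0)
    if not np.any(mask):
        raise NoReferencePhaseError(
            f"no voxel with Z > {z_thr} and positive phase; cannot estimate phi"
        )
    edges = np.linspace(0.0, np.pi, n_phase_bins + 1)
    sel_phase = phase[mask]
    sel_z = z[mask]
    counts, _ = np.histogram(sel_phase, bins=edges)
    best = np.flatnonzero(counts == counts.max())
    if best.size > 1:
        # tie-break toward the bin with the larger summed Z of its members
        bin_of = np.clip(np.digitize(sel_phase, edges) - 1, 0, n_phase_bins - 1)
        zsums = np.array([sel_z[bin_of == b].sum() for b in best])
        best = best[[int(np.argmax(zsums))]]
    phi = float(0.5 * (edges[best[0]] + edges[best[0] + 1]))
    dist = np.abs(_wrap(phase - phi))
    sign = np.where(dist < np.pi / 2, 1.0, -1.0)
    return SignedZMap(z=z, phase=phase, center_phase_phi=phi, sign=sign, signed_z=sign * z)


def analyze_bold_run(
    run: BoldRunData,
    stim_freq_hz: float = STIM_FREQ_HZ,
    n_side: int = 10,
    z_thr: float = 3.1,
    n_phase_bins: int = 20,
) -> SignedZMap:
    """Full BOLD branch: FFT, Z map at the stimulation bin, phase-based signs."""
    freqs, amp, phase = voxel_fourier(run)
    zmap = voxel_z(freqs, amp, stim_freq_hz, n_side)
    idx = _stim_bin(freqs, stim_freq_hz)
    return assign_signs(zmap, phase[..., idx], z_thr=z_thr, n_phase_bins=n_phase_bins)
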