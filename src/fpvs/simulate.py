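"""Synthetic spike trains and BOLD runs with the structure the analysis assumes.

Spike trains are drawn from an inhomogeneous Poisson process whose rate is
the product of a baseline, a multiplicative 6 Hz contrast modulation, and a
face-locked gain that can be positive (increase), negative (relative
decrease) or -1 (full suppression of firing during the face window).
Sampling uses Poisson thinning, which is exact and fully reproducible given
a seed.

BOLD voxels are a burst boxcar convolved with a canonical double-gamma
haemodynamic response, scaled by a signed amplitude (negative amplitude =
deactivation), plus linear drift and white Gaussian noise.  Ground-truth
voxel labels are returned alongside the volumes so that recovery of the
activation/deactivation partition can be tested.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma

from .containers import SpikeTrain
from .exceptions import InvalidParameterError
from .schedules import BoldStimulusSchedule, SpikeStimulusSchedule

__all__ = [
    "UnitSimParams",
    "BoldSimParams",
    "simulate_spike_train",
    "simulate_bold_run",
    "double_gamma_hrf",
    "firing_rate",
]


@dataclass
class UnitSimParams:
    """Ground-truth generative parameters for one simulated unit.

    ``face_gain`` is the fractional rate change during the face response
    window of each face cycle: +1 doubles the rate, -1 silences the unit
    (values below -1 are clipped to full suppression).

    ``face_response_latency_s`` is measured from the *effective* face onset:
    the sinusoidal contrast modulation makes a face visible only
    ``contrast_onset_delay_s`` (~1/5 of a 6 Hz cycle) after its nominal
    onset, which is exactly the forward shift the time-domain analysis
    applies, so the latency recovered downstream estimates this parameter
    directly.
    """

    baseline_rate_hz: float = 5.0
    base_mod_depth: float = 0.5
    face_gain: float = 0.0
    face_response_latency_s: float = 0.120
    face_response_duration_s: float = 0.300
    contrast_onset_delay_s: float = 0.033
    seed: Optional[int] = None


@dataclass
class BoldSimParams:
    """Ground-truth generative parameters for one simulated BOLD run."""

    response_amplitude: float = 1.0
    noise_sd: float = 0.5
    drift_slope: float = 0.005  # signal units per volume
    n_voxels_active: int = 40
    n_voxels_deactive: int = 40
    n_voxels_null: int = 120
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 6.0
    seed: Optional[int] = None


def _face_indicator(
    t: np.ndarray, schedule: SpikeStimulusSchedule, params: UnitSimParams
) -> np.ndarray:
    """1 inside [onset+latency, onset+latency+duration] of each face cycle."""
    period = 1.0 / schedule.oddball_rate_hz
    u = t - params.face_response_latency_s - params.contrast_onset_delay_s
    return ((u >= 0) & (np.mod(u, period) < params.face_response_duration_s)).astype(float)


def firing_rate(
    t, schedule: SpikeStimulusSchedule, params: UnitSimParams
) -> np.ndarray:
    """Instantaneous rate r(t) of the generative model, clipped at zero."""
    t = np.asarray(t, dtype=float)
    gain = max(params.face_gain, -1.0)
    r = (
        params.baseline_rate_hz
        * (1.0 + params.base_mod_depth * schedule.contrast(t))
        * (1.0 + gain * _face_indicator(t, schedule, params))
    )
    return np.clip(r, 0.0, None)


def simulate_spike_train(
    schedule: SpikeStimulusSchedule,
    params: UnitSimParams,
    rng: Optional[np.random.Generator] = None,
    unit_id: str = "u0",
    sequence_id: int = 0,
) -> SpikeTrain:
    """Draw one spike train by Poisson thinning of the rate function."""
    if params.baseline_rate_hz < 0:
        raise InvalidParameterError("baseline_rate_hz must be non-negative")
    if params.base_mod_depth < 0:
        raise InvalidParameterError("base_mod_depth must be non-negative")
    if params.face_response_duration_s < 0 or params.face_response_latency_s < 0:
        raise InvalidParameterError("face response latency/duration must be non-negative")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    gain = max(params.face_gain, -1.0)
    lam_max = (
        params.baseline_rate_hz
        * (1.0 + params.base_mod_depth)
        * (1.0 + max(gain, 0.0))
    )
    if lam_max == 0:
        return SpikeTrain(np.empty(0), schedule.duration_s, unit_id, sequence_id)

    n_cand = rng.poisson(lam_max * schedule.duration_s)
    t_cand = np.sort(rng.uniform(0.0, schedule.duration_s, n_cand))
    accept = rng.uniform(0.0, 1.0, n_cand) * lam_max < firing_rate(t_cand, schedule, params)
    return SpikeTrain(t_cand[accept], schedule.duration_s, unit_id, sequence_id)


def double_gamma_hrf(
    t, peak_s: float = 6.0, undershoot_s: float = 16.0, ratio: float = 6.0
) -> np.ndarray:
    """Canonical double-gamma haemodynamic impulse response (peak normalised to 1)."""
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, peak_s) - _gamma.pdf(t, undershoot_s) / ratio
    peak = h.max()
    return h / peak if peak > 0 else h


def simulate_bold_run(
    schedule: BoldStimulusSchedule,
    params: BoldSimParams,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Simulate one 4-D BOLD run plus ground-truth voxel labels.

    Returns ``(data, labels)`` where ``data`` has shape ``(n_voxels, 1, 1,
    n_volumes)`` covering the full run (including the initial dummy-scan
    period that :func:`fpvs.io.read_bold_nifti` trims), and ``labels`` is a
    DataFrame of voxel index triplets with class ``active | deactive | null``.
    """
    if not isinstance(schedule, BoldStimulusSchedule):
        raise InvalidParameterError("schedule must be a BoldStimulusSchedule")
    if params.noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n_vol = schedule.n_volumes  # raises if tr does not divide the run
    dt = schedule.tr_s / 30.0
    t_hi = np.arange(0.0, schedule.run_duration_s + 32.0, dt)
    boxcar = np.zeros_like(t_hi)
    for onset in schedule.burst_onsets_s:
        boxcar[(t_hi >= onset) & (t_hi < onset + schedule.burst_duration_s)] = 1.0
    hrf = double_gamma_hrf(
        np.arange(0.0, 32.0, dt), params.hrf_peak_s, params.hrf_undershoot_s, params.hrf_ratio
    )
    resp_hi = np.convolve(boxcar, hrf)[: t_hi.size] * dt
    if resp_hi.max() > 0:
        resp_hi = resp_hi / resp_hi.max()  # unit peak so amplitude is in signal units
    vol_idx = np.round(np.arange(n_vol) * schedule.tr_s / dt).astype(int)
    resp = resp_hi[vol_idx]

    amps = np.concatenate(
        [
            np.full(params.n_voxels_active, params.response_amplitude),
            np.full(params.n_voxels_deactive, -params.response_amplitude),
            np.zeros(params.n_voxels_null),
        ]
    )
    classes = (
        ["active"] * params.n_voxels_active
        + ["deactive"] * params.n_voxels_deactive
        + ["null"] * params.n_voxels_null
    )
    n_vox = amps.size
    drift = params.drift_slope * np.arange(n_vol)
    data = (
        amps[:, None] * resp[None, :]
        + drift[None, :]
        + rng.normal(0.0, params.noise_sd, (n_vox, n_vol))
    )
    labels = pd.DataFrame(
        {
            "i": np.arange(n_vox),
            "j": np.zeros(n_vox, dtype=int),
            "k": np.zeros(n_vox, dtype=int),
            "label": classes,
        }
    )
    return data.reshape(n_vox, 1, 1, n_vol), labels
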