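"""Model/Results interface over the functional pipeline.

``SpikeUnitModel`` wraps one unit's spike trains plus the stimulation
schedule; ``fit()`` runs the spectral classification and the time-domain
characterisation and returns a ``SpikeUnitResults`` carrying the Z-scores,
the classification flags, the peri-face response curve, latency, amplitude
and sign, with a ``summary()`` table and a ``plot()`` helper.

``BoldRunModel`` wraps a (dummy-trimmed, run-averaged) BOLD 4-D array;
``fit()`` returns a ``BoldRunResults`` with the Z map, phases, the centre
phase phi and the signed Z map.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bold as _bold
from . import spectral as _spectral
from . import temporal as _temporal
from .containers import BoldRunData, SignedZMap, SpikeTrain
from .exceptions import InvalidParameterError
from .schedules import SpikeStimulusSchedule, make_spike_schedule

__all__ = ["SpikeUnitModel", "SpikeUnitResults", "BoldRunModel", "BoldRunResults"]


class SpikeUnitModel:
    """Frequency-tagging analysis of one unit (one or more 70 s sequences)."""

    def __init__(
        self,
        trains: Sequence[SpikeTrain],
        schedule: Optional[SpikeStimulusSchedule] = None,
        *,
        unit_kind: str = "SU",
        bin_rate_hz: float = 1000.0,
        n_side: int = 10,
        aggregate: str = "average",
        base_mode: str = "6+12",
        **temporal_kwargs,
    ) -> None:
        if isinstance(trains, SpikeTrain):
            trains = [trains]
        if not trains:
            raise InvalidParameterError("at least one spike train is required")
        self.trains = list(trains)
        self.schedule = schedule if schedule is not None else make_spike_schedule()
        self.unit_kind = unit_kind
        self.bin_rate_hz = bin_rate_hz
        self.n_side = n_side
        self.aggregate = aggregate
        self.base_mode = base_mode
        self.temporal_kwargs = temporal_kwargs

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        unit_id: str,
        schedule: Optional[SpikeStimulusSchedule] = None,
        **kwargs,
    ) -> "SpikeUnitModel":
        """Build from a tidy spike table (columns unit_id, sequence_id, spike_time_s)."""
        schedule = schedule if schedule is not None else make_spike_schedule()
        sub = df[df["unit_id"].astype(str) == str(unit_id)]
        if sub.empty:
            raise InvalidParameterError(f"no spikes for unit {unit_id!r}")
        trains = [
            SpikeTrain(g["spike_time_s"].to_numpy(), schedule.duration_s, str(unit_id), int(seq))
            for seq, g in sub.groupby("sequence_id")
        ]
        return cls(trains, schedule, **kwargs)

    def fit(self) -> "SpikeUnitResults":
        peri = _temporal.peri_face_response(
            self.trains, self.schedule, bin_rate_hz=self.bin_rate_hz, **self.temporal_kwargs
        )
        classification = _spectral.classify_unit(
            self.trains,
            self.schedule,
            bin_rate_hz=self.bin_rate_hz,
            n_side=self.n_side,
            aggregate=self.aggregate,
            base_mode=self.base_mode,
            response_sign=peri.sign,
            unit_kind=self.unit_kind,
        )
        return SpikeUnitResults(self, classification, peri)


class SpikeUnitResults:
    """Fitted per-unit estimates: spectral Z-scores, flags, latency, amplitude."""

    def __init__(self, model, classification, peri) -> None:
        self.model = model
        self.classification = classification
        self.peri = peri

    # convenience accessors
    @property
    def base_z(self) -> float:
        return self.classification.base_z

    @property
    def face_z(self) -> float:
        return self.classification.face_z

    @property
    def latency_ms(self):
        return self.peri.latency_ms

    @property
    def amplitude_hz(self) -> float:
        return self.peri.amplitude_hz

    @property
    def sign(self) -> str:
        return self.peri.sign

    def to_row(self) -> dict:
        c = self.classification
        return {
            "unit_id": c.unit_id,
            "unit_kind": c.unit_kind,
            "base_z": c.base_z,
            "face_z": c.face_z,
            "visually_responsive": c.visually_responsive,
            "face_selective_p05": c.face_selective_p05,
            "face_selective_p01": c.face_selective_p01,
            "response_sign": c.response_sign,
            "face_exclusive": c.face_exclusive,
            "latency_ms": self.peri.latency_ms,
            "amplitude_hz": self.peri.amplitude_hz,
            "baseline_sd_hz": self.peri.baseline_sd_hz,
        }

    def summary(self) -> str:
        c = self.classification
        lat = "-" if self.latency_ms is None else f"{self.latency_ms:.1f} ms"
        lines = [
            "Frequency-tagging unit analysis",
            "=" * 46,
            f"unit                 {c.unit_id} ({c.unit_kind})",
            f"sequences            {len(self.model.trains)}",
            f"base Z (6+12 Hz)     {c.base_z:8.3f}",
            f"face Z (1.2-4.8 Hz)  {c.face_z:8.3f}",
            f"visually responsive  {c.visually_responsive}",
            f"face-selective p<.05 {c.face_selective_p05}",
            f"face-selective p<.01 {c.face_selective_p01}",
            f"response sign        {c.response_sign}",
            f"face-exclusive       {c.face_exclusive}",
            f"latency              {lat}",
            f"amplitude [130-300]  {self.amplitude_hz:+.3f} spikes/s",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the net peri-face rate curve with the +/- 2.58 s.d. band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.peri
        ax.plot(p.time_s, p.net_rate_hz, lw=1.2, color="k")
        thr = 2.58 * p.baseline_sd_hz
        ax.axhspan(-thr, thr, color="0.85", zorder=0)
        ax.axvline(0.0, color="0.4", ls="--", lw=0.8)
        if p.latency_ms is not None:
            ax.axvline(p.latency_ms / 1000.0, color="r", ls=":", lw=0.8)
        ax.set_xlabel("time from (shifted) face onset (s)")
        ax.set_ylabel("net firing rate (spikes/s)")
        return ax


class BoldRunModel:
    """Voxel-wise spectral model of a run-averaged BOLD time series."""

    def __init__(
        self,
        data: np.ndarray,
        tr_s: float = 1.5,
        stim_freq_hz: float = _bold.STIM_FREQ_HZ,
        n_side: int = 10,
    ) -> None:
        self.run = data if isinstance(data, BoldRunData) else BoldRunData(np.asarray(data, float), tr_s)
        self.stim_freq_hz = stim_freq_hz
        self.n_side = n_side

    @classmethod
    def from_nifti(cls, paths, tr_s: float = 1.5, dummy_s: float = 9.0, **kwargs) -> "BoldRunModel":
        from .io import read_bold_nifti

        return cls(read_bold_nifti(paths, tr_s=tr_s, dummy_s=dummy_s), tr_s, **kwargs)

    def fit(self, z_thr: float = 3.1, n_phase_bins: int = 20) -> "BoldRunResults":
        zmap = _bold.analyze_bold_run(
            self.run, self.stim_freq_hz, self.n_side, z_thr=z_thr, n_phase_bins=n_phase_bins
        )
        return BoldRunResults(self, zmap, z_thr)


class BoldRunResults:
    """Signed Z map at the stimulation frequency plus the reference phase."""

    def __init__(self, model: BoldRunModel, zmap: SignedZMap, z_thr: float) -> None:
        self.model = model
        self.zmap = zmap
        self.z_thr = z_thr

    @property
    def z(self) -> np.ndarray:
        return self.zmap.z

    @property
    def phase(self) -> np.ndarray:
        return self.zmap.phase

    @property
    def phi(self) -> float:
        return self.zmap.center_phase_phi

    @property
    def sign(self) -> np.ndarray:
        return self.zmap.sign

    @property
    def signed_z(self) -> np.ndarray:
        return self.zmap.signed_z

    def to_dataframe(self) -> pd.DataFrame:
        idx = np.argwhere(np.isfinite(self.z))
        rows = {
            "i": idx[:, 0],
            "j": idx[:, 1],
            "k": idx[:, 2],
            "z": self.z[tuple(idx.T)],
            "phase": self.phase[tuple(idx.T)],
            "sign": np.where(self.sign[tuple(idx.T)] > 0, "+", "-"),
        }
        return pd.DataFrame(rows)

    def summary(self) -> str:
        sig = np.isfinite(self.z) & (self.z > self.z_thr)
        n_act = int(np.sum(sig & (self.sign > 0)))
        n_deact = int(np.sum(sig & (self.sign < 0)))
        lines = [
            "BOLD frequency-tagging analysis",
            "=" * 46,
            f"volumes              {self.model.run.n_volumes} (TR {self.model.run.tr_s} s)",
            f"stimulation freq     {self.model.stim_freq_hz:.4f} Hz",
            f"centre phase phi     {self.phi:.3f} rad",
            f"threshold            Z > {self.z_thr}",
            f"activated voxels     {n_act}",
            f"deactivated voxels   {n_deact}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Histogram of phases of supra-threshold voxels with phi marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mask = np.isfinite(self.z) & (self.z > self.z_thr)
        ax.hist(self.phase[mask], bins=20, range=(-np.pi, np.pi), color="0.6")
        ax.axvline(self.phi, color="r", ls="--", label="phi")
        ax.set_xlabel("phase (rad)")
        ax.set_ylabel("voxel count")
        ax.legend()
        return ax
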