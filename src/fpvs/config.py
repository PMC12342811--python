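"""Pipeline configuration: analysis constants, simulation parameters, YAML I/O.

The defaults are the constants of the published analysis: Z thresholds
1.64 / 2.32 / 3.1 (one-tailed p < .05 / .01 / .001), latency threshold
2.58 s.d., notch width 0.05 Hz, onset shift 0.033 s, 20 ms smoothing,
amplitude window [0.130, 0.300] s.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .exceptions import InvalidParameterError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # spike paradigm
    spike_duration_s: float = 70.0
    base_rate_hz: float = 6.0
    oddball_divisor: int = 5
    fade_s: float = 2.0
    n_sequences: int = 2
    # fMRI paradigm
    bold_n_cycles: int = 44
    bold_burst_rate_hz: float = 1.0 / 9.0
    bold_burst_duration_s: float = 13.0 / 6.0
    bold_baseline_pad_s: float = 4.5
    tr_s: float = 1.5
    dummy_s: float = 9.0
    # spectral analysis
    bin_rate_hz: float = 1000.0
    n_side_z: int = 10
    n_side_snr: int = 12
    z_p05: float = 1.64
    z_p01: float = 2.32
    z_p001: float = 3.1
    aggregate: str = "average"
    base_mode: str = "6+12"
    # temporal analysis
    notch_width_hz: float = 0.05
    shift_s: float = 0.033
    smooth_window_s: float = 0.020
    latency_k: float = 2.58
    min_duration_s: float = 0.030
    amplitude_window_s: Tuple[float, float] = (0.130, 0.300)
    baseline_method: str = "samples"
    # BOLD analysis
    n_phase_bins: int = 20
    # simulation
    n_units: int = 10
    baseline_rate_hz: float = 5.0
    base_mod_depth: float = 0.5
    face_gain: float = 0.8
    face_response_latency_s: float = 0.120
    face_response_duration_s: float = 0.300
    bold_response_amplitude: float = 1.0
    bold_noise_sd: float = 0.5
    bold_drift_slope: float = 0.005
    n_voxels_active: int = 40
    n_voxels_deactive: int = 40
    n_voxels_null: int = 120
    seed: Optional[int] = None

    def validate(self) -> "PipelineConfig":
        for name in ("z_p05", "z_p01", "z_p001", "latency_k", "notch_width_hz",
                     "bin_rate_hz", "smooth_window_s", "min_duration_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.aggregate not in ("average", "concatenate"):
            raise InvalidParameterError("aggregate must be 'average' or 'concatenate'")
        if self.base_mode not in ("6+12", "6"):
            raise InvalidParameterError("base_mode must be '6+12' or '6'")
        if self.baseline_method not in ("samples", "bootstrap"):
            raise InvalidParameterError("baseline_method must be 'samples' or 'bootstrap'")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config merged over the defaults; unknown keys are an error."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise InvalidParameterError(f"{path}: config must be a YAML mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise InvalidParameterError(f"unknown config key(s): {sorted(unknown)}")
    if "amplitude_window_s" in values:
        values["amplitude_window_s"] = tuple(values["amplitude_window_s"])
    return PipelineConfig(**values).validate()
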