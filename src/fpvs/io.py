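"""Readers and writers: spike CSV tables, NIfTI volumes, provenance records."""
from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BoldRunData, SpikeTrain
from .exceptions import InvalidParameterError

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_bold_nifti",
    "read_bold_nifti",
    "write_provenance",
]

logger = logging.getLogger(__name__)

SPIKE_COLUMNS = ["unit_id", "sequence_id", "spike_time_s"]


def write_spike_csv(trains: Sequence[SpikeTrain], path) -> None:
    """Write spike trains as tidy CSV (unit_id, sequence_id, spike_time_s)."""
    frames = [
        pd.DataFrame(
            {
                "unit_id": t.unit_id,
                "sequence_id": t.sequence_id,
                "spike_time_s": t.times_s,
            }
        )
        for t in trains
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SPIKE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_spike_csv(path, duration_s: float = 70.0) -> List[SpikeTrain]:
    """Read spike trains, one per (unit, sequence), validating event times.

    Rows with non-numeric or out-of-range times raise an error naming the
    offending line; an empty file yields an empty list with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: no spikes found", path)
        return []
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = times.isna() | (times < 0) | (times >= duration_s)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based, after header
        raise InvalidParameterError(
            f"{path}: invalid spike time {df['spike_time_s'].iloc[line - 2]!r} on line {line}"
        )
    df["spike_time_s"] = times
    return [
        SpikeTrain(g["spike_time_s"].to_numpy(), duration_s, str(uid), int(seq))
        for (uid, seq), g in df.groupby(["unit_id", "sequence_id"], sort=True)
    ]


def write_bold_nifti(data: np.ndarray, path, tr_s: float = 1.5) -> None:
    """Write a 4-D array as NIfTI with an identity affine and TR in the header."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr_s))
    nib.save(img, str(path))


def read_bold_nifti(
    paths: Union[str, Path, Sequence],
    tr_s: float = 1.5,
    dummy_s: float = 9.0,
) -> BoldRunData:
    """Load one or more runs, trim dummy scans, and average volume-wise.

    The leading ``dummy_s / tr_s`` volumes of each run are discarded; runs
    must share a grid (an error lists the offending shapes otherwise).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    n_dummy = int(round(dummy_s / tr_s))
    arrays = []
    shapes = []
    for p in paths:
        arr = np.asarray(nib.load(str(p)).get_fdata(), dtype=float)
        shapes.append(arr.shape)
        arrays.append(arr[..., n_dummy:])
    if len({s for s in shapes}) > 1:
        raise InvalidParameterError(f"inconsistent run shapes: {shapes}")
    return BoldRunData(data=np.mean(arrays, axis=0), tr_s=float(tr_s))


def write_provenance(path, config: dict, seed: Optional[int] = None, command: str = "") -> None:
    """Record everything needed to reproduce an output directory bit-for-bit."""
    import scipy

    from . import __version__

    record = {
        "package": "fpvs",
        "version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "command": command,
        "seed": seed,
        "config": config,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
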