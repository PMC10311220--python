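"""Readers and writers for the pipeline's open file contracts.

Spike times travel as 2/3-column CSV (electrode_id, time_s[,
amplitude_uV]); voltage as an HDF5 dataset with sampling-rate/unit
attributes or as raw float32 plus a JSON sidecar; images as
single-channel TIFFs; ground truth as JSON.  Arbors use SWC via
:mod:`neuroagg.morpho`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import h5py
import tifffile

from .ephys import SpikeTrain, VoltageTrace
from .synth import GroundTruth

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_voltage_h5",
    "read_voltage_h5",
    "write_voltage_raw",
    "read_voltage_raw",
    "read_voltage",
    "write_image",
    "read_image",
    "write_ground_truth",
    "read_points_csv",
]


def write_spike_csv(trains: List[SpikeTrain] | SpikeTrain, path) -> None:
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    rows = []
    for tr in trains:
        amps = tr.amplitudes if tr.amplitudes is not None else np.full(tr.n_spikes, np.nan)
        for t, a in zip(tr.times, amps):
            rows.append({"electrode_id": tr.electrode_id, "time_s": t, "amplitude_uV": a})
    df = pd.DataFrame(rows, columns=["electrode_id", "time_s", "amplitude_uV"])
    df.to_csv(path, index=False, float_format="%.9g")


def read_spike_csv(path, duration: Optional[float] = None) -> List[SpikeTrain]:
    """Read spike trains grouped by electrode.

    ``duration`` is the recording length in seconds; if omitted it is
    taken as the latest spike time (a lower bound, adequate only for
    burst detection).
    """
    df = pd.read_csv(path)
    if "electrode_id" not in df.columns or "time_s" not in df.columns:
        raise ValueError("spike CSV needs electrode_id and time_s columns")
    trains = []
    for eid, grp in df.groupby("electrode_id", sort=True):
        times = np.sort(grp["time_s"].to_numpy(dtype=float))
        dur = duration if duration is not None else (float(times[-1]) if times.size else 0.0)
        amps = None
        if "amplitude_uV" in grp.columns and not grp["amplitude_uV"].isna().all():
            amps = grp.sort_values("time_s")["amplitude_uV"].to_numpy(dtype=float)
        trains.append(SpikeTrain(str(eid), times, dur, amps))
    return trains


def write_voltage_h5(trace: VoltageTrace, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("voltage", data=trace.samples.astype(np.float32))
        ds.attrs["sampling_rate"] = trace.sampling_rate
        ds.attrs["units"] = "uV"
        ds.attrs["electrode_id"] = trace.electrode_id


def read_voltage_h5(path) -> VoltageTrace:
    with h5py.File(path, "r") as fh:
        ds = fh["voltage"]
        return VoltageTrace(
            np.asarray(ds[...], dtype=float),
            float(ds.attrs["sampling_rate"]),
            str(ds.attrs.get("electrode_id", "e0")),
        )


def write_voltage_raw(trace: VoltageTrace, path) -> None:
    """Raw little-endian float32 samples plus a JSON sidecar (<path>.json)."""
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    sidecar = {
        "sampling_rate": trace.sampling_rate,
        "units": "uV",
        "dtype": "<f4",
        "electrode_id": trace.electrode_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_voltage_raw(path) -> VoltageTrace:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = np.fromfile(path, dtype=meta.get("dtype", "<f4"))
    return VoltageTrace(
        samples.astype(float), float(meta["sampling_rate"]), str(meta.get("electrode_id", "e0"))
    )


def read_voltage(path) -> VoltageTrace:
    """Dispatch on extension: .h5/.hdf5 -> HDF5, otherwise raw + sidecar."""
    if str(path).endswith((".h5", ".hdf5")):
        return read_voltage_h5(path)
    return read_voltage_raw(path)


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        k: _jsonable(v)
        for k, v in dataclasses.asdict(truth).items()
        if v is not None
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_points_csv(path) -> np.ndarray:
    """Read an (n, 2) point table with columns x_um, y_um."""
    df = pd.read_csv(path)
    if not {"x_um", "y_um"} <= set(df.columns):
        raise ValueError("points CSV needs x_um and y_um columns")
    return df[["x_um", "y_um"]].to_numpy(dtype=float)
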