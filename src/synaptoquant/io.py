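"""File formats: HDF5 traces, CSV tables, JSON ground truth, TIFF stacks.

Arrays are SI internally; tables use display units (pA, pS, fF, ms) in
their column names.  Every writer's output is readable by its reader with
lossless numeric content.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import AmperometricTrace, ImageStack, LockInTrace, PatchCurrentTrace
from .capacitance import CapacitanceEvent
from .synthetic import GroundTruth

__all__ = [
    "write_lockin_h5", "read_lockin_h5",
    "write_current_h5", "read_current_h5",
    "write_amperometric_h5", "read_amperometric_h5",
    "write_ground_truth", "read_ground_truth",
    "events_to_csv", "read_events_csv",
    "write_stack_tiff", "read_stack_tiff",
    "write_json",
]


def write_lockin_h5(path, trace: LockInTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=trace.time)
        f.create_dataset("Re", data=trace.Re)
        f.create_dataset("Im", data=trace.Im)
        f.attrs["units"] = "s,S,S"
        f.attrs["sampling_rate"] = trace.sampling_rate
        f.attrs["lockin_frequency"] = trace.lockin_frequency


def read_lockin_h5(path) -> LockInTrace:
    with h5py.File(path, "r") as f:
        return LockInTrace(
            time=f["time"][:], Re=f["Re"][:], Im=f["Im"][:],
            sampling_rate=float(f.attrs["sampling_rate"]),
            lockin_frequency=float(f.attrs["lockin_frequency"]),
        )


def write_current_h5(path, trace: PatchCurrentTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=trace.time)
        f.create_dataset("I", data=trace.I)
        f.attrs["units"] = "s,A"
        f.attrs["V_patch"] = trace.V_patch
        f.attrs["filter_hz"] = trace.filter_hz
        if trace.t_event is not None:
            f.attrs["t_event"] = trace.t_event


def read_current_h5(path) -> PatchCurrentTrace:
    with h5py.File(path, "r") as f:
        return PatchCurrentTrace(
            time=f["time"][:], I=f["I"][:],
            V_patch=float(f.attrs["V_patch"]),
            filter_hz=float(f.attrs["filter_hz"]),
            t_event=float(f.attrs["t_event"]) if "t_event" in f.attrs else None,
        )


def write_amperometric_h5(path, trace: AmperometricTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=trace.time)
        f.create_dataset("I", data=trace.I)
        f.attrs["units"] = "s,A"
        f.attrs["sampling_rate"] = trace.sampling_rate
        f.attrs["stim_time"] = trace.stim_time


def read_amperometric_h5(path) -> AmperometricTrace:
    with h5py.File(path, "r") as f:
        return AmperometricTrace(
            time=f["time"][:], I=f["I"][:],
            sampling_rate=float(f.attrs["sampling_rate"]),
            stim_time=float(f.attrs["stim_time"]),
        )


def write_ground_truth(path, truth: GroundTruth) -> None:
    Path(path).write_text(truth.to_json(indent=1) + "\n")


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def events_to_csv(path, events: Sequence[CapacitanceEvent], cell_id: str) -> None:
    """Per-event table in display units (fF, ms, pS)."""
    rows = []
    for e in events:
        rows.append({
            "cell_id": cell_id,
            "t_step_s": e.t_step,
            "direction": e.direction,
            "Cv_fF": e.cv * 1e15,
            "duration_ms": None if e.fission_pore_duration is None
            else e.fission_pore_duration * 1e3,
            "Gp_mean_pS": None if e.gp_mean is None else e.gp_mean * 1e12,
            "kinetics_valid": e.kinetics_valid,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stack_tiff(path, stack: ImageStack) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     metadata={"frame_times": stack.frame_times.tolist()})


def read_stack_tiff(path, frame_times=None) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        if frame_times is None:
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
            frame_times = meta.get("frame_times")
    if frame_times is None:
        frame_times = np.arange(frames.shape[0], dtype=float)
    return ImageStack(frames=frames.astype(float), frame_times=np.asarray(frame_times))


def write_json(path, obj) -> None:
    """Deterministic JSON: sorted keys, newline-terminated."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, default=default) + "\n")
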