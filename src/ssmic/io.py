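"""Reading and writing the pipeline's on-disk formats.

Image stacks are stored as one multi-page TIFF per channel plus a JSON
sidecar carrying the physical calibration (pixel size, z-step, frame time)
and, for synthetic data, the ground truth.  Trajectories and force curves
travel as CSV with header comments, using the common SPT column convention
(track_id, frame, x_um, y_um, intensity).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceCurve
from .imgproc import ImageStack
from .spt import Trajectory

__all__ = [
    "save_stack", "load_stack",
    "trajectories_to_frame", "frame_to_trajectories",
    "save_trajectories", "load_trajectories",
    "save_force_curve", "load_force_curve",
]


def save_stack(stack: ImageStack, directory, name: str = "stack", truth=None):
    """Write one TIFF per channel and a JSON calibration sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, ch in enumerate(stack.channel_names):
        tifffile.imwrite(directory / f"{name}_{ch}.tif",
                         np.asarray(stack.pixels[i], dtype=np.float32))
    meta = {
        "channels": list(stack.channel_names),
        "pixel_size_um": stack.pixel_size,
        "z_step_um": stack.z_step,
        "frame_time_s": stack.frame_time,
    }
    if truth is not None:
        meta["truth"] = _jsonable(truth)
    with open(directory / f"{name}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_stack(directory, name: str = "stack") -> ImageStack:
    """Load a stack written by :func:`save_stack`."""
    directory = Path(directory)
    with open(directory / f"{name}.json") as fh:
        meta = json.load(fh)
    planes = [tifffile.imread(directory / f"{name}_{ch}.tif")
              for ch in meta["channels"]]
    return ImageStack(np.stack(planes), pixel_size=meta["pixel_size_um"],
                      z_step=meta["z_step_um"], frame_time=meta["frame_time_s"],
                      channel_names=list(meta["channels"]))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        if obj.dtype == bool:
            return {"__bool_array__": obj.astype(np.uint8).tolist()}
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def trajectories_to_frame(trajectories) -> pd.DataFrame:
    """Flatten trajectories into a tidy table (track_id, frame, x_um, y_um, intensity)."""
    rows = []
    for tr in trajectories:
        inten = tr.intensities if tr.intensities is not None else np.full(len(tr), np.nan)
        for f, (x, y), i in zip(tr.frames, tr.positions, inten):
            rows.append((tr.track_id, int(f), float(x), float(y), float(i)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "intensity"])


def frame_to_trajectories(df: pd.DataFrame, frame_time: float = 0.050):
    """Rebuild Trajectory objects from a tidy trajectory table."""
    out = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        inten = grp["intensity"].to_numpy() if "intensity" in grp else None
        out.append(Trajectory(frames=grp["frame"].to_numpy(),
                              positions=grp[["x_um", "y_um"]].to_numpy(),
                              frame_time=frame_time, intensities=inten,
                              track_id=int(tid)))
    return out


def save_trajectories(trajectories, path, frame_time: float | None = None):
    path = Path(path)
    if frame_time is None and trajectories:
        frame_time = trajectories[0].frame_time
    with open(path, "w") as fh:
        fh.write(f"# frame_time_s={frame_time}\n")
        trajectories_to_frame(trajectories).to_csv(fh, index=False)


def load_trajectories(path):
    path = Path(path)
    frame_time = 0.050
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            frame_time = float(first.strip().split("=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return frame_to_trajectories(df, frame_time=frame_time)


def save_force_curve(curve: ForceCurve, path):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# spring_constant_n_per_m={curve.spring_constant}\n")
        fh.write(f"# ramp_size_um={curve.ramp_size}\n")
        fh.write(f"# ramp_speed_um_per_s={curve.ramp_speed}\n")
        pd.DataFrame({"z_um": curve.z_um,
                      "deflection_um": curve.deflection_um}).to_csv(fh, index=False)


def load_force_curve(path) -> ForceCurve:
    path = Path(path)
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, val = line[1:].strip().split("=")
            header[key.strip()] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return ForceCurve(z_um=df["z_um"].to_numpy(),
                      deflection_um=df["deflection_um"].to_numpy(),
                      spring_constant=header.get("spring_constant_n_per_m", 0.03),
                      ramp_size=header.get("ramp_size_um", 5.0),
                      ramp_speed=header.get("ramp_speed_um_per_s", 10.0))
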