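"""File formats: HDF5 pose layout, ethogram CSVs, and ground-truth storage.

Pose layout: ``/tracks`` (frames x nodes x 2 float, NaN = missing),
``/node_names`` (strings), attrs ``fps``, ``px_per_mm``, ``t0_clock`` (ISO
string or empty), ``fly_id``.  Ground truth, when present, lives under
``/truth``.
"""
from __future__ import annotations

from datetime import datetime
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ethogram import Ethogram
from .preprocess import PoseSequence
from .synth import GroundTruth

__all__ = ["SchemaError", "save_pose", "load_pose", "save_ethogram_csv",
           "load_ethogram_csv", "save_bouts_csv"]


class SchemaError(ValueError):
    """A required dataset or attribute is absent from a pose file."""


def save_pose(pose: PoseSequence, path, truth: GroundTruth | None = None) -> None:
    tracks = pose.coords.copy()
    tracks[pose.missing] = np.nan
    with h5py.File(path, "w") as f:
        f.create_dataset("tracks", data=tracks)
        f.create_dataset("node_names", data=np.array(pose.node_names, dtype="S32"))
        f.attrs["fps"] = pose.fps
        f.attrs["px_per_mm"] = pose.px_per_mm
        f.attrs["t0_clock"] = pose.t0_clock.isoformat() if pose.t0_clock else ""
        f.attrs["fly_id"] = pose.fly_id
        if truth is not None:
            g = f.create_group("truth")
            if truth.true_ethogram is not None:
                g.create_dataset("ethogram", data=np.asarray(truth.true_ethogram, dtype="S24"))
            g.create_dataset("edge_mask", data=truth.true_edge_mask)
            g.create_dataset("missing_mask", data=truth.true_missing_mask)


def load_pose(path, with_truth: bool = False):
    with h5py.File(path, "r") as f:
        for required in ("tracks", "node_names"):
            if required not in f:
                raise SchemaError(f"pose file missing dataset {required!r}")
        tracks = f["tracks"][...]
        node_names = tuple(s.decode() for s in f["node_names"][...])
        t0 = str(f.attrs.get("t0_clock", "")) or None
        pose = PoseSequence(
            coords=np.nan_to_num(tracks),
            missing=np.isnan(tracks).any(axis=2),
            fps=float(f.attrs.get("fps", 100.0)),
            px_per_mm=float(f.attrs.get("px_per_mm", 28.25)),
            t0_clock=datetime.fromisoformat(t0) if t0 else None,
            fly_id=str(f.attrs.get("fly_id", "fly0")),
            node_names=node_names,
        )
        # NaN coordinates are missing-mask entries; keep NaN in coords there
        pose.coords[pose.missing] = np.nan
        if not with_truth:
            return pose
        truth = None
        if "truth" in f:
            g = f["truth"]
            etho = g["ethogram"][...].astype("U24") if "ethogram" in g else None
            truth = GroundTruth(
                true_ethogram=etho,
                true_edge_mask=g["edge_mask"][...].astype(bool),
                true_missing_mask=g["missing_mask"][...].astype(bool),
            )
    return pose, truth


def save_ethogram_csv(etho: Ethogram, path, run_length: bool = False) -> None:
    path = Path(path)
    if run_length:
        from .ethogram import extract_bouts
        rows = [(b.behavior, b.start_frame, b.end_frame) for b in extract_bouts(etho)]
        df = pd.DataFrame(rows, columns=["label", "start_frame", "end_frame"])
    else:
        df = pd.DataFrame({"frame": np.arange(etho.n_frames), "label": etho.labels})
    df.to_csv(path, index=False)


def load_ethogram_csv(path, fps: float = 100.0, fly_id: str = "fly0") -> Ethogram:
    df = pd.read_csv(path)
    if {"label", "start_frame", "end_frame"} <= set(df.columns):
        n = int(df["end_frame"].max()) if len(df) else 0
        labels = np.empty(n, dtype="U20")
        for _, row in df.iterrows():
            labels[int(row["start_frame"]):int(row["end_frame"])] = row["label"]
    elif {"frame", "label"} <= set(df.columns):
        labels = df.sort_values("frame")["label"].to_numpy(dtype="U20")
    else:
        raise SchemaError("ethogram CSV needs (frame,label) or (label,start_frame,end_frame)")
    return Ethogram(labels=labels, fps=fps, fly_id=fly_id)


def save_bouts_csv(etho: Ethogram, path) -> None:
    from .ethogram import extract_bouts
    rows = [(b.behavior, b.start_frame, b.end_frame, b.duration_frames / etho.fps)
            for b in extract_bouts(etho)]
    pd.DataFrame(rows, columns=["behavior", "start", "end", "duration_s"]).to_csv(path, index=False)
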