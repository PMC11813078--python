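"""Pose cleaning: gap interpolation, median/Gaussian smoothing, egocentric alignment.

The cleaning chain is interpolate -> smooth -> egocentrize.  Head and thorax
are fully interpolated (they anchor the egocentric frame); all other nodes are
only interpolated across short gaps; proboscis falls back to the head position
(a retracted proboscis).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import PchipInterpolator

from ._alphabet import HEAD, N_NODES, NODE_NAMES, PROBOSCIS, THORAX

__all__ = [
    "PoseSequence",
    "EgocentricPose",
    "ArenaGeometry",
    "interpolate_pose",
    "smooth_pose",
    "egocentrize",
    "invert_egocentrize",
]


@dataclass
class PoseSequence:
    """Keypoint tracks for one fly: ``coords`` in px, frames x nodes x 2."""

    coords: np.ndarray
    missing: np.ndarray
    fps: float = 100.0
    px_per_mm: float = 28.25
    t0_clock: datetime | None = None
    fly_id: str = "fly0"
    node_names: tuple[str, ...] = NODE_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_NODES, 2):
            raise ValueError(f"coords must be (frames, {N_NODES}, 2), got {self.coords.shape}")
        if self.missing.shape != self.coords.shape[:2]:
            raise ValueError("missing mask must be (frames, nodes)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if len(set(self.node_names)) != N_NODES or not {"head", "thorax", "proboscis"} <= set(self.node_names):
            raise ValueError("node_names must be 14 unique names including head/thorax/proboscis")
        observed = ~self.missing
        if not np.all(np.isfinite(self.coords[observed])):
            raise ValueError("coords must be finite wherever not missing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "PoseSequence":
        return replace(self, coords=self.coords.copy(), missing=self.missing.copy())


@dataclass
class EgocentricPose:
    """Body-frame pose in mm: thorax at the origin, head on the +x axis."""

    coords: np.ndarray          # frames x nodes x 2, mm; NaN where missing
    missing: np.ndarray         # frames x nodes
    heading: np.ndarray         # radians rotated away per frame
    origin: np.ndarray          # thorax position, px, per frame
    fps: float = 100.0
    px_per_mm: float = 28.25
    fly_id: str = "fly0"
    node_names: tuple[str, ...] = NODE_NAMES

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class ArenaGeometry:
    center_px: tuple[float, float]
    radius_px: float
    px_per_mm: float = 28.25

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("arena radius must be positive")


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a 1-D boolean mask."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def _pchip_fill_full(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Fill every missing frame: PCHIP in the interior, nearest-value at the ends."""
    out = values.copy()
    obs = np.flatnonzero(~missing)
    if obs.size == 0:
        raise ValueError("node has no observed frames")
    gaps = np.flatnonzero(missing)
    if gaps.size == 0:
        return out
    if obs.size == 1:
        out[gaps] = values[obs[0]]
        return out
    interior = gaps[(gaps > obs[0]) & (gaps < obs[-1])]
    if interior.size:
        interp = PchipInterpolator(obs, values[obs])
        out[interior] = interp(interior)
    out[gaps[gaps < obs[0]]] = values[obs[0]]
    out[gaps[gaps > obs[-1]]] = values[obs[-1]]
    return out


def interpolate_pose(pose: PoseSequence, gap_limit: int = 5) -> PoseSequence:
    """Fill missing keypoints.

    Head and thorax are interpolated across gaps of any length (PCHIP per
    coordinate; leading/trailing runs held at the nearest observation).  Every
    other node except the proboscis is PCHIP-interpolated only across interior
    gaps of at most ``gap_limit`` consecutive missing frames.  Missing
    proboscis frames are then set to the post-interpolation head position.

    Idempotent; never modifies observed values.
    """
    coords = pose.coords.copy()
    missing = pose.missing.copy()
    if pose.n_frames == 0:
        return pose.copy()

    names = pose.node_names
    head, thorax, prob = names.index("head"), names.index("thorax"), names.index("proboscis")

    for node in (head, thorax):
        m = missing[:, node]
        if m.all():
            raise ValueError(f"{names[node]} has no observed frames; cannot egocentrize")
        for c in range(2):
            coords[:, node, c] = _pchip_fill_full(coords[:, node, c], m)
        missing[:, node] = False

    for node in range(len(names)):
        if node in (head, thorax, prob):
            continue
        m = missing[:, node]
        if not m.any():
            continue
        if m.all():
            warnings.warn(f"node {names[node]} has no observed frames; left missing")
            continue
        obs = np.flatnonzero(~m)
        fillable: list[np.ndarray] = []
        for start, end in _missing_runs(m):
            if end - start <= gap_limit and start > obs[0] and end <= obs[-1]:
                fillable.append(np.arange(start, end))
        if fillable:
            idx = np.concatenate(fillable)
            if obs.size >= 2:
                interp = PchipInterpolator(obs, coords[obs, node, :])
                coords[idx, node, :] = interp(idx)
            else:
                coords[idx, node, :] = coords[obs[0], node, :]
            missing[idx, node] = False

    # retracted proboscis: adopt the (now complete) head track
    pm = missing[:, prob]
    coords[pm, prob, :] = coords[pm, head, :]
    missing[:, prob] = False

    coords[missing] = np.nan
    return replace(pose, coords=coords, missing=missing)


def _masked_window_stack(values: np.ndarray, window: int) -> np.ndarray:
    """(n, window) view of a NaN-padded trace centered on each frame."""
    half = window // 2
    padded = np.full(values.size + 2 * half, np.nan)
    padded[half:half + values.size] = values
    return sliding_window_view(padded, window)


def smooth_pose(pose: PoseSequence, median_window: int = 5,
                gauss_sd: float = 1.0, gauss_window: int = 5) -> PoseSequence:
    """Median filter (window 5) then Gaussian filter (sigma 1, window 5) per trace.

    Missing frames stay missing and are excluded from every window; kernels are
    renormalized over the available in-window samples (shrink-window boundary
    handling).
    """
    coords = pose.coords.copy()
    missing = pose.missing
    n = pose.n_frames
    if n == 0:
        return pose.copy()
    offsets = np.arange(gauss_window) - gauss_window // 2
    kernel = np.exp(-0.5 * (offsets / gauss_sd) ** 2)
    for node in range(coords.shape[1]):
        m = missing[:, node]
        if m.all():
            continue
        for c in range(2):
            trace = coords[:, node, c].copy()
            trace[m] = np.nan
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(_masked_window_stack(trace, median_window), axis=1)
            med[m] = np.nan
            windows = _masked_window_stack(med, gauss_window)
            weights = np.where(np.isnan(windows), 0.0, kernel)
            wsum = weights.sum(axis=1)
            smoothed = np.nansum(windows * weights, axis=1) / np.where(wsum == 0, np.nan, wsum)
            out = coords[:, node, c]
            out[~m] = smoothed[~m]
    coords[missing] = np.nan
    return replace(pose, coords=coords, missing=missing.copy())


def egocentrize(pose: PoseSequence) -> EgocentricPose:
    """Translate thorax to the origin and rotate the thorax->head axis onto +x.

    Requires head and thorax present at every frame (run interpolate_pose
    first).  Output coordinates are in mm.  If head and thorax coincide the
    previous frame's heading is reused (an error at frame 0).
    """
    names = pose.node_names
    head, thorax = names.index("head"), names.index("thorax")
    if pose.missing[:, [head, thorax]].any():
        raise ValueError("head and thorax must be non-missing at every frame")
    origin = pose.coords[:, thorax, :].copy()
    vec = pose.coords[:, head, :] - origin
    norm = np.hypot(vec[:, 0], vec[:, 1])
    heading = np.arctan2(vec[:, 1], vec[:, 0])
    degenerate = np.flatnonzero(norm == 0)
    if degenerate.size and degenerate[0] == 0:
        raise ValueError("head coincides with thorax at frame 0; heading undefined")
    for i in degenerate:
        heading[i] = heading[i - 1]

    rel = pose.coords - origin[:, None, :]
    cos, sin = np.cos(-heading), np.sin(-heading)
    rotated = np.empty_like(rel)
    rotated[..., 0] = cos[:, None] * rel[..., 0] - sin[:, None] * rel[..., 1]
    rotated[..., 1] = sin[:, None] * rel[..., 0] + cos[:, None] * rel[..., 1]
    coords_mm = rotated / pose.px_per_mm
    coords_mm[pose.missing] = np.nan
    return EgocentricPose(
        coords=coords_mm, missing=pose.missing.copy(), heading=heading,
        origin=origin, fps=pose.fps, px_per_mm=pose.px_per_mm,
        fly_id=pose.fly_id, node_names=names,
    )


def invert_egocentrize(ego: EgocentricPose) -> np.ndarray:
    """Reconstruct world-frame px coordinates from an EgocentricPose."""
    px = ego.coords * ego.px_per_mm
    cos, sin = np.cos(ego.heading), np.sin(ego.heading)
    out = np.empty_like(px)
    out[..., 0] = cos[:, None] * px[..., 0] - sin[:, None] * px[..., 1]
    out[..., 1] = sin[:, None] * px[..., 0] + cos[:, None] * px[..., 1]
    return out + ego.origin[:, None, :]
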