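"""Non-compositional behavioral statistics: Zeitgeber time, locomotion speed,
bout-duration summaries, and radial occupancy."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

from ._alphabet import ALL_LABELS, THORAX
from .preprocess import ArenaGeometry, PoseSequence

__all__ = [
    "ZTStamp", "SpeedSeries",
    "zeitgeber_time", "frame_zeitgeber",
    "locomotion_speed", "speed_by_group",
    "bout_duration_stats", "radial_occupancy",
]


@dataclass(frozen=True)
class ZTStamp:
    zt_hours: float      # in [0, 24)
    day_index: int       # >= 1, increments at each lights-on


def _lights_anchor(start: datetime, lights_on: time | float) -> datetime:
    if isinstance(lights_on, (int, float)):
        lights_on = time(hour=int(lights_on), minute=int(round((lights_on % 1) * 60)))
    anchor = datetime.combine(start.date(), lights_on)
    if anchor > start:
        anchor -= timedelta(days=1)
    return anchor


def zeitgeber_time(clock: datetime, lights_on_clock: time | float,
                   experiment_start: datetime | None = None) -> ZTStamp:
    """ZT stamp of a wall-clock time: hours since the most recent lights-on,
    wrapped to [0, 24); ZT 12 is lights-off.  ``day_index`` counts lights-on
    events since the experiment start (the first day is 1)."""
    start = experiment_start if experiment_start is not None else clock
    if clock < start:
        raise ValueError("clock precedes experiment start")
    anchor = _lights_anchor(start, lights_on_clock)
    hours = (clock - anchor).total_seconds() / 3600.0
    return ZTStamp(zt_hours=hours % 24.0, day_index=int(hours // 24.0) + 1)


def frame_zeitgeber(etho_or_pose, lights_on_hour: float = 8.0,
                    experiment_start: datetime | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-frame (zt_hours, day_index) for an Ethogram/PoseSequence.

    If the object carries no ``t0_clock``, frame 0 is taken to be lights-on of
    day 1 (ZT 0).
    """
    n = etho_or_pose.n_frames
    fps = etho_or_pose.fps
    t0 = getattr(etho_or_pose, "t0_clock", None)
    if t0 is None:
        zt0_hours = 0.0
    else:
        stamp = zeitgeber_time(t0, lights_on_hour, experiment_start)
        zt0_hours = stamp.zt_hours + (stamp.day_index - 1) * 24.0
    hours = zt0_hours + np.arange(n) / fps / 3600.0
    return hours % 24.0, (hours // 24.0).astype(int) + 1


@dataclass
class SpeedSeries:
    """Per-frame thorax speed (mm/s); NaN outside locomotion-state frames."""

    values: np.ndarray
    window: int
    fps: float


def locomotion_speed(pose: PoseSequence, etho, window: int = 5,
                     behavior: str = "locomotion") -> SpeedSeries:
    """Thorax speed during the locomotion state, smoothed with a centered
    rolling mean of ``window`` frames computed within each bout (windows never
    cross bout boundaries; bouts shorter than the window get their plain mean).
    """
    from .ethogram import extract_bouts

    if pose.n_frames != etho.n_frames:
        raise ValueError("pose and ethogram must be frame-aligned")
    thorax = pose.coords[:, pose.node_names.index("thorax"), :]
    inst = np.full(pose.n_frames, np.nan)
    if pose.n_frames >= 2:
        step = np.linalg.norm(np.diff(thorax, axis=0), axis=1)
        inst[:-1] = step * pose.fps / pose.px_per_mm
        inst[-1] = inst[-2] if pose.n_frames >= 2 else np.nan

    out = np.full(pose.n_frames, np.nan)
    for b in extract_bouts(etho):
        if b.behavior != behavior:
            continue
        seg = inst[b.start_frame:b.end_frame]
        if b.duration_frames <= window:
            out[b.start_frame:b.end_frame] = np.nanmean(seg)
        else:
            out[b.start_frame:b.end_frame] = (
                pd.Series(seg).rolling(window, center=True, min_periods=1).mean().to_numpy()
            )
    return SpeedSeries(values=out, window=window, fps=pose.fps)


def speed_by_group(series: SpeedSeries, zt_hours: np.ndarray, day_index: np.ndarray,
                   group_by: str = "zt_hour") -> pd.DataFrame:
    """Mean +/- SE of the speed series grouped by ZT hour or by day."""
    key = np.floor(zt_hours).astype(int) if group_by == "zt_hour" else np.asarray(day_index)
    df = pd.DataFrame({"group": key, "speed": series.values}).dropna()
    return df.groupby("group")["speed"].agg(
        mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n="count").reset_index()


def bout_duration_stats(etho, behavior: str, group_by: str = "zt_hour",
                        lights_on_hour: float = 8.0) -> pd.DataFrame:
    """Mean +/- SE bout duration (seconds) for one behavior, grouped by the ZT
    hour (or day) containing the bout's start frame."""
    from .ethogram import extract_bouts

    if group_by not in ("zt_hour", "day"):
        raise ValueError("group_by must be 'zt_hour' or 'day'")
    zt, day = frame_zeitgeber(etho, lights_on_hour)
    rows = []
    for b in extract_bouts(etho):
        if b.behavior != behavior:
            continue
        key = int(zt[b.start_frame]) if group_by == "zt_hour" else int(day[b.start_frame])
        rows.append({"group": key, "duration_s": b.duration_frames / etho.fps})
    if not rows:
        return pd.DataFrame(columns=["group", "mean", "se", "n"])
    df = pd.DataFrame(rows)
    return df.groupby("group")["duration_s"].agg(
        mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n="count").reset_index()


def radial_occupancy(pose: PoseSequence, arena: ArenaGeometry, etho,
                     n_bins: int = 10) -> pd.DataFrame:
    """Frame occupancy and per-behavior fractions by equal-area radial annulus.

    Bin k spans normalized radius [sqrt(k/n), sqrt((k+1)/n)).  Radii more than
    5% outside the arena are clamped with a warning.
    """
    thorax = pose.coords[:, pose.node_names.index("thorax"), :]
    r = np.linalg.norm(thorax - np.asarray(arena.center_px), axis=1) / arena.radius_px
    if np.any(r > 1.05):
        warnings.warn("thorax outside arena radius by > 5%; clamping")
    r = np.clip(r, 0.0, 1.0 - 1e-12)
    edges = np.sqrt(np.arange(n_bins + 1) / n_bins)
    bins = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_bins - 1)
    labels = np.asarray(etho.labels)
    rows = []
    for k in range(n_bins):
        mask = bins == k
        count = int(mask.sum())
        row = {"bin": k, "r_inner": edges[k], "r_outer": edges[k + 1],
               "n_frames": count, "occupancy": count / max(len(r), 1)}
        for lab in ALL_LABELS:
            row[lab] = float((labels[mask] == lab).mean()) if count else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
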