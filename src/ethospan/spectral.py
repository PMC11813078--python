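"""Rolling Lomb-Scargle spectral features on egocentric pose traces.

The classical (tau-shifted, mean-subtracted) Lomb-Scargle periodogram is
evaluated on centered rolling windows whose length scales inversely with the
probe frequency, so each frequency is probed with a fixed number of periods —
the same envelope scaling a continuous wavelet transform would give.  Missing
samples are simply excluded from the window sums, which is the point of using
Lomb-Scargle on gappy tracking data.

Normalization: a pure sinusoid of amplitude A at an on-grid frequency under
complete even sampling yields power A**2/4 (mm^2) at that frequency.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EgocentricPose

__all__ = [
    "FrequencyGrid",
    "SpectralFeatures",
    "lomb_scargle",
    "rolling_spectral_features",
    "total_spectral_amplitude",
]

DEFAULT_AMPLITUDE_THRESHOLD = 0.5012  # mm^2, idle/moving separatrix


@dataclass
class FrequencyGrid:
    """Ordered positive probe frequencies (Hz)."""

    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.freqs_hz.ndim != 1 or self.freqs_hz.size == 0:
            raise ValueError("freqs_hz must be a non-empty 1-D array")
        if np.any(self.freqs_hz <= 0) or np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly increasing and positive")

    @classmethod
    def dyadic(cls, n_freqs: int = 25, f_min: float = 0.5, f_max: float = 25.0) -> "FrequencyGrid":
        """Geometrically (log2-evenly) spaced grid, default 25 points in [0.5, 25] Hz."""
        return cls(np.geomspace(f_min, f_max, n_freqs))

    @property
    def n_freqs(self) -> int:
        return self.freqs_hz.size


@dataclass
class SpectralFeatures:
    """Per-frame concatenated Lomb-Scargle powers, one column per (node, coord, freq)."""

    power: np.ndarray                 # n_out x (n_channels * n_freqs), mm^2
    valid: np.ndarray                 # n_out bool
    frame_index: np.ndarray           # original frame of each output row
    freqs_hz: np.ndarray
    channel_index: list               # column -> (node_name, 'x'|'y', freq_hz)
    fps: float

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]


def _ls_power_from_sums(N, Y, YC, YS, C, S, CC, SS, CS):
    """Classical Lomb-Scargle power from masked window sums; power = P / N."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = np.where(N > 0, Y / np.maximum(N, 1), 0.0)
        YCc = YC - ybar * C
        YSc = YS - ybar * S
        phi = 0.5 * np.arctan2(2.0 * CS, CC - SS)
        a, b = np.cos(phi), np.sin(phi)
        num1 = (a * YCc + b * YSc) ** 2
        den1 = a * a * CC + 2 * a * b * CS + b * b * SS
        num2 = (a * YSc - b * YCc) ** 2
        den2 = a * a * SS - 2 * a * b * CS + b * b * CC
        t1 = np.where(den1 > 1e-12, num1 / np.maximum(den1, 1e-300), 0.0)
        t2 = np.where(den2 > 1e-12, num2 / np.maximum(den2, 1e-300), 0.0)
        power = 0.5 * (t1 + t2) / np.maximum(N, 1)
    return np.where(N >= 2, power, np.nan)


def lomb_scargle(times: np.ndarray, values: np.ndarray, freqs: FrequencyGrid | np.ndarray) -> np.ndarray:
    """Classical Lomb-Scargle periodogram of one unevenly sampled signal.

    Parameters
    ----------
    times : seconds of the observed samples
    values : signal values (mm); NaNs are treated as missing
    freqs : probe frequencies (Hz)

    Returns
    -------
    power per frequency (mm^2); all-NaN if fewer than 2 observed samples.
    """
    f = freqs.freqs_hz if isinstance(freqs, FrequencyGrid) else np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values) & np.isfinite(times)
    t, y = times[keep], values[keep]
    if np.unique(t).size < 2:
        return np.full(f.shape, np.nan)
    w = 2.0 * np.pi * f[:, None]
    c, s = np.cos(w * t), np.sin(w * t)
    N = float(t.size)
    power = _ls_power_from_sums(
        N, y.sum(), c @ y, s @ y, c.sum(axis=1), s.sum(axis=1),
        (c * c).sum(axis=1), (s * s).sum(axis=1), (c * s).sum(axis=1),
    )
    return power


def _window_bounds(n: int, centers: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    half = length // 2
    lo = np.maximum(centers - half, 0)
    hi = np.minimum(centers + half + 1, n)
    return lo, hi


def rolling_spectral_features(
    ego: EgocentricPose,
    grid: FrequencyGrid | None = None,
    window_periods: float = 5.0,
    stride: int = 1,
    min_occupancy: float = 0.5,
    min_window_frames: int = 5,
) -> SpectralFeatures:
    """Per-frame Lomb-Scargle powers for every node-coordinate channel.

    For each frequency f the window is centered and ``window_periods / f``
    seconds long (at least ``min_window_frames`` frames).  The thorax is
    excluded (identically zero in the egocentric frame).  Frames whose window
    occupancy drops below ``min_occupancy`` for any channel are marked invalid.
    ``stride`` subsamples the output frames; window sums still use every input
    frame.
    """
    if grid is None:
        grid = FrequencyGrid.dyadic()
    n = ego.n_frames
    fps = ego.fps
    if grid.freqs_hz[-1] >= fps / 2:
        raise ValueError("f_max must be below the Nyquist frequency")
    nodes = [i for i, name in enumerate(ego.node_names) if name != "thorax"]
    nf = grid.n_freqs
    centers = np.arange(0, n, max(int(stride), 1))
    n_out = centers.size
    power = np.zeros((n_out, len(nodes) * 2 * nf))
    valid = np.ones(n_out, dtype=bool)

    t = np.arange(n) / fps
    masks = {node: (~ego.missing[:, node]).astype(float) for node in nodes}
    mask_cums = {node: np.concatenate([[0.0], np.cumsum(m)]) for node, m in masks.items()}

    def wsum(cum, lo, hi):
        return cum[hi] - cum[lo]

    for k, f in enumerate(grid.freqs_hz):
        length = max(min_window_frames, int(round(window_periods / f * fps)))
        lo, hi = _window_bounds(n, centers, length)
        span = (hi - lo).astype(float)
        w = 2.0 * np.pi * f
        c, s = np.cos(w * t), np.sin(w * t)
        cc, ss, cs = c * c, s * s, c * s
        for node in nodes:
            m = masks[node]
            N = wsum(mask_cums[node], lo, hi)
            C = wsum(np.concatenate([[0.0], np.cumsum(m * c)]), lo, hi)
            S = wsum(np.concatenate([[0.0], np.cumsum(m * s)]), lo, hi)
            CC = wsum(np.concatenate([[0.0], np.cumsum(m * cc)]), lo, hi)
            SS = wsum(np.concatenate([[0.0], np.cumsum(m * ss)]), lo, hi)
            CS = wsum(np.concatenate([[0.0], np.cumsum(m * cs)]), lo, hi)
            node_pos = nodes.index(node)
            for coord in range(2):
                y = np.where(m > 0, np.nan_to_num(ego.coords[:, node, coord]), 0.0)
                Y = wsum(np.concatenate([[0.0], np.cumsum(y)]), lo, hi)
                YC = wsum(np.concatenate([[0.0], np.cumsum(y * c)]), lo, hi)
                YS = wsum(np.concatenate([[0.0], np.cumsum(y * s)]), lo, hi)
                p = _ls_power_from_sums(N, Y, YC, YS, C, S, CC, SS, CS)
                col = (node_pos * 2 + coord) * nf + k
                power[:, col] = np.nan_to_num(p)
            valid &= (N / span) >= min_occupancy
            valid &= N >= 2

    channel_index = [
        (ego.node_names[node], "xy"[coord], float(f))
        for node in nodes for coord in range(2) for f in grid.freqs_hz
    ]
    return SpectralFeatures(
        power=power, valid=valid, frame_index=centers,
        freqs_hz=grid.freqs_hz.copy(), channel_index=channel_index, fps=fps,
    )


def total_spectral_amplitude(features: SpectralFeatures) -> np.ndarray:
    """Sum of power over all channels and frequencies per frame (mm^2).

    Invalid frames return NaN.  Compared downstream against the idle threshold
    (default 0.5012 mm^2).
    """
    total = features.power.sum(axis=1)
    return np.where(features.valid, total, np.nan)
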