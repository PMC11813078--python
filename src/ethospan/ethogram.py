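"""Ethogram bout operations: run-length extraction, two-geometric dwell-time
mixture fitting, exclusion fractions, and minimum-bout forward-filling."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from datetime import datetime

import numpy as np

from ._alphabet import ALL_LABELS, EDGE_LABEL, UNSTEREOTYPED_LABEL

__all__ = [
    "Ethogram",
    "Bout",
    "DwellMixture",
    "extract_bouts",
    "fit_dwell_mixture",
    "exclusion_fractions",
    "enforce_min_bout",
]

FLAG_LABELS = frozenset({EDGE_LABEL, UNSTEREOTYPED_LABEL})


@dataclass
class Ethogram:
    """Per-frame behavior labels for one fly."""

    labels: np.ndarray
    fps: float = 100.0
    t0_clock: datetime | None = None
    fly_id: str = "fly0"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U20")
        bad = set(np.unique(self.labels)) - set(ALL_LABELS)
        if bad:
            raise ValueError(f"labels outside the behavior alphabet: {sorted(bad)}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def copy(self) -> "Ethogram":
        return replace(self, labels=self.labels.copy())


@dataclass(frozen=True)
class Bout:
    """Maximal run of one label, half-open [start_frame, end_frame)."""

    behavior: str
    start_frame: int
    end_frame: int

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame


def extract_bouts(etho: Ethogram) -> list[Bout]:
    """Run-length encode an ethogram; concatenating bouts reproduces it."""
    labels = etho.labels
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [Bout(str(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


@dataclass
class DwellMixture:
    """Two-component geometric mixture over bout durations (support >= 1).

    ``w`` weights the short component; ordering p_long <= p_short is enforced.
    """

    w: float
    p_short: float
    p_long: float
    loglik: float
    n_iter: int
    converged: bool
    degenerate: bool = False

    @property
    def mean(self) -> float:
        return self.w / self.p_short + (1.0 - self.w) / self.p_long


def _geom_logpmf(k: np.ndarray, p: float) -> np.ndarray:
    return np.log(p) + (k - 1) * np.log1p(-p)


def _em_once(values: np.ndarray, counts: np.ndarray, w: float, ps: float, pl: float,
             tol: float, max_iter: int) -> tuple[float, float, float, float, int, bool]:
    n = counts.sum()
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        la = np.log(w + 1e-300) + _geom_logpmf(values, ps)
        lb = np.log(1 - w + 1e-300) + _geom_logpmf(values, pl)
        norm = np.logaddexp(la, lb)
        loglik = float((counts * norm).sum())
        r = np.exp(la - norm)                       # responsibility of short comp
        na = (counts * r).sum()
        nb = n - na
        sa = (counts * r * values).sum()
        sb = (counts * values).sum() - sa
        w = na / n
        ps = min(na / sa, 1.0) if sa > 0 else 1.0
        pl = min(nb / sb, 1.0) if sb > 0 else 1.0
        ps = max(ps, 1e-12)
        pl = max(pl, 1e-12)
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
    return w, ps, pl, loglik, it, converged


def fit_dwell_mixture(durations, seed: int = 0, n_restarts: int = 5,
                      tol: float = 1e-8, max_iter: int = 500) -> DwellMixture:
    """EM fit of the two-geometric mixture to bout durations (frames).

    Runs ``n_restarts`` seeded initializations and keeps the best
    log-likelihood.  All-identical durations trigger the degenerate
    single-component fallback.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 10:
        raise ValueError("need at least 10 durations")
    if np.any(durations < 1):
        raise ValueError("durations must be >= 1 frame")
    values, counts = np.unique(durations, return_counts=True)
    counts = counts.astype(float)
    if values.size == 1:
        p = min(1.0 / values[0], 1.0)
        ll = float((counts * _geom_logpmf(values, p)).sum())
        return DwellMixture(w=1.0, p_short=p, p_long=p, loglik=ll,
                            n_iter=0, converged=True, degenerate=True)

    rng = np.random.default_rng(seed)
    mean = float(durations.mean())
    best: tuple | None = None
    for _ in range(n_restarts):
        w0 = rng.uniform(0.2, 0.8)
        ps0 = min(1.0, 1.0 / max(mean * rng.uniform(0.05, 0.5), 1.0))
        pl0 = min(1.0, 1.0 / (mean * rng.uniform(1.0, 4.0)))
        fit = _em_once(values, counts, w0, ps0, pl0, tol, max_iter)
        if best is None or fit[3] > best[3]:
            best = fit
    w, ps, pl, ll, it, conv = best
    if ps < pl:                                    # enforce component ordering
        ps, pl, w = pl, ps, 1.0 - w
    return DwellMixture(w=float(w), p_short=float(ps), p_long=float(pl),
                        loglik=ll, n_iter=it, converged=conv)


def exclusion_fractions(fit: DwellMixture, t: int) -> tuple[float, float]:
    """P(X < t) for each component: 1 - (1-p)^(t-1), support starting at 1."""
    if t < 1:
        raise ValueError("threshold must be >= 1 frame")
    frac = lambda p: 1.0 - (1.0 - p) ** (t - 1)
    return frac(fit.p_short), frac(fit.p_long)


def enforce_min_bout(etho: Ethogram, min_frames: int = 5) -> Ethogram:
    """Forward-fill bouts shorter than ``min_frames``.

    Scanning forward, each short bout is relabeled to the most recent preceding
    bout of duration >= ``min_frames``; leading short bouts take the first
    subsequent long bout's label.  Edge/unstereotyped short bouts are flags,
    not behaviors, and are never repainted (they may act as fill sources).
    Frame count is conserved; adjacent same-label bouts are merged afterwards.
    """
    bouts = extract_bouts(etho)
    long_labels = [b.behavior for b in bouts if b.duration_frames >= min_frames]
    if not long_labels:
        warnings.warn("no bout reaches the minimum duration; ethogram unchanged")
        return etho.copy()
    labels = etho.labels.copy()
    first_long = long_labels[0]
    last_long: str | None = None
    for b in bouts:
        if b.duration_frames >= min_frames:
            last_long = b.behavior
        elif b.behavior not in FLAG_LABELS:
            labels[b.start_frame:b.end_frame] = last_long if last_long is not None else first_long
    return replace(etho, labels=labels)
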