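"""Compositional analysis of fly-hour ethograms.

Fly-hour behavior fractions live on the 7-part simplex; all statistics run
through log-ratio geometry: CLR/ILR transforms, MCD-robust PCA with loadings
back-transformed to CLR space, Aitchison perturbation curves, ternary
condensation, diurnal contrast metrics, and bootstrap enrichment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.covariance import MinCovDet

from ._alphabet import BEHAVIORS
from .ethogram import Ethogram
from .kinematics import frame_zeitgeber

__all__ = [
    "CompPCA", "Enrichment",
    "closure", "hourly_compositions", "geometric_mean_composition",
    "clr", "clr_inv", "default_ilr_basis", "ilr", "ilr_inv",
    "robust_composition_pca", "day_night_difference",
    "condense", "ternary_coords", "pc_direction_curve", "enrichment_bootstrap",
]

CONDENSED_PARTS = ("groom", "loco", "rest")
_GROOM = ("fore_groom", "hind_groom", "wing_groom")
_LOCO = ("locomotion", "altered_locomotion")
_REST = ("idle", "proboscis")


def closure(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Rescale positive parts to sum to 1."""
    x = np.asarray(x, dtype=float)
    return x / x.sum(axis=axis, keepdims=True)


def hourly_compositions(
    etho: Ethogram,
    lights_on_hour: float = 8.0,
    zero_strategy: str = "multiplicative",
    min_frames_frac: float = 0.10,
    delta: float | None = None,
) -> pd.DataFrame:
    """Per (fly, day, ZT-hour) behavior fractions over the 7-part alphabet.

    Edge and unstereotyped frames are excluded from the denominator.  Hours
    with fewer than ``min_frames_frac`` of a nominal hour's frames are
    dropped.  Zeros are replaced multiplicatively with
    delta_j = 0.5 x (smallest observed nonzero fraction of part j), the other
    parts rescaled so rows still sum to one.
    """
    zt, day = frame_zeitgeber(etho, lights_on_hour)
    hour = np.floor(zt).astype(int)
    labels = etho.labels
    part_code = np.full(labels.shape, -1, dtype=np.int64)
    for i, b in enumerate(BEHAVIORS):
        part_code[labels == b] = i
    used = part_code >= 0                      # excludes edge/unstereotyped
    frames_per_hour = etho.fps * 3600.0

    key = day.astype(np.int64) * 24 + hour
    all_keys = np.unique(key)
    used_keys, inv = np.unique(key[used], return_inverse=True)
    nb = len(BEHAVIORS)
    counts = np.bincount(inv * nb + part_code[used], minlength=len(used_keys) * nb)
    counts = counts.reshape(len(used_keys), nb).astype(float)
    n_used = counts.sum(axis=1)

    rows = []
    for k, cnt, n in zip(used_keys, counts, n_used):
        d, h = int(k // 24), int(k % 24)
        if n < min_frames_frac * frames_per_hour:
            warnings.warn(f"hour (day={d}, zt={h}) dropped: only {int(n)} usable frames")
            continue
        rows.append({"fly_id": etho.fly_id, "day_index": d, "zt_hour": h,
                     "n_frames_used": int(n), **dict(zip(BEHAVIORS, cnt / n))})
    for k in set(all_keys.tolist()) - set(used_keys.tolist()):
        warnings.warn(f"hour (day={k // 24}, zt={k % 24}) dropped: entirely edge/unstereotyped")
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    parts = out[list(BEHAVIORS)].to_numpy()
    if zero_strategy == "multiplicative":
        parts = _multiplicative_replacement(parts, delta)
    elif zero_strategy != "none":
        raise ValueError(f"unknown zero_strategy {zero_strategy!r}")
    out[list(BEHAVIORS)] = parts
    return out


def _multiplicative_replacement(parts: np.ndarray, delta: float | None) -> np.ndarray:
    parts = parts.copy()
    d = parts.shape[1]
    # fallback for never-observed parts stays a pure fraction (scale-invariant)
    global_min = parts[parts > 0].min() if np.any(parts > 0) else 1e-6
    deltas = np.empty(d)
    for j in range(d):
        nz = parts[:, j][parts[:, j] > 0]
        if delta is not None:
            deltas[j] = delta
        elif nz.size:
            deltas[j] = 0.5 * nz.min()
        else:
            deltas[j] = 0.5 * global_min
    zero = parts <= 0
    replaced = np.where(zero, deltas[None, :], 0.0).sum(axis=1)
    parts = np.where(zero, deltas[None, :], parts * (1.0 - replaced[:, None]))
    return closure(parts)


def geometric_mean_composition(parts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Component-wise geometric mean, re-closed — the 'behavior component'."""
    if isinstance(parts, pd.DataFrame):
        parts = parts[list(BEHAVIORS)].to_numpy()
    parts = np.atleast_2d(np.asarray(parts, dtype=float))
    if parts.shape[0] == 0:
        raise ValueError("need at least one composition")
    return closure(gmean(parts, axis=0))


def clr(x: np.ndarray) -> np.ndarray:
    """Centered log-ratio: log(x_i) - mean(log x). Rows sum to zero."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive parts (handle zeros upstream)")
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def clr_inv(y: np.ndarray) -> np.ndarray:
    return closure(np.exp(np.asarray(y, dtype=float)))


def default_ilr_basis(d: int = len(BEHAVIORS)) -> np.ndarray:
    """(d-1) x d orthonormal zero-sum contrast matrix (Helmert-type balances)."""
    rows = []
    for i in range(1, d):
        r = np.zeros(d)
        r[:i] = 1.0 / i
        r[i] = -1.0
        rows.append(r * np.sqrt(i / (i + 1.0)))
    return np.array(rows)


def _check_basis(basis: np.ndarray, d: int) -> np.ndarray:
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (d - 1, d):
        raise ValueError(f"ILR basis must be {(d - 1, d)}, got {basis.shape}")
    if not np.allclose(basis @ basis.T, np.eye(d - 1), atol=1e-10):
        raise ValueError("ILR basis rows must be orthonormal")
    if not np.allclose(basis.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("ILR basis rows must sum to zero")
    return basis


def ilr(x: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates, y = clr(x) @ B^T."""
    x = np.asarray(x, dtype=float)
    basis = default_ilr_basis(x.shape[-1]) if basis is None else _check_basis(basis, x.shape[-1])
    return clr(x) @ basis.T


def ilr_inv(y: np.ndarray, basis: np.ndarray | None = None, d: int | None = None) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    d = (y.shape[-1] + 1) if d is None else d
    basis = default_ilr_basis(d) if basis is None else _check_basis(basis, d)
    return clr_inv(y @ basis)


@dataclass
class CompPCA:
    clr_loadings: np.ndarray        # components x parts, each row sums to 0
    scores: np.ndarray              # fly-hours x components
    variance_explained: np.ndarray
    center_clr: np.ndarray
    robust: bool
    mcd_support_fraction: float | None
    part_names: tuple = BEHAVIORS


def robust_composition_pca(
    comps: pd.DataFrame | np.ndarray,
    basis: np.ndarray | None = None,
    robust: bool = True,
    support_fraction: float = 0.75,
    seed: int = 0,
) -> CompPCA:
    """PCA of ILR-transformed fly-hours with MCD-robust covariance.

    The fit is intrinsic to the simplex: whatever ``basis`` is supplied, the
    coordinates are rotated into a fixed canonical ILR basis before the MCD
    step, so scores and CLR-back-transformed loadings are basis-invariant by
    construction.  Sign convention: PC1 has a non-negative locomotion CLR
    loading; the other PCs have their largest-|loading| part positive.
    """
    if isinstance(comps, pd.DataFrame):
        parts = comps[list(BEHAVIORS)].to_numpy()
    else:
        parts = np.asarray(comps, dtype=float)
    n, d = parts.shape
    if n < d + 1:
        raise ValueError(f"need more fly-hours ({n}) than ILR dimension ({d - 1})")
    if basis is not None:
        _check_basis(basis, d)
    canon = default_ilr_basis(d)
    Z = clr(parts) @ canon.T
    if np.linalg.matrix_rank(Z - Z.mean(axis=0), tol=1e-10) < d - 1:
        var = (Z - Z.mean(axis=0)).var(axis=0)
        flat = [BEHAVIORS[i] if i < len(BEHAVIORS) else str(i)
                for i in np.argsort(var)[: max(1, int((var < 1e-12).sum()))]]
        raise ValueError(f"rank-deficient compositions; near-collinear parts involving {flat}")

    if robust:
        mcd = MinCovDet(support_fraction=support_fraction, random_state=seed).fit(Z)
        cov, loc = mcd.covariance_, mcd.location_
    else:
        cov, loc = np.cov(Z, rowvar=False), Z.mean(axis=0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    clr_loadings = evecs.T @ canon                       # components x parts
    loco = list(BEHAVIORS).index("locomotion")
    signs = np.ones(d - 1)
    if clr_loadings[0, loco] < 0:
        signs[0] = -1
    for k in range(1, d - 1):
        if clr_loadings[k, np.argmax(np.abs(clr_loadings[k]))] < 0:
            signs[k] = -1
    evecs *= signs
    clr_loadings *= signs[:, None]

    scores = (Z - loc) @ evecs
    return CompPCA(
        clr_loadings=clr_loadings,
        scores=scores,
        variance_explained=np.clip(evals, 0, None) / np.clip(evals, 0, None).sum(),
        center_clr=loc @ canon,
        robust=robust,
        mcd_support_fraction=support_fraction if robust else None,
    )


def day_night_difference(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-day |mean night score - mean day score|, averaged over flies.

    ``scores`` needs columns score, zt_hour, day_index, fly_id.  Day is
    ZT [0, 12), night ZT [12, 24).  A fly-day missing one side yields NaN and
    is dropped from the fly average.
    """
    df = scores.copy()
    df["is_day"] = df["zt_hour"] < 12
    per_fly = []
    for (fly, day), grp in df.groupby(["fly_id", "day_index"]):
        day_scores = grp.loc[grp["is_day"], "score"]
        night_scores = grp.loc[~grp["is_day"], "score"]
        val = np.nan
        if len(day_scores) and len(night_scores):
            val = abs(night_scores.mean() - day_scores.mean())
        per_fly.append({"fly_id": fly, "day_index": day, "diff": val})
    per_fly = pd.DataFrame(per_fly).dropna()
    out = per_fly.groupby("day_index")["diff"].agg(
        mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n="count").reset_index()
    return out


def condense(parts: np.ndarray) -> np.ndarray:
    """Amalgamate the 7 parts into (groom, loco, rest) and re-close."""
    parts = np.atleast_2d(np.asarray(parts, dtype=float))
    idx = {b: i for i, b in enumerate(BEHAVIORS)}
    groom = parts[:, [idx[b] for b in _GROOM]].sum(axis=1)
    loco = parts[:, [idx[b] for b in _LOCO]].sum(axis=1)
    rest = parts[:, [idx[b] for b in _REST]].sum(axis=1)
    out = closure(np.stack([groom, loco, rest], axis=1))
    return out[0] if out.shape[0] == 1 and np.asarray(parts).ndim == 1 else out


def ternary_coords(parts3: np.ndarray) -> np.ndarray:
    """Barycentric -> Cartesian for 3-part compositions (a,b,c):
    x = (2b + c) / (2 (a+b+c)), y = sqrt(3)/2 * c / (a+b+c)."""
    p = np.atleast_2d(np.asarray(parts3, dtype=float))
    s = p.sum(axis=1)
    x = 0.5 * (2 * p[:, 1] + p[:, 2]) / s
    y = (np.sqrt(3) / 2) * p[:, 2] / s
    out = np.stack([x, y], axis=1)
    return out[0] if np.asarray(parts3).ndim == 1 else out


def pc_direction_curve(center: np.ndarray, clr_loading: np.ndarray,
                       scales: np.ndarray) -> np.ndarray:
    """Aitchison perturbation of ``center`` along a CLR loading:
    closure(center * exp(s * loading)) for each scale s."""
    center = np.asarray(center, dtype=float)
    loading = np.asarray(clr_loading, dtype=float)
    if np.any(center <= 0):
        raise ValueError("center must be strictly positive")
    if abs(loading.sum()) > 1e-8:
        raise ValueError("clr loading must sum to zero")
    scales = np.asarray(scales, dtype=float)
    return closure(center[None, :] * np.exp(scales[:, None] * loading[None, :]))


@dataclass
class Enrichment:
    hour: int
    ratio: float
    ci_low: float
    ci_high: float
    n_boot: int


def enrichment_bootstrap(
    hour_parts: np.ndarray,
    reference: np.ndarray,
    part: int,
    hour: int = 0,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> Enrichment:
    """Enrichment of one part at one ZT hour relative to a reference
    composition, with a percentile bootstrap over flies.

    ``hour_parts`` holds one composition per fly (rows); ``part`` indexes the
    column in both ``hour_parts`` and ``reference``.
    """
    hour_parts = np.atleast_2d(np.asarray(hour_parts, dtype=float))
    reference = np.asarray(reference, dtype=float)
    if hour_parts.shape[0] < 2:
        raise ValueError("need at least 2 flies at the hour")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable confidence intervals")
    ref = reference[part]

    def ratio_of(rows: np.ndarray) -> float:
        return float(gmean(rows[:, part]) / ref)

    point = ratio_of(hour_parts)
    rng = np.random.default_rng(seed)
    n = hour_parts.shape[0]
    boots = np.array([ratio_of(hour_parts[rng.integers(0, n, n)]) for _ in range(n_boot)])
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    return Enrichment(hour=hour, ratio=point, ci_low=min(float(lo), point),
                      ci_high=max(float(hi), point), n_boot=n_boot)
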