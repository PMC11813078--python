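"""Stereotyped-behavior map: filtered/quota'd training-set assembly, 2-D
embedding with an out-of-sample transform, density-based region segmentation,
and full-dataset label assignment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed
from sklearn.neighbors import NearestNeighbors

from ._alphabet import BEHAVIORS, EDGE_LABEL, UNSTEREOTYPED_LABEL
from .spectral import DEFAULT_AMPLITUDE_THRESHOLD

__all__ = [
    "FeatureGroup", "TrainingSet", "EmbeddedMap", "RegionMap", "MapConfig",
    "assemble_training_set", "importance_sample", "fit_embedding",
    "segment_density", "assign_behaviors", "name_regions_by_majority",
]


@dataclass
class MapConfig:
    amplitude_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD
    group_cap: int = 36000        # uniform per-group cap before importance sampling
    group_quota: int = 454        # importance-sampled points per fly-hour group
    knn_k: int = 20
    density_exponent: float = 2.0
    seed: int = 0
    umap_n_neighbors: int = 20
    umap_min_dist: float = 0.1
    umap_metric: str = "cosine"
    grid_size: int = 512
    kde_bandwidth_factor: float = 0.5
    low_density_quantile: float = 0.05
    adaptive_block: int = 128
    adaptive_offset: float = 0.0
    min_region_mass: float = 0.02   # cores below this density share are dropped


@dataclass
class FeatureGroup:
    """Per-frame spectral features for one fly-hour with aligned filter inputs."""

    features: np.ndarray     # frames x dims
    edge_flags: np.ndarray   # frames, bool
    amplitude: np.ndarray    # frames, mm^2 (NaN = invalid frame)
    fly_id: str = "fly0"
    hour: int = 0
    frame_index: np.ndarray | None = None   # original frame per row (provenance)


@dataclass
class TrainingSet:
    features: np.ndarray
    provenance: list         # (fly_id, hour, frame) per point
    group_counts: dict


@dataclass
class EmbeddedMap:
    reducer: object
    train_coords: np.ndarray
    seed: int

    def transform(self, X: np.ndarray, batch: int = 20000) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = [self.reducer.transform(X[i:i + batch]) for i in range(0, len(X), batch)]
        return np.concatenate(out, axis=0) if out else np.empty((0, 2))


@dataclass
class RegionMap:
    density: np.ndarray                  # H x W
    labels: np.ndarray                   # H x W int, 0 = unstereotyped/background
    extent: tuple                        # (xmin, xmax, ymin, ymax)
    kde_bandwidth: float
    behavior_names: dict = field(default_factory=dict)   # region id -> behavior

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def lookup(self, points: np.ndarray) -> np.ndarray:
        """Integer region per 2-D point; 0 outside the extent."""
        xmin, xmax, ymin, ymax = self.extent
        h, w = self.labels.shape
        pts = np.asarray(points, dtype=float)
        ix = np.floor((pts[:, 0] - xmin) / (xmax - xmin) * w).astype(int)
        iy = np.floor((pts[:, 1] - ymin) / (ymax - ymin) * h).astype(int)
        inside = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        out = np.zeros(len(pts), dtype=int)
        out[inside] = self.labels[iy[inside], ix[inside]]
        return out


def importance_sample(group_features: np.ndarray, quota: int, seed: int = 0,
                      k: int = 20, exponent: float = 2.0) -> np.ndarray:
    """Coverage-equalizing subsample: k-NN local density is estimated per point
    and points are drawn without replacement with probability proportional to
    inverse density (selection weight r_k**exponent, r_k = distance to the k-th
    neighbor), enriching sparse regions of postural-dynamics space."""
    X = np.asarray(group_features, dtype=float)
    n = len(X)
    if quota < 0:
        raise ValueError("quota must be >= 0")
    if quota == 0:
        return np.empty(0, dtype=int)
    if quota >= n:
        return np.arange(n)
    kk = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    r_k = dist[:, -1]
    w = np.maximum(r_k, 1e-12) ** exponent
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(n, size=quota, replace=False, p=p, shuffle=False)


def assemble_training_set(groups: list[FeatureGroup], config: MapConfig | None = None) -> TrainingSet:
    """Filter, cap, and importance-sample each fly-hour group, then concatenate.

    Per group: drop edge-flagged frames and frames with total spectral
    amplitude below the idle threshold; uniformly sample at most ``group_cap``
    of the survivors; importance-sample ``group_quota`` of those (all, if
    fewer).  An empty group contributes nothing but does not stop assembly.
    """
    config = config or MapConfig()
    parts, provenance = [], []
    counts: dict = {}
    seeds = np.random.SeedSequence(config.seed).spawn(len(groups))
    for group, ss in zip(groups, seeds):
        amp = np.asarray(group.amplitude, dtype=float)
        keep = (~np.asarray(group.edge_flags, dtype=bool)) \
            & np.isfinite(amp) & (amp >= config.amplitude_threshold)
        idx = np.flatnonzero(keep)
        key = (group.fly_id, group.hour)
        if idx.size == 0:
            warnings.warn(f"group {key} empty after filtering")
            counts[key] = {"unfiltered": 0, "capped": 0, "selected": 0}
            continue
        n_unfiltered = idx.size
        rng = np.random.default_rng(ss)
        if idx.size > config.group_cap:
            idx = rng.choice(idx, size=config.group_cap, replace=False, shuffle=False)
            idx.sort()
        sub = np.asarray(group.features)[idx]
        sel = importance_sample(sub, config.group_quota,
                                seed=int(rng.integers(2**31)),
                                k=config.knn_k, exponent=config.density_exponent)
        parts.append(sub[sel])
        frames = idx[sel] if group.frame_index is None else np.asarray(group.frame_index)[idx[sel]]
        provenance.extend((group.fly_id, group.hour, int(f)) for f in frames)
        counts[key] = {"unfiltered": int(n_unfiltered), "capped": int(idx.size),
                       "selected": int(sel.size)}
    features = np.concatenate(parts, axis=0) if parts else np.empty((0, 0))
    return TrainingSet(features=features, provenance=provenance, group_counts=counts)


def fit_embedding(train: TrainingSet | np.ndarray, config: MapConfig | None = None,
                  seed: int | None = None) -> EmbeddedMap:
    """2-D UMAP embedding with a reusable out-of-sample transform."""
    import umap  # deferred: slow import

    config = config or MapConfig()
    seed = config.seed if seed is None else seed
    X = train.features if isinstance(train, TrainingSet) else np.asarray(train)
    if len(X) < 10:
        raise ValueError("need at least 10 training points")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate training set: all feature rows identical")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(config.umap_n_neighbors, len(X) - 1),
        min_dist=config.umap_min_dist,
        metric=config.umap_metric,
        random_state=seed,
    )
    coords = reducer.fit_transform(np.asarray(X, dtype=np.float32))
    return EmbeddedMap(reducer=reducer, train_coords=np.asarray(coords), seed=seed)


def segment_density(emap: EmbeddedMap, config: MapConfig | None = None) -> RegionMap:
    """Grid KDE of the training embedding, low-density elimination, adaptive
    thresholding into cores, and watershed expansion into labeled regions.

    The KDE is a 2-D histogram smoothed with a Gaussian of Scott's-rule
    bandwidth (times ``kde_bandwidth_factor``).  Cells below the low-density
    quantile (measured at the training points) are zeroed; cores come from a
    local-mean adaptive threshold (block mean minus offset); each core is then
    expanded over the retained density support by watershed so the regions
    partition the above-threshold mass.  Label 0 is reserved for background.
    """
    config = config or MapConfig()
    pts = emap.train_coords
    g = config.grid_size
    if pts.size == 0:
        z = np.zeros((g, g))
        return RegionMap(density=z, labels=z.astype(int), extent=(0, 1, 0, 1), kde_bandwidth=0.0)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    pad_x = 0.05 * max(xmax - xmin, 1e-6)
    pad_y = 0.05 * max(ymax - ymin, 1e-6)
    extent = (xmin - pad_x, xmax + pad_x, ymin - pad_y, ymax + pad_y)

    hist, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=g,
                                range=[[extent[2], extent[3]], [extent[0], extent[1]]])
    n = len(pts)
    sigma_data = pts.std(axis=0, ddof=1).mean()
    bandwidth = sigma_data * n ** (-1 / 6) * config.kde_bandwidth_factor   # Scott, 2-D
    if bandwidth <= 0:
        raise ValueError("KDE bandwidth must be positive")
    cell = max((extent[1] - extent[0]) / g, (extent[3] - extent[2]) / g)
    density = ndimage.gaussian_filter(hist, sigma=bandwidth / cell)
    density /= density.sum() or 1.0

    # eliminate extreme low density, measured where the training points sit
    ix = np.clip(((pts[:, 0] - extent[0]) / (extent[1] - extent[0]) * g).astype(int), 0, g - 1)
    iy = np.clip(((pts[:, 1] - extent[2]) / (extent[3] - extent[2]) * g).astype(int), 0, g - 1)
    cutoff = np.quantile(density[iy, ix], config.low_density_quantile)
    support = density > cutoff

    local_mean = ndimage.uniform_filter(density, size=config.adaptive_block)
    cores = support & (density > local_mean - config.adaptive_offset)
    core_labels, n_cores = ndimage.label(cores, structure=np.ones((3, 3), dtype=int))
    if n_cores:
        # prune noise cores carrying a negligible share of the density mass
        mass = ndimage.sum_labels(density, core_labels, index=np.arange(1, n_cores + 1))
        keep = np.flatnonzero(mass >= config.min_region_mass * mass.sum()) + 1
        remap = np.zeros(n_cores + 1, dtype=int)
        remap[keep] = np.arange(1, keep.size + 1)
        core_labels = remap[core_labels]
    labels = watershed(-density, markers=core_labels, mask=support)
    return RegionMap(density=density, labels=labels, extent=extent, kde_bandwidth=float(bandwidth))


def name_regions_by_majority(region_ids: np.ndarray, true_labels: np.ndarray) -> dict:
    """Map each region id to the majority ground-truth behavior among its
    points — the test-time stand-in for manual clip review."""
    names: dict[int, str] = {}
    region_ids = np.asarray(region_ids)
    true_labels = np.asarray(true_labels)
    for rid in np.unique(region_ids):
        if rid == 0:
            continue
        labs, cnt = np.unique(true_labels[region_ids == rid], return_counts=True)
        names[int(rid)] = str(labs[np.argmax(cnt)])
    return names


def assign_behaviors(
    features: np.ndarray,
    edge_flags: np.ndarray,
    amplitude: np.ndarray,
    emap: EmbeddedMap,
    regions: RegionMap,
    config: MapConfig | None = None,
) -> np.ndarray:
    """Per-frame labels with the fixed precedence: edge flag -> edge;
    sub-threshold amplitude -> idle; else embed and look up the region grid
    (region 0 or outside the extent -> unstereotyped).  Regions named ``idle``
    merge into idle.  Raises if any populated region is unnamed."""
    config = config or MapConfig()
    present = set(np.unique(regions.labels)) - {0}
    unnamed = sorted(present - set(regions.behavior_names))
    if unnamed:
        raise ValueError(f"regions without behavior names: {unnamed}")
    bad = set(regions.behavior_names.values()) - set(BEHAVIORS)
    if bad:
        raise ValueError(f"region names outside the behavior alphabet: {sorted(bad)}")

    n = len(features)
    edge_flags = np.asarray(edge_flags, dtype=bool)
    amp = np.asarray(amplitude, dtype=float)
    labels = np.full(n, UNSTEREOTYPED_LABEL, dtype="U20")
    invalid = ~np.isfinite(amp)
    idle = ~invalid & (amp < config.amplitude_threshold)
    labels[idle] = "idle"
    todo = ~edge_flags & ~invalid & ~idle
    if todo.any():
        coords = emap.transform(np.asarray(features)[todo])
        rids = regions.lookup(coords)
        mapped = np.array([regions.behavior_names.get(int(r), UNSTEREOTYPED_LABEL)
                           if r else UNSTEREOTYPED_LABEL for r in rids], dtype="U20")
        labels[todo] = mapped
    labels[edge_flags] = EDGE_LABEL
    return labels
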