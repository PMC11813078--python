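"""Wall (edge) frame detection: geometric feature construction and a
max-margin binary classifier over standardized features."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ._alphabet import EDGE_FEATURE_NODES
from .preprocess import ArenaGeometry, PoseSequence

__all__ = ["EdgeFeatures", "EdgeModel", "build_edge_features",
           "train_edge_classifier", "predict_edge"]

_N = len(EDGE_FEATURE_NODES)                       # 13 non-proboscis nodes
N_EDGE_FEATURES = _N * (_N - 1) // 2 + _N + _N     # 78 + 13 + 13 = 104


@dataclass
class EdgeFeatures:
    """Per-frame feature rows: 78 pairwise distances, 13 node speeds,
    13 node-to-wall distances (all mm or mm/s)."""

    X: np.ndarray          # frames x 104; NaN rows where incomplete
    missing: np.ndarray    # frames; True where any contributing node missing
    feature_names: list


@dataclass
class EdgeModel:
    pipeline: Pipeline
    holdout_accuracy: float
    n_train: int
    class_balance: float
    seed: int


def build_edge_features(pose: PoseSequence, arena: ArenaGeometry) -> EdgeFeatures:
    """All-by-all distances among the 13 non-proboscis nodes, per-node speeds
    (centered differences), and per-node distance to the arena wall.

    Frames with any missing contributing node get a NaN row flagged missing.
    """
    if arena.radius_px <= 0:
        raise ValueError("arena radius must be positive")
    ppm = pose.px_per_mm
    idx = [pose.node_names.index(n) for n in EDGE_FEATURE_NODES]
    pts = pose.coords[:, idx, :] / ppm                       # mm
    center = np.asarray(arena.center_px) / ppm
    n = pose.n_frames

    missing = pose.missing[:, idx].any(axis=1)

    iu, ju = np.triu_indices(_N, k=1)
    diffs = pts[:, iu, :] - pts[:, ju, :]
    pair_d = np.linalg.norm(diffs, axis=2)                   # n x 78

    vel = np.empty_like(pts)
    if n >= 2:
        vel[1:-1] = (pts[2:] - pts[:-2]) / 2.0
        vel[0] = pts[1] - pts[0]
        vel[-1] = pts[-1] - pts[-2]
    else:
        vel[:] = 0.0
    speeds = np.linalg.norm(vel, axis=2) * pose.fps          # mm/s

    radial = np.linalg.norm(pts - center, axis=2)
    edge_d = np.clip(arena.radius_px / ppm - radial, 0.0, None)

    X = np.concatenate([pair_d, speeds, edge_d], axis=1)
    X[missing] = np.nan
    names = ([f"dist_{EDGE_FEATURE_NODES[i]}_{EDGE_FEATURE_NODES[j]}" for i, j in zip(iu, ju)]
             + [f"speed_{nm}" for nm in EDGE_FEATURE_NODES]
             + [f"wall_{nm}" for nm in EDGE_FEATURE_NODES])
    return EdgeFeatures(X=X, missing=missing, feature_names=names)


def train_edge_classifier(X: np.ndarray, y: np.ndarray, seed: int = 0) -> EdgeModel:
    """Fit a standardized linear max-margin classifier; reports accuracy on a
    stratified 20% held-out split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    keep = ~np.isnan(X).any(axis=1)
    X, y = X[keep], y[keep]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", LinearSVC(C=1.0, random_state=seed)),
    ])
    pipe.fit(X_tr, y_tr)
    acc = float((pipe.predict(X_te) == y_te).mean())
    return EdgeModel(pipeline=pipe, holdout_accuracy=acc, n_train=int(y_tr.size),
                     class_balance=float(y.mean()), seed=seed)


def predict_edge(model: EdgeModel, features: EdgeFeatures | np.ndarray) -> np.ndarray:
    """Per-frame edge flags; frames with missing features are conservatively
    flagged True (occlusion correlates with wall visits)."""
    X = features.X if isinstance(features, EdgeFeatures) else np.asarray(features, dtype=float)
    expected = model.pipeline.named_steps["scale"].n_features_in_
    if X.shape[1] != expected:
        raise ValueError(f"feature dimension mismatch: got {X.shape[1]}, expected {expected}")
    out = np.ones(X.shape[0], dtype=bool)
    complete = ~np.isnan(X).any(axis=1)
    if complete.any():
        out[complete] = model.pipeline.predict(X[complete]).astype(bool)
    return out
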