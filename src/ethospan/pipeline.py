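"""End-to-end orchestration on synthetic cohorts.

simulate -> preprocess -> featurize -> edge -> map -> assign -> boutfix ->
compositions -> robust PCA, with a manifest recording the config hash and
per-stage output hashes.  Each stage reads parameters only from the config.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._alphabet import BEHAVIORS, EDGE_LABEL, UNSTEREOTYPED_LABEL
from .compositional import hourly_compositions, robust_composition_pca
from .config import PipelineConfig
from .edge import build_edge_features, predict_edge, train_edge_classifier
from .ethogram import Ethogram, enforce_min_bout
from .mapping import (FeatureGroup, MapConfig, assemble_training_set, assign_behaviors,
                      fit_embedding, name_regions_by_majority, segment_density)
from .preprocess import egocentrize, interpolate_pose, smooth_pose
from .spectral import FrequencyGrid, rolling_spectral_features, total_spectral_amplitude
from .synth import SynthConfig, simulate_fly

log = logging.getLogger("ethospan.pipeline")


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    stages: list = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def add(self, stage: str, **payload) -> None:
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]
        self.stages.append({"stage": stage, "hash": digest, **payload})

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "package_version": self.package_version,
             "stages": self.stages, "results": self.results},
            indent=2, default=str)


def _array_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunManifest:
    """Run the full synthetic pipeline and return the manifest (results under
    ``manifest.results``: frame accuracy vs ground truth, unstereotyped
    fraction, compositions, PCA summaries)."""
    config.validate()
    manifest = RunManifest(config_hash=config.config_hash, package_version=__version__)
    synth_cfg = SynthConfig(fps=config.fps, px_per_mm=config.px_per_mm,
                            n_flies=config.n_flies, n_hours=config.n_hours,
                            seed=config.seed_simulate, **config.synth)
    stride = int(config.spectral.get("stride", 20))
    grid = FrequencyGrid.dyadic(
        n_freqs=int(config.spectral.get("n_freqs", 25)),
        f_min=float(config.spectral.get("f_min", 0.5)),
        f_max=float(config.spectral.get("f_max", 25.0)))
    map_cfg = MapConfig(seed=config.seed_map, **config.map)
    min_bout = int(config.ethogram.get("min_bout_frames", 5))
    arena = synth_cfg.arena

    flies = []
    fly_seeds = np.random.SeedSequence(config.seed_simulate).spawn(config.n_flies)
    for i, ss in enumerate(fly_seeds):
        seed_i = int(np.random.default_rng(ss).integers(2**31))
        pose, truth = simulate_fly(synth_cfg, seed=seed_i, fly_id=f"fly{i}")
        log.info("simulated %s: %d frames", pose.fly_id, pose.n_frames)

        interp = interpolate_pose(pose)
        smooth = smooth_pose(interp)
        ego = egocentrize(smooth)

        feats = rolling_spectral_features(ego, grid, stride=stride,
                                          **{k: v for k, v in config.spectral.items()
                                             if k in ("window_periods", "min_occupancy")})
        amp = total_spectral_amplitude(feats)
        efeat = build_edge_features(interp, arena)
        flies.append(dict(pose=pose, truth=truth, interp=interp, ego=ego,
                          feats=feats, amp=amp, efeat=efeat))
        manifest.add("simulate+featurize", fly=pose.fly_id,
                     n_frames=pose.n_frames, feats_hash=_array_hash(feats.power))

    # --- edge classifier: trained on ground-truth flags where rows are complete
    X_parts, y_parts = [], []
    for fl in flies:
        complete = ~fl["efeat"].missing
        X_parts.append(fl["efeat"].X[complete])
        y_parts.append(fl["truth"].true_edge_mask[complete])
    X_all = np.concatenate(X_parts)
    y_all = np.concatenate(y_parts)
    model = None
    if 20 <= y_all.sum() and 20 <= (~y_all).sum():
        n_per = min(int(y_all.sum()), int((~y_all).sum()),
                    int(config.synth.get("edge_train_per_class", 2000)))
        rng = np.random.default_rng(config.seed_edge)
        pick = np.concatenate([
            rng.choice(np.flatnonzero(y_all), n_per, replace=False),
            rng.choice(np.flatnonzero(~y_all), n_per, replace=False)])
        model = train_edge_classifier(X_all[pick], y_all[pick], seed=config.seed_edge)
        manifest.add("edge", n_train=model.n_train, holdout_accuracy=model.holdout_accuracy)
    else:
        log.info("too few complete edge rows for training; using missing-row flags only")
        manifest.add("edge", n_train=0, holdout_accuracy=None)

    for fl in flies:
        if model is not None:
            flags_full = predict_edge(model, fl["efeat"])
        else:
            flags_full = fl["efeat"].missing.copy()
        fl["edge_flags"] = flags_full[fl["feats"].frame_index]

    # --- behavior map
    groups = []
    for fl in flies:
        feats = fl["feats"]
        hours = (feats.frame_index / fl["pose"].fps / 3600.0).astype(int)
        for h in np.unique(hours):
            rows = hours == h
            groups.append(FeatureGroup(
                features=feats.power[rows], edge_flags=fl["edge_flags"][rows],
                amplitude=fl["amp"][rows], fly_id=fl["pose"].fly_id, hour=int(h),
                frame_index=feats.frame_index[rows]))
    train = assemble_training_set(groups, map_cfg)
    emap = fit_embedding(train, map_cfg)
    regions = segment_density(emap, map_cfg)

    truth_by_fly = {fl["pose"].fly_id: fl["truth"].true_ethogram for fl in flies}
    train_truth = np.array([truth_by_fly[fly][frame]
                            for fly, _, frame in train.provenance], dtype="U20")
    region_ids = regions.lookup(emap.train_coords)
    regions.behavior_names = name_regions_by_majority(region_ids, train_truth)
    manifest.add("map", n_train=len(train.features), n_regions=regions.n_regions,
                 region_names=regions.behavior_names)

    # --- assignment, upsampling to full frame rate, min-bout fill
    all_comps = []
    acc_num = acc_den = 0
    unstereo = total_assigned = 0
    for fl in flies:
        feats = fl["feats"]
        labels_strided = assign_behaviors(feats.power, fl["edge_flags"], fl["amp"],
                                          emap, regions, map_cfg)
        n = fl["pose"].n_frames
        row = np.minimum(np.round(np.arange(n) / stride).astype(int), len(labels_strided) - 1)
        labels_full = labels_strided[row]
        etho = enforce_min_bout(
            Ethogram(labels=labels_full, fps=fl["pose"].fps,
                     t0_clock=fl["pose"].t0_clock, fly_id=fl["pose"].fly_id),
            min_frames=min_bout)
        fl["ethogram"] = etho

        truth_labels = fl["truth"].true_ethogram
        scored = (~np.isin(etho.labels, (EDGE_LABEL, UNSTEREOTYPED_LABEL))
                  & ~fl["truth"].true_edge_mask)
        acc_num += int((etho.labels[scored] == truth_labels[scored]).sum())
        acc_den += int(scored.sum())
        not_true_edge = ~fl["truth"].true_edge_mask
        unstereo += int((etho.labels[not_true_edge] == UNSTEREOTYPED_LABEL).sum())
        total_assigned += int(not_true_edge.sum())

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comps = hourly_compositions(etho, lights_on_hour=config.lights_on_hour,
                                        **config.composition)
        if not comps.empty:
            all_comps.append(comps)
        manifest.add("assign", fly=fl["pose"].fly_id, labels_hash=_array_hash(etho.labels))

    results = {
        "frame_accuracy": acc_num / acc_den if acc_den else np.nan,
        "unstereotyped_fraction": unstereo / total_assigned if total_assigned else np.nan,
        "n_fly_hours": int(sum(len(c) for c in all_comps)),
    }
    if all_comps:
        comp_table = pd.concat(all_comps, ignore_index=True)
        results["compositions"] = comp_table
        if len(comp_table) >= len(BEHAVIORS) + 1:
            pca = robust_composition_pca(comp_table, seed=config.seed_pca)
            results["pca_variance_explained"] = pca.variance_explained.tolist()
            results["pca_clr_loadings"] = pca.clr_loadings.tolist()
    manifest.results = {k: v for k, v in results.items() if k != "compositions"}
    manifest.results["ethograms"] = {fl["pose"].fly_id: fl["ethogram"] for fl in flies}
    manifest.results["compositions"] = results.get("compositions")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import save_ethogram_csv
        for fl in flies:
            save_ethogram_csv(fl["ethogram"], outdir / f"{fl['pose'].fly_id}_ethogram.csv",
                              run_length=True)
        if results.get("compositions") is not None:
            results["compositions"].to_csv(outdir / "compositions.csv", index=False)
        slim = {k: v for k, v in manifest.results.items()
                if k not in ("ethograms", "compositions")}
        (outdir / "manifest.json").write_text(json.dumps(
            {"config_hash": manifest.config_hash, "package_version": manifest.package_version,
             "stages": manifest.stages, "results": slim}, indent=2, default=str))
    return manifest
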