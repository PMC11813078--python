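"""Synthetic fly generator: diurnal semi-Markov behavior states rendered onto a
rigid 14-node skeleton, plus a corruption stage (dropout, jitter, wall bouts).

All archetype parameters are scaffold choices — the generator emulates the
statistical structure the downstream analysis assumes (diurnally modulated
state occupancy, two-geometric dwell mixtures, per-behavior limb oscillations,
missing keypoints, edge bouts), not fly biomechanics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping, Sequence

import numpy as np

from ._alphabet import BEHAVIORS, HEAD, LEG_NODES, NODE_NAMES, PROBOSCIS, THORAX
from .preprocess import ArenaGeometry, PoseSequence

__all__ = [
    "BehaviorArchetype",
    "DiurnalSchedule",
    "SynthConfig",
    "GroundTruth",
    "default_archetypes",
    "default_schedule",
    "generate_state_sequence",
    "render_pose",
    "corrupt",
    "simulate_fly",
    "geometric_mixture_mean",
]

#: rigid body template, mm, body frame (+x anterior). Head 2.5 mm anterior of
#: thorax, legs on a ~1.5 mm lateral arc; geometry is configurable, not biology.
BODY_TEMPLATE_MM: dict[str, tuple[float, float]] = {
    "head": (2.5, 0.0),
    "eyeL": (2.3, 0.4),
    "eyeR": (2.3, -0.4),
    "proboscis": (3.0, 0.0),   # 0.5 mm anterior of head when visible
    "thorax": (0.0, 0.0),
    "abdomen": (-2.5, 0.0),
    "wingL": (-2.0, 0.8),
    "wingR": (-2.0, -0.8),
    "forelegL": (1.5, 1.2),
    "forelegR": (1.5, -1.2),
    "midlegL": (0.0, 1.5),
    "midlegR": (0.0, -1.5),
    "hindlegL": (-1.5, 1.3),
    "hindlegR": (-1.5, -1.3),
}


class ConfigurationError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass
class BehaviorArchetype:
    """Kinematic signature of one behavior state."""

    name: str
    node_freq_hz: Mapping[str, float] = field(default_factory=dict)
    node_amp_mm: Mapping[str, float] = field(default_factory=dict)
    translation_speed_mm_s: float = 0.0
    proboscis_visible: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in BEHAVIORS:
            raise ConfigurationError(f"unknown behavior name {self.name!r}")
        for node, f in self.node_freq_hz.items():
            if node not in NODE_NAMES:
                raise ConfigurationError(f"unknown node {node!r}")
            if not 0 < f < 50:
                raise ConfigurationError("oscillation frequencies must be in (0, 50) Hz")
        if any(a < 0 for a in self.node_amp_mm.values()):
            raise ConfigurationError("amplitudes must be >= 0")
        if self.name == "idle" and (self.node_amp_mm and max(self.node_amp_mm.values()) > 0
                                    or self.translation_speed_mm_s != 0):
            raise ConfigurationError("idle archetype must have zero amplitudes and speed")

    @property
    def oscillating_nodes(self) -> set[str]:
        return {n for n, a in self.node_amp_mm.items() if a > 0}


@dataclass
class DiurnalSchedule:
    """ZT-dependent state occupancy weights and per-behavior dwell mixtures.

    Weights are *frame occupancy* targets: states are entered with probability
    proportional to weight/mean_dwell so that the marginal fraction of frames
    in each behavior converges to the normalized weights.
    """

    lights_on_hour: float = 8.0
    day_state_weights: Mapping[str, float] = field(default_factory=dict)
    night_state_weights: Mapping[str, float] = field(default_factory=dict)
    dwell_short_p: Mapping[str, float] | float = 0.05
    dwell_long_p: Mapping[str, float] | float = 0.005
    dwell_mix_w: Mapping[str, float] | float = 0.5

    def _param(self, table, behavior: str) -> float:
        return table[behavior] if isinstance(table, Mapping) else float(table)

    def dwell_params(self, behavior: str) -> tuple[float, float, float]:
        w = self._param(self.dwell_mix_w, behavior)
        ps = self._param(self.dwell_short_p, behavior)
        pl = self._param(self.dwell_long_p, behavior)
        if not (0 < ps <= 1 and 0 < pl <= 1 and 0 <= w <= 1):
            raise ConfigurationError("dwell parameters must satisfy 0 < p <= 1, 0 <= w <= 1")
        return w, ps, pl

    def mean_dwell(self, behavior: str) -> float:
        return geometric_mixture_mean(*self.dwell_params(behavior))


def geometric_mixture_mean(w: float, p_short: float, p_long: float) -> float:
    """Mean of the two-geometric dwell mixture, w/p_short + (1-w)/p_long."""
    return w / p_short + (1.0 - w) / p_long


@dataclass
class SynthConfig:
    fps: float = 100.0
    px_per_mm: float = 28.25
    arena_diameter_mm: float = 25.0
    n_flies: int = 1
    n_hours: float = 1.0
    seed: int = 0
    missing_rate: float = 0.02
    edge_bout_rate: float = 0.002       # bout starts per second
    edge_bout_duration_s: float = 2.0   # mean duration
    noise_sd_mm: float = 0.05
    heading_sd: float = 0.05            # rad per moving frame
    edge_drop_legs: bool = True
    wall_margin_mm: float = 1.0         # thorax offset from wall during edge bouts
    confine_margin_mm: float = 4.0      # keeps the whole body off the wall

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.px_per_mm <= 0:
            raise ConfigurationError("fps and px_per_mm must be positive")
        for p in (self.missing_rate,):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must be in [0, 1]")

    @property
    def arena(self) -> ArenaGeometry:
        r = self.arena_diameter_mm / 2 * self.px_per_mm
        return ArenaGeometry(center_px=(r, r), radius_px=r, px_per_mm=self.px_per_mm)


@dataclass
class GroundTruth:
    true_ethogram: np.ndarray | None
    true_edge_mask: np.ndarray
    true_missing_mask: np.ndarray


def default_archetypes() -> dict[str, BehaviorArchetype]:
    """Archetypes with distinct spectral signatures; amplitudes sized so every
    non-idle behavior clears the 0.5012 mm^2 total-amplitude threshold after
    the median/Gaussian smoothing stage."""
    legs = dict.fromkeys(LEG_NODES)
    return {
        "idle": BehaviorArchetype("idle"),
        "proboscis": BehaviorArchetype(
            "proboscis", node_freq_hz={"proboscis": 2.0}, node_amp_mm={"proboscis": 2.0},
            proboscis_visible=0.95),
        "fore_groom": BehaviorArchetype(
            "fore_groom",
            node_freq_hz={"forelegL": 8.0, "forelegR": 8.0},
            node_amp_mm={"forelegL": 1.5, "forelegR": 1.5}),
        "hind_groom": BehaviorArchetype(
            "hind_groom",
            node_freq_hz={"hindlegL": 10.0, "hindlegR": 10.0},
            node_amp_mm={"hindlegL": 1.6, "hindlegR": 1.6}),
        "wing_groom": BehaviorArchetype(
            "wing_groom",
            node_freq_hz={"wingL": 5.0, "wingR": 5.0},
            node_amp_mm={"wingL": 1.5, "wingR": 1.5}),
        "locomotion": BehaviorArchetype(
            "locomotion",
            node_freq_hz={n: 12.0 for n in legs}, node_amp_mm={n: 1.2 for n in legs},
            translation_speed_mm_s=3.0),
        "altered_locomotion": BehaviorArchetype(
            "altered_locomotion",
            node_freq_hz={n: 4.0 for n in legs}, node_amp_mm={n: 1.2 for n in legs},
            translation_speed_mm_s=1.0),
    }


def default_schedule() -> DiurnalSchedule:
    return DiurnalSchedule(
        lights_on_hour=8.0,
        day_state_weights={
            "idle": 0.30, "proboscis": 0.05, "fore_groom": 0.15, "hind_groom": 0.12,
            "wing_groom": 0.08, "locomotion": 0.22, "altered_locomotion": 0.08,
        },
        night_state_weights={
            "idle": 0.75, "proboscis": 0.07, "fore_groom": 0.08, "hind_groom": 0.02,
            "wing_groom": 0.02, "locomotion": 0.04, "altered_locomotion": 0.02,
        },
        dwell_short_p=0.005, dwell_long_p=0.001, dwell_mix_w=0.3,
    )


def generate_state_sequence(
    schedule: DiurnalSchedule,
    archetypes: Sequence[BehaviorArchetype] | Mapping[str, BehaviorArchetype],
    n_frames: int,
    fps: float,
    seed: int,
    zt0: float = 0.0,
    return_bouts: bool = False,
):
    """Semi-Markov behavior label sequence with ZT-dependent occupancy.

    At each bout start the current Zeitgeber time selects day or night weights
    (day = ZT [0, 12)); the state is drawn with probability proportional to
    weight/mean_dwell and the dwell length from the behavior's two-geometric
    mixture.  With ``return_bouts`` the drawn (state, start, duration) triples
    are returned as well (adjacent bouts may share a state, so drawn dwells are
    not recoverable from the label sequence alone).
    """
    if isinstance(archetypes, Mapping):
        arch_names = list(archetypes)
    else:
        arch_names = [a.name for a in archetypes]
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    if not arch_names:
        raise ConfigurationError("need at least one archetype")
    for weights in (schedule.day_state_weights, schedule.night_state_weights):
        unknown = set(weights) - set(arch_names)
        if unknown:
            raise ConfigurationError(f"weights refer to unknown behaviors: {sorted(unknown)}")

    weighted = set(schedule.day_state_weights) | set(schedule.night_state_weights)
    if weighted:
        arch_names = [n for n in arch_names if n in weighted]
    mean_dwell = np.array([schedule.mean_dwell(n) for n in arch_names])

    def entry_probs(weights: Mapping[str, float]) -> np.ndarray:
        w = np.array([float(weights.get(n, 0.0)) for n in arch_names])
        if np.any(w < 0) or w.sum() == 0:
            raise ConfigurationError("weights must be >= 0 and not all zero")
        rate = w / mean_dwell
        return rate / rate.sum()

    p_day = entry_probs(schedule.day_state_weights or dict.fromkeys(arch_names, 1.0))
    p_night = entry_probs(schedule.night_state_weights or schedule.day_state_weights
                          or dict.fromkeys(arch_names, 1.0))

    rng = np.random.default_rng(seed)
    codes = np.empty(n_frames, dtype=np.int32)
    bouts: list[tuple[str, int, int]] = []
    cursor = 0
    idx = np.arange(len(arch_names))
    while cursor < n_frames:
        zt = (zt0 + cursor / fps / 3600.0) % 24.0
        p = p_day if zt < 12.0 else p_night
        state = int(rng.choice(idx, p=p))
        w, ps, pl = schedule.dwell_params(arch_names[state])
        pgeo = ps if rng.random() < w else pl
        dwell = int(rng.geometric(pgeo))
        dwell = min(dwell, n_frames - cursor)
        codes[cursor:cursor + dwell] = state
        bouts.append((arch_names[state], cursor, dwell))
        cursor += dwell
    labels = np.array(arch_names, dtype="U20")[codes] if n_frames else np.empty(0, dtype="U20")
    if return_bouts:
        return labels, bouts
    return labels


def _confined_walk(step: np.ndarray, theta: np.ndarray, r_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Integrate per-frame steps inside a disc of radius ``r_max`` (centered at
    the origin), reflecting the heading off the wall; preserves step lengths.

    Only frames with a nonzero step are visited, so long stationary stretches
    cost nothing.  Returns (positions, possibly-updated headings).
    """
    n = step.size
    pos = np.zeros((n, 2))
    theta = theta.copy()
    p = np.zeros(2)
    moving = np.flatnonzero(step > 0)
    prev = 0
    for i in moving:
        if i > prev:
            pos[prev:i] = p
        th = theta[i]
        v = step[i] * np.array([np.cos(th), np.sin(th)])
        q = p + v
        r = np.hypot(q[0], q[1])
        if r > r_max:
            nvec = q / r
            v = v - 2.0 * (v @ nvec) * nvec
            q = p + v
            r2 = np.hypot(q[0], q[1])
            if r2 > r_max:                       # grazing corner case
                q *= r_max / r2
            # subsequent frames continue along the reflected heading
            theta[i:] += np.arctan2(v[1], v[0]) - th
        p = q
        pos[i] = p
        prev = i + 1
    if prev < n:
        pos[prev:] = p
    return pos, theta


def render_pose(
    states: np.ndarray,
    archetypes: Mapping[str, BehaviorArchetype] | Sequence[BehaviorArchetype],
    config: SynthConfig,
    seed: int,
    t0_clock: datetime | None = None,
    fly_id: str = "fly0",
) -> PoseSequence:
    """Render a state sequence onto the rigid body template.

    The body translates at the archetype speed along a heading random walk
    (frozen while speed is zero, so an all-idle fly is exactly stationary) and
    is confined to the arena disc by radial reflection.  Oscillating nodes are
    displaced sinusoidally along the body x-axis with a fresh phase per bout;
    an invisible proboscis coincides with the head and is marked missing.
    """
    if isinstance(archetypes, Mapping):
        arch = dict(archetypes)
    else:
        arch = {a.name: a for a in archetypes}
    states = np.asarray(states)
    n = states.size
    missing_arch = set(np.unique(states)) - set(arch)
    if missing_arch:
        raise ConfigurationError(f"states without archetype: {sorted(missing_arch)}")
    names = sorted(arch)
    name_to_code = {s: i for i, s in enumerate(names)}
    codes = np.array([name_to_code[s] for s in states], dtype=np.int32)

    amp = np.zeros((len(names), len(NODE_NAMES)))
    freq = np.zeros_like(amp)
    speed = np.zeros(len(names))
    vis = np.zeros(len(names))
    for i, s in enumerate(names):
        a = arch[s]
        speed[i] = a.translation_speed_mm_s
        vis[i] = a.proboscis_visible
        for node, v in a.node_amp_mm.items():
            amp[i, NODE_NAMES.index(node)] = v
        for node, v in a.node_freq_hz.items():
            freq[i, NODE_NAMES.index(node)] = v

    rng = np.random.default_rng(seed)
    fps, ppm = config.fps, config.px_per_mm
    t = np.arange(n) / fps

    # heading random walk, frozen while stationary
    frame_speed = speed[codes] if n else np.empty(0)
    moving = frame_speed > 0
    dtheta = rng.normal(0.0, config.heading_sd, n) * moving
    theta = rng.uniform(0, 2 * np.pi) + np.cumsum(dtheta)

    # trajectory confined to the arena disc by wall reflection
    arena = config.arena
    r_max = arena.radius_px - config.confine_margin_mm * ppm
    step = frame_speed / fps * ppm
    path, theta = _confined_walk(step, theta, r_max)
    pos = path + np.asarray(arena.center_px)

    # per-bout oscillation phases
    if n:
        bout_id = np.concatenate([[0], np.cumsum(np.diff(codes) != 0)])
        phases = rng.uniform(0, 2 * np.pi, (bout_id[-1] + 1, len(NODE_NAMES)))
        phase = phases[bout_id]
    else:
        phase = np.zeros((0, len(NODE_NAMES)))

    template = np.array([BODY_TEMPLATE_MM[nm] for nm in NODE_NAMES])
    osc_x = amp[codes] * np.sin(2 * np.pi * freq[codes] * t[:, None] + phase)
    local_x = template[None, :, 0] + osc_x
    local_y = np.broadcast_to(template[None, :, 1], local_x.shape)

    cos, sin = np.cos(theta), np.sin(theta)
    coords = np.empty((n, len(NODE_NAMES), 2))
    coords[..., 0] = pos[:, 0:1] + ppm * (cos[:, None] * local_x - sin[:, None] * local_y)
    coords[..., 1] = pos[:, 1:2] + ppm * (sin[:, None] * local_x + cos[:, None] * local_y)

    missing = np.zeros((n, len(NODE_NAMES)), dtype=bool)
    visible = rng.random(n) < vis[codes] if n else np.empty(0, dtype=bool)
    coords[~visible, PROBOSCIS, :] = coords[~visible, HEAD, :]
    missing[~visible, PROBOSCIS] = True

    coords[missing] = np.nan
    return PoseSequence(coords=coords, missing=missing, fps=fps, px_per_mm=ppm,
                        t0_clock=t0_clock, fly_id=fly_id)


def corrupt(
    pose: PoseSequence,
    config: SynthConfig,
    seed: int,
    states: np.ndarray | None = None,
) -> tuple[PoseSequence, GroundTruth]:
    """Apply wall bouts, per-node dropout, and Gaussian jitter.

    Edge bouts translate the whole body so the thorax sits within
    ``wall_margin_mm`` of the wall and (optionally) drop the leg nodes, the
    regime the edge classifier must flag.  Returns the corrupted pose and the
    aligned GroundTruth (``states`` fills the true ethogram when provided).
    """
    rng = np.random.default_rng(seed)
    n = pose.n_frames
    coords = pose.coords.copy()
    missing = pose.missing.copy()
    ppm = pose.px_per_mm
    arena = config.arena

    edge_mask = np.zeros(n, dtype=bool)
    if config.edge_bout_rate > 0 and config.edge_bout_duration_s > 0 and n:
        starts = np.flatnonzero(rng.random(n) < config.edge_bout_rate / pose.fps)
        p_dur = 1.0 / (config.edge_bout_duration_s * pose.fps)
        for s in starts:
            edge_mask[s:s + int(rng.geometric(min(p_dur, 1.0)))] = True
    if edge_mask.any():
        thorax = coords[edge_mask, THORAX, :] - np.asarray(arena.center_px)
        r = np.hypot(thorax[:, 0], thorax[:, 1])
        ang = np.where(r > 0, np.arctan2(thorax[:, 1], thorax[:, 0]), 0.0)
        r_edge = arena.radius_px - config.wall_margin_mm * ppm
        target = np.stack([r_edge * np.cos(ang), r_edge * np.sin(ang)], axis=1) \
            + np.asarray(arena.center_px)
        shift = target - coords[edge_mask, THORAX, :]
        coords[edge_mask] += shift[:, None, :]
        if config.edge_drop_legs:
            for leg in LEG_NODES:
                missing[edge_mask, NODE_NAMES.index(leg)] = True

    if config.missing_rate > 0:
        missing |= rng.random((n, len(NODE_NAMES))) < config.missing_rate
    if config.noise_sd_mm > 0:
        coords += rng.normal(0.0, config.noise_sd_mm * ppm, coords.shape)

    coords[missing] = np.nan
    out = PoseSequence(coords=coords, missing=missing, fps=pose.fps, px_per_mm=ppm,
                       t0_clock=pose.t0_clock, fly_id=pose.fly_id, node_names=pose.node_names)
    truth = GroundTruth(
        true_ethogram=None if states is None else np.asarray(states).copy(),
        true_edge_mask=edge_mask,
        true_missing_mask=missing.copy(),
    )
    return out, truth


def simulate_fly(
    config: SynthConfig,
    schedule: DiurnalSchedule | None = None,
    archetypes: Mapping[str, BehaviorArchetype] | None = None,
    seed: int | None = None,
    fly_id: str = "fly0",
    t0_clock: datetime | None = None,
    zt0: float = 0.0,
) -> tuple[PoseSequence, GroundTruth]:
    """generate_state_sequence -> render_pose -> corrupt for one fly."""
    schedule = schedule or default_schedule()
    archetypes = archetypes or default_archetypes()
    seed = config.seed if seed is None else seed
    sub = [int(np.random.default_rng(s).integers(2**31))
           for s in np.random.SeedSequence(seed).spawn(3)]
    n_frames = int(round(config.n_hours * 3600 * config.fps))
    states = generate_state_sequence(schedule, archetypes, n_frames, config.fps,
                                     seed=sub[0], zt0=zt0)
    pose = render_pose(states, archetypes, config, seed=sub[1],
                       t0_clock=t0_clock, fly_id=fly_id)
    pose, truth = corrupt(pose, config, seed=sub[2], states=states)
    return pose, truth
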