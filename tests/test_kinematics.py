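from datetime import datetime, time

import numpy as np
import pytest
from scipy.stats import chisquare

from ethospan._alphabet import THORAX
from ethospan.ethogram import Ethogram
from ethospan.kinematics import (bout_duration_stats, frame_zeitgeber, locomotion_speed,
                                 radial_occupancy, speed_by_group, zeitgeber_time)
from ethospan.preprocess import ArenaGeometry
from ethospan.synth import (DiurnalSchedule, SynthConfig, default_archetypes,
                            generate_state_sequence, render_pose)

from conftest import make_pose


class TestZeitgeberTime:
    def test_lights_on_is_zero(self):
        clock = datetime(2022, 2, 17, 8, 0)
        zt = zeitgeber_time(clock, time(8, 0), experiment_start=clock)
        assert zt.zt_hours == 0.0
        assert zt.day_index == 1

    def test_lights_off_is_twelve(self):
        start = datetime(2022, 2, 17, 8, 0)
        zt = zeitgeber_time(datetime(2022, 2, 17, 20, 0), time(8, 0), start)
        assert zt.zt_hours == 12.0

    def test_wraps_same_day_index(self):
        start = datetime(2022, 2, 17, 8, 0)
        zt = zeitgeber_time(datetime(2022, 2, 18, 7, 0), time(8, 0), start)
        assert zt.zt_hours == pytest.approx(23.0)
        assert zt.day_index == 1
        nxt = zeitgeber_time(datetime(2022, 2, 18, 9, 0), time(8, 0), start)
        assert nxt.day_index == 2

    def test_before_start_errors(self):
        start = datetime(2022, 2, 17, 8, 0)
        with pytest.raises(ValueError):
            zeitgeber_time(datetime(2022, 2, 16, 8, 0), time(8, 0), start)

    def test_frame_zeitgeber_defaults_to_zt0(self):
        etho = Ethogram(labels=np.full(7200, "idle", dtype="U20"), fps=1.0)
        zt, day = frame_zeitgeber(etho)
        assert zt[0] == 0.0
        assert zt[3600] == pytest.approx(1.0)
        assert np.all(day == 1)


class TestLocomotionSpeed:
    def test_stationary_zero(self, static_pose):
        etho = Ethogram(labels=np.full(static_pose.n_frames, "locomotion", dtype="U20"))
        s = locomotion_speed(static_pose, etho)
        assert np.nanmax(s.values) == 0.0

    def test_px_per_frame_conversion(self):
        n = 200
        coords = np.zeros((n, 14, 2))
        coords[:, :, 0] = np.arange(n)[:, None]      # 1 px/frame
        pose = make_pose(coords, fps=100.0, px_per_mm=28.25)
        etho = Ethogram(labels=np.full(n, "locomotion", dtype="U20"))
        s = locomotion_speed(pose, etho)
        assert np.allclose(s.values[~np.isnan(s.values)], 100.0 / 28.25)
        assert 100.0 / 28.25 == pytest.approx(3.5398, abs=1e-4)

    def test_windows_confined_to_bouts(self):
        n = 40
        coords = np.zeros((n, 14, 2))
        coords[20:, :, 0] = 1000.0                   # huge jump in the idle half
        pose = make_pose(coords, fps=100.0, px_per_mm=1.0)
        labels = np.array(["locomotion"] * 18 + ["idle"] * 22, dtype="U20")
        s = locomotion_speed(pose, Ethogram(labels=labels))
        assert np.nanmax(s.values[:18]) == 0.0

    def test_speed_rotation_invariant(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(0, 1, (100, 14, 2)).cumsum(axis=0)
        etho = Ethogram(labels=np.full(100, "locomotion", dtype="U20"))
        base = locomotion_speed(make_pose(coords), etho).values
        ang = 0.9
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rot = locomotion_speed(make_pose(coords @ R.T + 50.0), etho).values
        assert np.allclose(base, rot, equal_nan=True, atol=1e-9)

    def test_day_night_speed_recovery(self):
        """Generator round-trip: 3 mm/s day locomotion vs 2 mm/s night."""
        arch = default_archetypes()
        cfg = SynthConfig(missing_rate=0.0, edge_bout_rate=0.0, noise_sd_mm=0.0)
        results = {}
        for speed, seed in ((3.0, 31), (2.0, 32)):
            import dataclasses
            loco = dataclasses.replace(arch["locomotion"], translation_speed_mm_s=speed)
            pose = render_pose(np.full(12000, "locomotion", dtype="U20"),
                               {**arch, "locomotion": loco}, cfg, seed=seed)
            etho = Ethogram(labels=np.full(12000, "locomotion", dtype="U20"), fps=cfg.fps)
            s = locomotion_speed(pose, etho)
            results[speed] = np.nanmean(s.values)
        assert results[3.0] == pytest.approx(3.0, rel=0.05)
        assert results[2.0] == pytest.approx(2.0, rel=0.05)
        assert results[3.0] / results[2.0] == pytest.approx(1.5, rel=0.05)

    def test_speed_by_group(self):
        n = 7200
        coords = np.zeros((n, 14, 2))
        coords[:, :, 0] = np.arange(n)[:, None]
        pose = make_pose(coords, fps=1.0, px_per_mm=1.0)
        etho = Ethogram(labels=np.full(n, "locomotion", dtype="U20"), fps=1.0)
        s = locomotion_speed(pose, etho)
        zt, day = frame_zeitgeber(etho)
        out = speed_by_group(s, zt, day, group_by="zt_hour")
        assert set(out["group"]) == {0, 1}
        assert np.allclose(out["mean"], 1.0)


class TestBoutDurationStats:
    def test_single_bout_seconds(self):
        labels = np.array(["proboscis"] * 300 + ["idle"] * 300, dtype="U20")
        etho = Ethogram(labels=labels, fps=100.0)
        out = bout_duration_stats(etho, "proboscis")
        assert out.loc[0, "mean"] == pytest.approx(3.0)

    def test_start_frame_rule_at_hour_boundary(self):
        # bout starting just before ZT 12 counts in hour 11
        fps = 1.0
        n = int(12 * 3600)
        labels = np.full(n + 100, "idle", dtype="U20")
        labels[n - 30: n + 30] = "proboscis"
        etho = Ethogram(labels=labels, fps=fps)
        out = bout_duration_stats(etho, "proboscis")
        assert list(out["group"]) == [11]

    def test_no_bouts_empty(self):
        etho = Ethogram(labels=np.full(100, "idle", dtype="U20"))
        out = bout_duration_stats(etho, "wing_groom")
        assert out.empty

    def test_day_night_duration_ratio_recovery(self):
        """Night proboscis bouts drawn 1.5x longer than day bouts."""
        arch = default_archetypes()
        fps = 10.0
        half = int(12 * 3600 * fps)
        segs = []
        for p_mean, seed in ((200.0, 51), (300.0, 52)):
            # short idle dwells keep proboscis self-transitions (bout merges) rare
            sched = DiurnalSchedule(
                day_state_weights={"proboscis": 0.5, "idle": 0.5},
                night_state_weights={"proboscis": 0.5, "idle": 0.5},
                dwell_short_p={"proboscis": 1.0 / p_mean, "idle": 0.1},
                dwell_long_p={"proboscis": 1.0 / p_mean, "idle": 0.1},
                dwell_mix_w=0.5)
            segs.append(generate_state_sequence(sched, arch, half, fps, seed=seed))
        etho = Ethogram(labels=np.concatenate(segs), fps=fps)
        out = bout_duration_stats(etho, "proboscis", group_by="zt_hour")
        day_mean = out[out["group"] < 12]["mean"].mean()
        night_mean = out[out["group"] >= 12]["mean"].mean()
        assert night_mean / day_mean == pytest.approx(1.5, abs=0.1)

    def test_frame_rate_reexpression(self):
        labels = np.array(["proboscis"] * 300 + ["idle"] * 300, dtype="U20")
        a = bout_duration_stats(Ethogram(labels=labels, fps=100.0), "proboscis")
        b = bout_duration_stats(Ethogram(labels=np.repeat(labels, 2), fps=200.0), "proboscis")
        assert a.loc[0, "mean"] == pytest.approx(b.loc[0, "mean"])


class TestRadialOccupancy:
    def arena(self):
        return ArenaGeometry(center_px=(0.0, 0.0), radius_px=100.0, px_per_mm=1.0)

    def test_uniform_fill(self):
        rng = np.random.default_rng(2)
        n = 10**5
        r = 100.0 * np.sqrt(rng.random(n))
        ang = rng.uniform(0, 2 * np.pi, n)
        coords = np.zeros((n, 14, 2))
        coords[:, THORAX, 0] = r * np.cos(ang)
        coords[:, THORAX, 1] = r * np.sin(ang)
        pose = make_pose(coords)
        etho = Ethogram(labels=np.full(n, "idle", dtype="U20"))
        out = radial_occupancy(pose, self.arena(), etho, n_bins=10)
        stat, p = chisquare(out["n_frames"])
        assert p > 0.01

    def test_all_center(self):
        coords = np.zeros((50, 14, 2))
        etho = Ethogram(labels=np.full(50, "idle", dtype="U20"))
        out = radial_occupancy(make_pose(coords), self.arena(), etho, n_bins=5)
        assert out.loc[0, "n_frames"] == 50
        assert out["n_frames"][1:].sum() == 0

    def test_wall_following_outermost(self):
        rng = np.random.default_rng(3)
        n = 2000
        ang = rng.uniform(0, 2 * np.pi, n)
        coords = np.zeros((n, 14, 2))
        coords[:, THORAX, 0] = 97.0 * np.cos(ang)
        coords[:, THORAX, 1] = 97.0 * np.sin(ang)
        etho = Ethogram(labels=np.full(n, "locomotion", dtype="U20"))
        out = radial_occupancy(make_pose(coords), self.arena(), etho, n_bins=10)
        assert out.loc[9, "n_frames"] == n

    def test_outside_clamped_with_warning(self):
        coords = np.zeros((10, 14, 2))
        coords[:, THORAX, 0] = 120.0
        etho = Ethogram(labels=np.full(10, "idle", dtype="U20"))
        with pytest.warns(UserWarning, match="clamp"):
            out = radial_occupancy(make_pose(coords), self.arena(), etho, n_bins=4)
        assert out["n_frames"].sum() == 10
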