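import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ethospan._alphabet import BEHAVIORS
from ethospan.compositional import (clr, clr_inv, closure, condense, day_night_difference,
                                    default_ilr_basis, enrichment_bootstrap,
                                    geometric_mean_composition, hourly_compositions, ilr,
                                    ilr_inv, pc_direction_curve, robust_composition_pca,
                                    ternary_coords)
from ethospan.ethogram import Ethogram


def random_compositions(n, d=7, seed=0):
    rng = np.random.default_rng(seed)
    return closure(rng.dirichlet(np.ones(d) * 2, size=n))


def comp_table(parts, zt=None, day=None, fly="fly0"):
    df = pd.DataFrame(parts, columns=list(BEHAVIORS))
    df["fly_id"] = fly
    df["zt_hour"] = zt if zt is not None else np.arange(len(parts)) % 24
    df["day_index"] = day if day is not None else 1
    df["n_frames_used"] = 1000
    return df


def make_ethogram(runs, fps=10.0):
    labels = np.concatenate([np.full(n, lab, dtype="U20") for lab, n in runs])
    return Ethogram(labels=labels, fps=fps)


class TestHourlyCompositions:
    def test_counts_to_fractions(self):
        # one ZT hour at 1 fps: 3600 frames
        etho = make_ethogram([("idle", 1800), ("locomotion", 1200), ("fore_groom", 600)],
                             fps=1.0)
        comps = hourly_compositions(etho, zero_strategy="none")
        assert len(comps) == 1
        row = comps.iloc[0]
        assert row["idle"] == pytest.approx(0.5)
        assert row["locomotion"] == pytest.approx(1200 / 3600)
        assert row["fore_groom"] == pytest.approx(600 / 3600)
        assert row["n_frames_used"] == 3600

    def test_edge_frames_excluded_from_denominator(self):
        etho = make_ethogram([("edge", 1800), ("idle", 900), ("locomotion", 900)], fps=1.0)
        comps = hourly_compositions(etho, zero_strategy="none")
        row = comps.iloc[0]
        assert row["idle"] == pytest.approx(0.5)
        assert row["n_frames_used"] == 1800

    def test_zero_replacement_closes_to_one(self):
        etho = make_ethogram([("idle", 3000), ("locomotion", 600)], fps=1.0)
        comps = hourly_compositions(etho)
        parts = comps[list(BEHAVIORS)].to_numpy()
        assert np.all(parts > 0)
        assert parts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sparse_hour_dropped(self):
        etho = make_ethogram([("idle", 3600), ("edge", 3400), ("idle", 200)], fps=1.0)
        with pytest.warns(UserWarning, match="dropped"):
            comps = hourly_compositions(etho)
        assert len(comps) == 1

    def test_scale_invariance(self):
        runs = [("idle", 1200), ("locomotion", 1200), ("fore_groom", 1200)]
        a = hourly_compositions(make_ethogram(runs, fps=1.0), min_frames_frac=0.01)
        b = hourly_compositions(make_ethogram([(l, n * 3) for l, n in runs], fps=3.0),
                                min_frames_frac=0.01)
        assert np.allclose(a[list(BEHAVIORS)].to_numpy(), b[list(BEHAVIORS)].to_numpy())


class TestGeometricMean:
    def test_identity(self):
        x = random_compositions(1, seed=1)
        assert np.allclose(geometric_mean_composition(x), x[0], atol=1e-12)

    def test_hand_computed_three_part(self):
        # brute-force oracle: per-part geometric mean of the two rows, re-closed
        a = np.array([0.5, 0.3, 0.2])
        b = np.array([0.2, 0.3, 0.5])
        raw = np.sqrt(a * b)
        expected = raw / raw.sum()
        got = geometric_mean_composition(np.stack([a, b]))
        assert np.allclose(got, expected, atol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_perturbation_equivariance(self):
        x = random_compositions(5, seed=2)
        p = closure(np.array([3.0, 1.0, 0.5, 2.0, 1.0, 0.25, 4.0]))
        lhs = geometric_mean_composition(closure(x * p))
        rhs = closure(geometric_mean_composition(x) * p)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_permutation_equivariance(self):
        x = random_compositions(5, seed=3)
        perm = np.random.default_rng(0).permutation(7)
        assert np.allclose(geometric_mean_composition(x[:, perm]),
                           geometric_mean_composition(x)[perm], atol=1e-12)


class TestLogRatios:
    def test_uniform_clr_zero(self):
        assert np.allclose(clr(np.full(7, 1 / 7)), 0.0, atol=1e-12)

    def test_clr_rows_sum_zero(self):
        x = random_compositions(20, seed=4)
        assert np.max(np.abs(clr(x).sum(axis=1))) < 1e-10

    def test_default_basis_properties(self):
        B = default_ilr_basis(7)
        assert np.allclose(B @ B.T, np.eye(6), atol=1e-12)
        assert np.allclose(B.sum(axis=1), 0.0, atol=1e-12)

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_ilr_round_trip(self, seed):
        x = random_compositions(4, seed=seed)
        assert np.max(np.abs(ilr_inv(ilr(x)) - x)) < 1e-10

    def test_nonpositive_part_errors(self):
        bad = np.array([0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            clr(bad)

    def test_clr_inv_inverts(self):
        x = random_compositions(6, seed=5)
        assert np.allclose(clr_inv(clr(x)), x, atol=1e-12)


def diurnal_cohort(n_days=2, n_flies=3, outlier_frac=0.0, seed=0):
    """Fly-hours with a single day/night locomotion<->idle contrast axis."""
    rng = np.random.default_rng(seed)
    day_center = np.array([0.15, 0.05, 0.15, 0.12, 0.08, 0.33, 0.12])
    night_center = np.array([0.72, 0.07, 0.08, 0.03, 0.03, 0.04, 0.03])
    rows, meta = [], []
    for f in range(n_flies):
        for d in range(1, n_days + 1):
            for h in range(24):
                center = day_center if h < 12 else night_center
                x = closure(center * np.exp(rng.normal(0, 0.08, 7)))
                if rng.random() < outlier_frac:
                    x = closure(np.array([0.01, 0.9, 0.02, 0.02, 0.02, 0.02, 0.01]))
                rows.append(x)
                meta.append((f"fly{f}", d, h))
    parts = np.array(rows)
    df = pd.DataFrame(parts, columns=list(BEHAVIORS))
    df["fly_id"], df["day_index"], df["zt_hour"] = zip(*meta)
    df["n_frames_used"] = 1000
    return df


class TestRobustPCA:
    def test_clr_loadings_sum_zero(self):
        pca = robust_composition_pca(diurnal_cohort(), seed=0)
        assert np.max(np.abs(pca.clr_loadings.sum(axis=1))) < 1e-9

    def test_variance_explained_sorted(self):
        pca = robust_composition_pca(diurnal_cohort(seed=1), seed=0)
        assert np.all(np.diff(pca.variance_explained) <= 1e-12)
        assert pca.variance_explained.sum() == pytest.approx(1.0)

    def test_basis_invariance(self):
        tab = diurnal_cohort(seed=2)
        B1 = default_ilr_basis(7)
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        B2 = Q @ B1
        a = robust_composition_pca(tab, basis=B1, seed=0)
        b = robust_composition_pca(tab, basis=B2, seed=0)
        assert np.max(np.abs(a.scores - b.scores)) < 1e-8
        assert np.max(np.abs(a.clr_loadings - b.clr_loadings)) < 1e-8

    def test_pc1_sign_structure_with_outliers(self):
        tab = diurnal_cohort(n_days=3, outlier_frac=0.05, seed=4)
        pca = robust_composition_pca(tab, seed=0)
        idx = {b: i for i, b in enumerate(BEHAVIORS)}
        assert pca.clr_loadings[0, idx["locomotion"]] > 0
        assert pca.clr_loadings[0, idx["idle"]] < 0

    def test_pc1_recovers_diurnal_axis(self):
        tab = diurnal_cohort(n_days=3, seed=5)
        pca = robust_composition_pca(tab, seed=0)
        indicator = (tab["zt_hour"] < 12).to_numpy(float)
        assert np.corrcoef(pca.scores[:, 0], indicator)[0, 1] >= 0.9

    def test_too_few_rows_errors(self):
        with pytest.raises(ValueError):
            robust_composition_pca(diurnal_cohort().head(5), seed=0)

    def test_classical_fallback(self):
        pca = robust_composition_pca(diurnal_cohort(seed=6), robust=False, seed=0)
        assert not pca.robust
        assert pca.mcd_support_fraction is None


class TestDayNight:
    def test_identical_scores_zero(self):
        tab = diurnal_cohort(seed=7)
        sc = pd.DataFrame({"score": 1.5, "zt_hour": tab["zt_hour"],
                           "day_index": tab["day_index"], "fly_id": tab["fly_id"]})
        out = day_night_difference(sc)
        assert np.allclose(out["mean"], 0.0)

    def test_constructed_difference(self):
        tab = diurnal_cohort(seed=8)
        score = np.where(tab["zt_hour"] < 12, 1.0, -1.0)
        sc = pd.DataFrame({"score": score, "zt_hour": tab["zt_hour"],
                           "day_index": tab["day_index"], "fly_id": tab["fly_id"]})
        out = day_night_difference(sc)
        assert np.allclose(out["mean"], 2.0)
        assert np.allclose(out["se"], 0.0)

    def test_missing_side_dropped(self):
        sc = pd.DataFrame({"score": [1.0, 2.0], "zt_hour": [3, 4],
                           "day_index": [1, 1], "fly_id": ["a", "a"]})
        out = day_night_difference(sc)
        assert len(out) == 0


class TestCondenseTernary:
    def test_seven_to_three(self):
        parts = np.array([0.4, 0.05, 0.1, 0.1, 0.1, 0.2, 0.05])
        got = condense(parts)
        assert np.allclose(got, [0.30, 0.25, 0.45], atol=1e-12)

    def test_vertex_maps_to_origin(self):
        assert np.allclose(ternary_coords(np.array([1.0, 0.0, 0.0])), (0.0, 0.0))

    def test_centroid(self):
        x, y = ternary_coords(np.array([1 / 3, 1 / 3, 1 / 3]))
        assert x == pytest.approx(0.5)
        assert y == pytest.approx(np.sqrt(3) / 6, abs=1e-12)


class TestPerturbationCurve:
    def test_zero_scale_identity(self):
        center = random_compositions(1, seed=9)[0]
        loading = clr(random_compositions(1, seed=10))[0]
        out = pc_direction_curve(center, loading, np.array([0.0]))
        assert np.allclose(out[0], center, atol=1e-12)

    def test_group_property(self):
        center = random_compositions(1, seed=11)[0]
        loading = clr(random_compositions(1, seed=12))[0]
        one = pc_direction_curve(center, loading, np.array([0.7]))[0]
        two = pc_direction_curve(one, loading, np.array([0.5]))[0]
        direct = pc_direction_curve(center, loading, np.array([1.2]))[0]
        assert np.max(np.abs(two - direct)) < 1e-10

    def test_groom_loading_moves_ternary_monotonically(self):
        center = np.full(7, 1 / 7)
        # loading contrasting grooming vs everything else, clr (zero-sum)
        raw = np.array([-1.0, -1.0, 1.0, 1.0, 1.0, -0.5, -0.5])
        loading = raw - raw.mean()
        scales = np.linspace(-1, 1, 9)
        curve = pc_direction_curve(center, loading, scales)
        groom = condense(curve)[:, 0]
        assert np.all(np.diff(groom) > 0)


class TestEnrichment:
    def test_identical_hour_and_reference(self):
        parts = np.tile(closure(np.arange(1.0, 8.0)), (5, 1))
        e = enrichment_bootstrap(parts, parts[0], part=2, n_boot=200, seed=0)
        assert e.ratio == pytest.approx(1.0)
        assert e.ci_low <= 1.0 <= e.ci_high

    def test_doubled_part_degenerate_ci(self):
        ref = closure(np.arange(1.0, 8.0))
        hour = np.tile(closure(ref * np.array([1, 1, 2, 1, 1, 1, 1.0])), (6, 1))
        scale = hour[0, 2] / ref[2]
        e = enrichment_bootstrap(hour, ref, part=2, n_boot=300, seed=1)
        assert e.ratio == pytest.approx(scale)
        assert e.ci_high - e.ci_low < 1e-9

    def test_morning_groom_boost_detected(self):
        hits = 0
        ref = closure(np.array([0.5, 0.05, 0.1, 0.1, 0.05, 0.15, 0.05]))
        for seed in range(20):
            rng = np.random.default_rng(seed)
            hour = closure(ref * np.exp(rng.normal(0, 0.1, (6, 7)))
                           * np.array([1, 1, 1.8, 1.8, 1.8, 1, 1.0]))
            e = enrichment_bootstrap(hour, ref, part=2, n_boot=400, seed=seed)
            if e.ratio > 1 and e.ci_low > 1:
                hits += 1
        assert hits >= 11

    def test_warns_small_bootstrap(self):
        parts = np.tile(closure(np.arange(1.0, 8.0)), (3, 1))
        with pytest.warns(UserWarning):
            enrichment_bootstrap(parts, parts[0], part=0, n_boot=50, seed=0)

    def test_needs_two_flies(self):
        parts = closure(np.arange(1.0, 8.0))[None, :]
        with pytest.raises(ValueError):
            enrichment_bootstrap(parts, parts[0], part=0, n_boot=200, seed=0)
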