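"""Path curvature, travel distances, correlations, flow patterns."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import oroflow as of


# ---------------------------------------------------------------------------
# brute-force rank oracles (independent of scipy)
# ---------------------------------------------------------------------------

def kruskal_h_brute(groups):
    """Kruskal-Wallis H by direct rank arithmetic with tie correction."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank (1-based)
        i = j
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start: start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n) if n > 1 else 1.0
    return h / tie if tie > 0 else np.nan


def kendall_tau_b_brute(x, y):
    """Tau-b by exhaustive concordant/discordant pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom > 0 else np.nan


class TestMengerCurvature:
    def test_collinear_points_zero(self):
        path = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        k = of.menger_curvature(path)
        np.testing.assert_allclose(k[1:-1], 0, atol=1e-12)

    def test_unit_circumradius_triangle(self):
        # (0,0), (1,1), (2,0) in the (x,z) plane lie on a circle of radius 1
        path = np.array([[0.0, 9, 0], [1, -3, 1], [2, 5, 0]])
        k = of.menger_curvature(path)
        assert k[1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("radius", [7.0, 0.5, 120.0])
    def test_circle_oracle(self, radius):
        """Any sampling of a circle of radius R gives curvature 1/R."""
        rng = np.random.default_rng(0)
        theta = np.sort(rng.uniform(0, 2 * np.pi, 40))
        path = np.column_stack(
            [radius * np.cos(theta), rng.normal(size=40), radius * np.sin(theta)]
        )
        k = of.menger_curvature(path)
        np.testing.assert_allclose(k[1:-1], 1.0 / radius, atol=1e-9 / radius)

    def test_coincident_points_give_missing(self):
        path = np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 1]])
        k = of.menger_curvature(path)
        assert np.isnan(k[1])

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="3 frames"):
            of.menger_curvature(np.zeros((2, 3)))

    @given(st.floats(-np.pi, np.pi), st.floats(0.1, 10.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_rigid_invariance_and_scaling(self, angle, scale, seed):
        """Curvature is invariant to in-plane rotation/translation and
        scales as 1/s under spatial scaling by s."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 2)) * 5
        path = np.column_stack([pts[:, 0], np.zeros(8), pts[:, 1]])
        k0 = of.menger_curvature(path)
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
        moved = pts @ R.T + rng.normal(size=2) * 10
        path_m = np.column_stack([moved[:, 0], np.zeros(8), moved[:, 1]])
        np.testing.assert_allclose(of.menger_curvature(path_m), k0, rtol=1e-6, atol=1e-12)
        path_s = path * scale
        np.testing.assert_allclose(
            of.menger_curvature(path_s), k0 / scale, rtol=1e-6, atol=1e-12
        )


class TestIntervalMaxCurvature:
    def test_constant_curvature_fills_all_bins(self):
        x = np.linspace(0, 50, 60)
        series = np.full(60, 0.25)
        prof = of.interval_max_curvature(series, x, n_bins=10)
        np.testing.assert_allclose(prof.max_curvature, 0.25)
        assert prof.edges[0] == 0 and prof.edges[-1] == 100

    def test_localized_curvature_hits_last_bin_only(self):
        x = np.linspace(0, 100, 200)
        series = np.zeros(200)
        series[x > 90] = 3.0
        prof = of.interval_max_curvature(series, x, n_bins=10)
        assert prof.max_curvature[-1] == pytest.approx(3.0)
        np.testing.assert_allclose(prof.max_curvature[:-1], 0, atol=1e-12)

    def test_zero_span_raises(self):
        with pytest.raises(ValueError, match="span"):
            of.interval_max_curvature(np.ones(5), np.ones(5), 5)

    def test_water_bins_dominate_food_bins_noise_free(self):
        """The generator's lateral S-curves guarantee per-bin dominance."""
        world = of.generate_feeding_sequence(of.CARP, n_cycles=1, seed=3, noise_sd=0.0)
        anat, _, pt = of.analyze_world(world)
        water, food = of.intake_curvature_profiles(anat, pt)
        assert food, "food profile missing"
        fmax = food[0].max_curvature
        for prof in water:
            ok = np.isfinite(prof.max_curvature) & np.isfinite(fmax)
            assert np.all(prof.max_curvature[ok] >= fmax[ok])


class TestCompareCurvature:
    def profile(self, vals, name="t"):
        edges = np.linspace(0, 100, len(vals) + 1)
        return of.CurvatureProfile(name, edges, np.asarray(vals, float))

    def test_identical_groups_no_evidence(self):
        w = [self.profile([1.0, 2, 3])]
        f = [self.profile([1.0, 2, 3])]
        res = of.compare_curvature(w, f)
        assert res.p_value > 0.5

    def test_separated_groups_small_p_and_oracle_h(self):
        w = [self.profile([10.0, 20, 30])]
        f = [self.profile([1.0, 2, 3])]
        res = of.compare_curvature(w, f)
        assert res.medians[0] > res.medians[1]
        assert res.p_value < 0.05
        h_brute = kruskal_h_brute([np.array([10.0, 20, 30]), np.array([1.0, 2, 3])])
        assert res.statistic == pytest.approx(h_brute, rel=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            of.compare_curvature([], [self.profile([1.0])])

    def test_per_interval_mode_shape(self):
        w = [self.profile([1.0, 5.0]), self.profile([2.0, 6.0])]
        f = [self.profile([0.5, 1.0]), self.profile([0.7, 1.2])]
        out = of.compare_curvature(w, f, mode="per_interval")
        assert len(out) == 2

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=8),
        st.lists(st.integers(0, 5), min_size=2, max_size=8),
    )
    @settings(max_examples=40, deadline=None)
    def test_kruskal_matches_brute_force_on_small_inputs(self, a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if np.all(np.concatenate([a, b]) == a[0]):
            return  # degenerate all-equal case handled separately
        h_brute = kruskal_h_brute([a, b])
        h_scipy, _ = stats.kruskal(a, b)
        assert h_scipy == pytest.approx(h_brute, rel=1e-9, abs=1e-9)


class TestPhaseDistance:
    def table(self, t1=1.0):
        return of.PhaseTable(intervals=[of.PhaseInterval("intake", 0.0, t1, -50.0)])

    def test_pure_x_motion_components(self):
        n = 100
        path = np.column_stack([np.linspace(0, 10, n), np.zeros(n), np.zeros(n)])
        rec = of.phase_distance(path, self.table(), frame_rate=100.0)[0]
        assert rec["total_distance_mm"] == pytest.approx(10.0)
        assert rec["component_x_pct"] == pytest.approx(100.0)
        assert rec["component_y_pct"] == pytest.approx(0.0)

    def test_equal_axis_motion_components(self):
        n = 50
        ramp = np.linspace(0, 5, n)
        path = np.column_stack([ramp, ramp, ramp])
        rec = of.phase_distance(path, self.table(), frame_rate=50.0)[0]
        for key in ("component_x_pct", "component_y_pct", "component_z_pct"):
            assert rec[key] == pytest.approx(100.0 / 3.0, abs=1e-9)

    def test_straight_distance_independent_of_sampling(self):
        for n in (5, 17, 200):
            path = np.column_stack([np.linspace(0, 10, n), np.zeros(n), np.zeros(n)])
            rec = of.phase_distance(path, self.table(), frame_rate=(n - 1) / 1.0)[0]
            assert rec["total_distance_mm"] == pytest.approx(10.0)

    def test_components_sum_to_100(self, carp_analyzed):
        world, anat, _, pt = carp_analyzed
        for name in anat.tracks_of_kind("water_tracer")[:3]:
            for rec in of.phase_distance(anat.points[name], pt, anat.frame_rate):
                if rec["total_distance_mm"] > 0:
                    total = (rec["component_x_pct"] + rec["component_y_pct"]
                             + rec["component_z_pct"])
                    assert total == pytest.approx(100.0, abs=1e-6)

    def test_sparse_phase_omitted(self):
        path = np.full((10, 3), np.nan)
        path[0] = 0.0
        recs = of.phase_distance(path, self.table(t1=0.09), frame_rate=100.0)
        assert recs == []

    def test_water_travels_farther_than_food(self, carp_analyzed):
        """Pooled intake+rf+bf distance: water tracers > food tracer."""
        world, anat, _, pt = carp_analyzed

        def pooled(name):
            recs = of.phase_distance(anat.points[name], pt, anat.frame_rate)
            return sum(r["total_distance_mm"] for r in recs
                       if r["label"] in ("intake", "rf", "bf"))

        food = pooled("food_00")
        water = np.mean([pooled(n) for n in anat.tracks_of_kind("water_tracer")])
        assert water > food


class TestPositionalCorrelation:
    def test_monotone_pairs_give_tau_one(self, carp_analyzed):
        world, anat, _, pt = carp_analyzed
        res = of.positional_correlation(anat, pt, "z_begin_vs_z_end")
        assert res.test == "kendall-tau-b"
        assert res.statistic > 0.5
        assert res.p_value < 0.05

    def test_brute_force_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = rng.integers(3, 9)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            brute = kendall_tau_b_brute(x, y)
            tau, _ = stats.kendalltau(x, y)
            if np.isnan(brute):
                assert np.isnan(tau)
            else:
                assert tau == pytest.approx(brute, abs=1e-12)

    def test_one_discordant_swap_among_four(self):
        x = [1.0, 2, 3, 4]
        y = [1.0, 2, 4, 3]
        tau, _ = stats.kendalltau(x, y)
        assert tau == pytest.approx(kendall_tau_b_brute(x, y))
        assert tau == pytest.approx(4.0 / 6.0)

    def test_too_few_tracers_raises(self):
        n = 800
        pts = {"water_00": np.zeros((n, 3)), "food_00": np.zeros((n, 3))}
        ts = of.TrajectorySet(frame_rate=750.0, points=pts,
                              track_kind={"water_00": "water_tracer",
                                          "food_00": "food_tracer"})
        pt = of.PhaseTable(intervals=[of.PhaseInterval("intake", 0.0, 1.0, -50.0)])
        with pytest.raises(ValueError, match=">= 3 water tracers"):
            of.positional_correlation(ts, pt)

    def test_side_preservation_over_seeded_cohorts(self):
        """Side-preserving generator worlds give tau > 0, p < 0.05."""
        hits = 0
        for seed in range(10):
            world = of.generate_feeding_sequence(of.CARP, n_cycles=0, seed=seed)
            anat, _, pt = of.analyze_world(world)
            res = of.positional_correlation(anat, pt, "z_begin_vs_z_end")
            hits += (res.statistic > 0) and (res.p_value < 0.05)
        assert hits == 10


class TestClassifyFlowPattern:
    def intake_table(self, t1=0.4):
        return of.PhaseTable(intervals=[of.PhaseInterval("intake", 0.0, t1, -60.0)])

    def path(self, x, z):
        n = len(x)
        return np.column_stack([x, np.zeros(n), z])

    def test_straight_posterior(self):
        n = 300
        x = np.linspace(60, 10, n)
        z = np.full(n, 4.0)
        out = of.classify_flow_pattern(self.path(x, z), self.intake_table(), 750.0)
        assert out == "posterior"

    def test_anterior_return(self):
        fps = 750.0
        n = 300
        t = np.arange(n) / fps
        v = np.full(n, -50.0)  # cm/s
        v[200:260] = 10.0  # sustained anterior segment deep in the cavity
        x = 60 + np.concatenate([[0], np.cumsum(0.5 * (v[1:] + v[:-1]) / fps)]) * 10
        out = of.classify_flow_pattern(self.path(x, np.full(n, 2.0)), self.intake_table(), fps)
        assert out == "anterior_return"

    def test_posteromedial(self):
        n = 300
        x = np.linspace(60, 10, n)
        z = np.linspace(8.0, 1.0, n)
        out = of.classify_flow_pattern(self.path(x, z), self.intake_table(), 750.0)
        assert out == "posteromedial"

    def test_no_intake_raises(self):
        pt = of.PhaseTable(intervals=[of.PhaseInterval("stasis", 0.0, 1.0, 0.0)])
        with pytest.raises(ValueError, match="intake"):
            of.classify_flow_pattern(np.zeros((100, 3)), pt, 750.0)

    def test_generator_subpopulations_recovered(self):
        world = of.generate_feeding_sequence(
            of.CARP, n_cycles=0, seed=2,
            anterior_return_fraction=0.2, posteromedial_fraction=0.2,
        )
        anat, _, pt = of.analyze_world(world)
        got = {
            name: of.classify_flow_pattern(anat.points[name], pt, anat.frame_rate)
            for name in anat.tracks_of_kind("water_tracer")
        }
        truth = world.flow_pattern_truth
        agree = np.mean([got[k] == truth[k] for k in got])
        assert agree >= 0.8


class TestCohortCurvature:
    def test_water_curvature_exceeds_food_in_default_cohort(self):
        """Seven carp-like trials: pooled Kruskal-Wallis, water > food."""
        allw, allf = [], []
        for seed in range(7):
            world = of.generate_feeding_sequence(of.CARP, n_cycles=1, seed=seed)
            anat, _, pt = of.analyze_world(world)
            w, f = of.intake_curvature_profiles(anat, pt)
            allw += w
            allf += f
        res = of.compare_curvature(allw, allf)
        assert res.medians[0] > res.medians[1]
        assert res.p_value <= 0.05
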