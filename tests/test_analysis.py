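"""Residential aggregation, site statistics, density maps, speeds, prospecting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paleowalk as pw
from paleowalk.analysis import SiteStats, compute_site_stats
from paleowalk.errors import InvalidInputError
from paleowalk.movement import Trajectory
from paleowalk.synthetic_world import SiteRecord


def make_traj(positions, step_lengths=None):
    positions = np.asarray(positions, dtype=float)
    if step_lengths is None:
        step_lengths = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    return Trajectory(
        positions=positions,
        states=np.zeros(len(positions) - 1, np.int8),
        step_lengths=np.asarray(step_lengths, dtype=float),
        cumulative_distance=np.cumsum(step_lengths),
    )


def oracle_aggregate(positions, step_lengths, radius):
    """Brute-force re-scan of the aggregation rule."""
    anchors = [0]
    seg_steps, seg_dist = [0], [0.0]
    ax, ay = positions[0]
    for i in range(1, len(positions)):
        seg_steps[-1] += 1
        seg_dist[-1] += step_lengths[i - 1]
        if np.hypot(positions[i][0] - ax, positions[i][1] - ay) > radius:
            anchors.append(i)
            ax, ay = positions[i]
            seg_steps.append(0)
            seg_dist.append(0.0)
    return anchors, seg_steps, seg_dist


class TestAggregateResidential:
    def test_all_within_radius_single_event(self):
        traj = make_traj([(0, 0), (1, 0), (0, 1), (1, 1)])
        path = pw.aggregate_residential(traj, radius=5.0)
        assert len(path.anchors) == 1
        assert path.segment_distances.sum() == pytest.approx(traj.total_distance)

    def test_collinear_hand_trace(self):
        traj = make_traj([(float(k), 0.0) for k in range(7)])
        path = pw.aggregate_residential(traj, radius=2.5)
        assert [a[0] for a in path.anchors] == [0.0, 3.0, 6.0]

    def test_vanishing_radius_every_step_an_event(self):
        traj = make_traj([(float(k), 0.0) for k in range(10)])
        path = pw.aggregate_residential(traj, radius=1e-9)
        assert len(path.anchors) == 10

    def test_empty_trajectory(self):
        traj = Trajectory(
            positions=np.empty((0, 2)), states=np.empty(0, np.int8),
            step_lengths=np.empty(0), cumulative_distance=np.empty(0),
        )
        assert pw.aggregate_residential(traj, 10.0).n_events == 0

    def test_anchor_spacing_invariant(self, corridor_map, corridor):
        traj = pw.simulate_walker(corridor.entry, corridor_map, pw.MovementParams(n_steps=20_000), seed=6)
        for radius in (5.0, 25.0, 50.0):
            path = pw.aggregate_residential(traj, radius)
            gaps = np.linalg.norm(np.diff(path.anchors, axis=0), axis=1)
            assert np.all(gaps > radius)
            assert path.segment_distances.sum() == pytest.approx(traj.total_distance)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), radius=st.floats(0.5, 20.0))
    def test_matches_brute_force_oracle(self, seed, radius):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 100))
        positions = np.cumsum(rng.normal(0, 2.0, (n, 2)), axis=0)
        steps = np.linalg.norm(np.diff(positions, axis=0), axis=1)
        path = pw.aggregate_residential(make_traj(positions, steps), radius)
        o_anchors, o_steps, o_dist = oracle_aggregate(positions, steps, radius)
        assert np.array_equal(path.anchors, positions[o_anchors])
        assert np.array_equal(path.segment_steps, o_steps)
        assert np.allclose(path.segment_distances, o_dist)


class TestSiteAccess:
    def site(self, x, y):
        return SiteRecord("S0", (x, y), 40.0, 45.0, 50.0)

    def test_far_site_empty(self):
        traj = make_traj([(0, 0), (1, 0), (2, 0)])
        acc = pw.site_access(traj, [self.site(100.0, 100.0)], access_radius=10.0)
        assert len(acc["S0"]["indices"]) == 0

    def test_pass_through_recorded(self):
        traj = make_traj([(0, 0), (5, 0), (10, 0)])
        acc = pw.site_access(traj, [self.site(5.0, 0.0)], access_radius=1.0)
        assert 1 in acc["S0"]["indices"]

    def test_toy_counts_match_exhaustive_check(self):
        pts = [(0, 0), (3, 0), (6, 0), (9, 0), (12, 0)]
        traj = make_traj(pts)
        site = self.site(6.0, 4.0)
        acc = pw.site_access(traj, [site], access_radius=5.0)
        expect = [i for i, (x, y) in enumerate(pts) if np.hypot(x - 6, y - 4) <= 5.0]
        assert list(acc["S0"]["indices"]) == expect
        # cumulative distance at a matched index equals the walked distance
        assert acc["S0"]["cumulative_distances"][0] == pytest.approx(3.0)


class TestCountDistinctVisits:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([100.0, 100.5, 101.0], 1),  # one tight pass
            ([100.0, 101.0, 500.0, 501.0], 2),  # two well-separated passes
            ([42.0], 1),
            ([], 0),
        ],
    )
    def test_known_groupings(self, values, expected):
        assert pw.count_distinct_visits(np.array(values)) == expected

    def test_three_clusters_recovered(self):
        vals = np.concatenate([np.linspace(0, 1, 5), np.linspace(200, 201, 5), np.linspace(900, 901, 5)])
        assert pw.count_distinct_visits(vals) == 3

    def test_visits_bounded_by_contiguous_runs(self, corridor_map, corridor):
        traj = pw.simulate_walker(corridor.entry, corridor_map, pw.MovementParams(n_steps=30_000), seed=8)
        site = SiteRecord("S0", tuple(traj.positions[15_000]), 40, 45, 50)
        acc = pw.site_access(traj, [site], access_radius=10.0)
        idx = acc["S0"]["indices"]
        runs = 1 + int(np.sum(np.diff(idx) > 1))
        visits = pw.count_distinct_visits(acc["S0"]["cumulative_distances"])
        assert 1 <= visits <= runs


class TestOccupationKde:
    def test_single_location_peak_one(self):
        g = pw.GridGeometry(32, 32, 1.0)
        traj = make_traj([(16.0, -16.0)] * 5)
        kde = pw.occupation_kde([traj], g)
        assert kde.max() == pytest.approx(1.0)
        assert np.unravel_index(kde.argmax(), kde.shape) == (16, 16)

    def test_two_equal_clusters_equal_modes(self):
        g = pw.GridGeometry(64, 64, 1.0)
        a = make_traj([(16.0, -32.0)] * 50)
        b = make_traj([(48.0, -32.0)] * 50)
        kde = pw.occupation_kde([a, b], g)
        assert kde[32, 16] == pytest.approx(kde[32, 48], rel=1e-6)

    def test_density_integrates_to_point_count(self):
        g = pw.GridGeometry(64, 64, 1.0)
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(20, 44, 500), -rng.uniform(20, 44, 500)])
        traj = make_traj(pts)
        dens = pw.occupation_kde([traj], g, bandwidth=2.0, normalise=False)
        integral = dens.sum() * g.cell_area
        assert integral == pytest.approx(len(pts), rel=1e-3)


class TestPresenceHeatmap:
    def test_count_conservation(self, corridor_map, corridor):
        trajs = pw.run_ensemble([corridor.entry], corridor_map, pw.MovementParams(n_steps=2000), 3, 0)
        heat, _ = pw.presence_heatmap(trajs, cell_size=1.0, geometry=corridor.geometry)
        assert heat.sum() == sum(len(t.positions) for t in trajs)

    def test_stationary_walker_single_cell(self):
        g = pw.GridGeometry(8, 8, 1.0)
        traj = make_traj([(3.0, -4.0)] * 7)
        heat, _ = pw.presence_heatmap([traj], 1.0, geometry=g)
        assert heat[4, 3] == 7
        assert heat.sum() == 7

    def test_toy_three_points_hand_binned(self):
        g = pw.GridGeometry(8, 8, 1.0)
        traj = make_traj([(0.2, -0.1), (0.3, -0.2), (6.9, -7.1)])
        heat, _ = pw.presence_heatmap([traj], 1.0, geometry=g)
        assert heat[0, 0] == 2
        assert heat[7, 7] == 1


class TestMigrationSpeed:
    def stats(self, distances):
        return SiteStats(
            site_id="S0", percent_visited=100.0,
            walker_counts=np.array([1]), occupation_numbers=np.array([1]),
            first_access_distances=np.array(distances, dtype=float),
        )

    def test_hand_arithmetic(self):
        site = SiteRecord("S0", (0, 0), 70.0, 70.0, 70.0)
        sp = pw.migration_speed(self.stats([150.0]), 75.0, site)
        assert sp.speed_from_mean["age_mean"] == pytest.approx(0.03)
        assert sp.speed_from_min["age_mean"] == pytest.approx(0.03)

    def test_min_speed_below_mean_speed(self):
        site = SiteRecord("S0", (0, 0), 50.0, 55.0, 60.0)
        sp = pw.migration_speed(self.stats([100.0, 300.0]), 75.0, site)
        for k in sp.speed_from_mean:
            assert sp.speed_from_min[k] <= sp.speed_from_mean[k]

    def test_halving_distances_halves_speeds(self):
        site = SiteRecord("S0", (0, 0), 50.0, 55.0, 60.0)
        a = pw.migration_speed(self.stats([100.0, 300.0]), 75.0, site)
        b = pw.migration_speed(self.stats([50.0, 150.0]), 75.0, site)
        for k in a.speed_from_mean:
            assert b.speed_from_mean[k] == pytest.approx(a.speed_from_mean[k] / 2)
            assert b.speed_from_min[k] == pytest.approx(a.speed_from_min[k] / 2)

    def test_site_older_than_entry_rejected(self):
        site = SiteRecord("S0", (0, 0), 70.0, 74.0, 76.0)
        with pytest.raises(InvalidInputError):
            pw.migration_speed(self.stats([100.0]), 75.0, site)


class TestProspectSites:
    def build_stats(self):
        # 10 candidates; exactly 3 pass (percent > 70 and mean count > 200)
        table = {
            "S0": (95.0, 400.0), "S1": (80.0, 250.0), "S2": (71.0, 201.0),
            "S3": (90.0, 150.0), "S4": (65.0, 500.0), "S5": (70.0, 300.0),
            "S6": (10.0, 10.0), "S7": (0.0, 0.0), "S8": (50.0, 220.0), "S9": (69.9, 999.0),
        }
        sites = [SiteRecord(k, (i * 1.0, 0.0), 40, 45, 50) for i, k in enumerate(table)]
        stats = {
            k: SiteStats(
                site_id=k, percent_visited=pv,
                walker_counts=np.full(4, wc), occupation_numbers=np.ones(4),
                first_access_distances=np.array([100.0 + i]),
            )
            for i, (k, (pv, wc)) in enumerate(table.items())
        }
        return sites, stats

    def test_threshold_filter_and_rank_order(self):
        sites, stats = self.build_stats()
        ranked = pw.prospect_sites(sites, stats, 70.0, 200.0, top_n=10)
        assert list(ranked.site_id) == ["S0", "S1", "S2"]

    def test_zero_thresholds_return_all_ranked(self):
        sites, stats = self.build_stats()
        ranked = pw.prospect_sites(sites, stats, 0.0, 0.0, top_n=10)
        nonzero = [k for k in stats if stats[k].percent_visited > 0 and stats[k].mean_walker_count > 0]
        assert len(ranked) == len(nonzero)
        assert ranked.percent_visited.is_monotonic_decreasing

    def test_never_visited_excluded(self):
        sites, stats = self.build_stats()
        ranked = pw.prospect_sites(sites, stats, 0.0, 0.0, top_n=10)
        assert "S7" not in set(ranked.site_id)

    def test_no_candidate_passing_returns_empty(self):
        sites, stats = self.build_stats()
        ranked = pw.prospect_sites(sites, stats, 99.9, 1e9)
        assert isinstance(ranked, pd.DataFrame) and len(ranked) == 0


def test_compute_site_stats_consistency(corridor_map, corridor):
    trajs = pw.run_ensemble([corridor.entry], corridor_map, pw.MovementParams(n_steps=5000), 4, 7)
    sites = [
        SiteRecord("near", tuple(trajs[0].positions[1000]), 40, 45, 50),
        SiteRecord("far", (1e6, 1e6), 40, 45, 50),
    ]
    stats = compute_site_stats(trajs, sites, access_radius=10.0)
    assert stats["far"].percent_visited == 0.0
    assert stats["near"].percent_visited > 0.0
    for st_ in stats.values():
        assert 0.0 <= st_.percent_visited <= 100.0
        assert np.all(st_.occupation_numbers <= st_.walker_counts)
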