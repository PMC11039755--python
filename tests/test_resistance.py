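"""Morphometrics, diversity and the combined resistance surface."""

import numpy as np
import pytest

import paleowalk as pw
from paleowalk.errors import ConfigurationError, InvalidInputError
from paleowalk.grids import SECONDS_PER_YEAR
from paleowalk.landscape import FlowField
from paleowalk.resistance import (
    DiversityConfig,
    EnvironmentalConfig,
    coastal_mask,
    river_masks,
)

from .conftest import flat_ramp


def make_flow(geometry, discharge_cms, ocean=None):
    """FlowField stub with prescribed discharge (m³/s) for index tests."""
    shape = geometry.shape
    ocean = ocean if ocean is not None else np.zeros(shape, dtype=bool)
    n = shape[0] * shape[1]
    return FlowField(
        geometry=geometry,
        discharge=np.asarray(discharge_cms, dtype=float) * SECONDS_PER_YEAR,
        upstream_area=np.ones(shape),
        flow_fractions=np.zeros((n, 8)),
        receiver=np.full(n, -1, np.int64),
        basin_id=np.zeros(shape, np.int64),
        slope=np.zeros(shape),
        sink_mask=~ocean,
        ocean_mask=ocean,
    )


class TestSlopeIndex:
    def test_flat_grid_is_zero(self):
        g = pw.GridGeometry(8, 8)
        assert np.all(pw.slope_index(pw.ElevationGrid(g, np.full((8, 8), 5.0))) == 0.0)

    def test_maximal_slope_cell_is_one(self):
        elev = flat_ramp(n=8)
        idx = pw.slope_index(elev)
        assert idx.max() == pytest.approx(1.0)

    def test_scale_invariance(self, dem64):
        a = pw.slope_index(dem64)
        b = pw.slope_index(pw.ElevationGrid(dem64.geometry, 2.0 * dem64.z))
        assert np.allclose(a, b)


class TestTopographicPosition:
    def test_flat_plane_zero(self):
        g = pw.GridGeometry(8, 8)
        tpi = pw.topographic_position(pw.ElevationGrid(g, np.full((8, 8), 3.0)), (1.0, 1.5))
        assert np.allclose(tpi, 0.0)

    def test_isolated_peak_hand_value(self):
        # centre z = 10, all others 0, annulus = the 8-neighbourhood
        g = pw.GridGeometry(8, 8, cell_size=1.0)
        z = np.zeros((8, 8))
        z[4, 4] = 10.0
        tpi = pw.topographic_position(pw.ElevationGrid(g, z), (1.0, 1.5))
        assert tpi[4, 4] == pytest.approx(10.0)
        # each 4-neighbour sees the peak among its 8 surrounding cells
        assert tpi[4, 3] == pytest.approx(-10.0 / 8.0)

    def test_inversion_antisymmetry(self, dem64):
        t = pw.topographic_position(dem64, (2.0, 6.0))
        t_inv = pw.topographic_position(pw.ElevationGrid(dem64.geometry, -dem64.z), (2.0, 6.0))
        assert np.allclose(t_inv, -t)

    def test_empty_annulus_rejected(self, dem64):
        with pytest.raises(ConfigurationError):
            pw.topographic_position(dem64, (0.1, 0.2))


class TestStandardizeTpi:
    def test_mean_zero_sd_hundred(self, dem64):
        t = pw.standardize_tpi(pw.topographic_position(dem64, (2.0, 6.0)))
        assert abs(t.mean()) < 1e-9
        assert t.std() == pytest.approx(100.0, abs=1e-6)

    def test_affine_invariance(self, dem64):
        t = pw.topographic_position(dem64, (2.0, 6.0))
        assert np.allclose(pw.standardize_tpi(t), pw.standardize_tpi(3.0 * t + 7.0))

    def test_two_value_raster_closed_form(self):
        t = np.array([[-1.0, 1.0]] * 4).reshape(4, 2).repeat(4, axis=1)
        out = pw.standardize_tpi(t)
        assert set(np.round(np.unique(out), 9)) == {-100.0, 100.0}

    def test_zero_variance_warns_and_zeros(self):
        with pytest.warns(UserWarning):
            out = pw.standardize_tpi(np.full((8, 8), 2.0))
        assert np.all(out == 0.0)


class TestCategorize:
    def test_constant_raster_single_class(self):
        c = np.full((8, 8), 1.0)
        s, f, t = pw.categorize(c, c, c)
        for arr, k in ((s, 7), (f, 5), (t, 10)):
            assert len(np.unique(arr)) == 1
            assert 1 <= arr.min() and arr.max() <= k

    def test_uniform_values_near_equal_occupancy(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=(64, 64))
        s, f, t = pw.categorize(v, v, v)
        for arr, k in ((s, 7), (f, 5), (t, 10)):
            counts = np.bincount(arr.ravel(), minlength=k + 1)[1:]
            assert counts.min() > 0.8 * v.size / k

    def test_labels_cover_declared_ranges_only(self, state64):
        s, f, t = pw.categorize(
            pw.slope_index(state64.elevation), state64.flow.discharge,
            pw.standardize_tpi(pw.topographic_position(state64.elevation, (4.0, 10.0))),
        )
        assert set(np.unique(s)) <= set(range(1, 8))
        assert set(np.unique(f)) <= set(range(1, 6))
        assert set(np.unique(t)) <= set(range(1, 11))


class TestPhysiographicDiversity:
    def test_single_type_zero(self):
        c = np.ones((8, 8), np.int64)
        assert np.all(pw.physiographic_diversity((c, c, c)) == 0.0)

    def test_three_equal_types_maximal(self):
        a = np.full((8, 8), 1, np.int64)
        b = np.full((8, 8), 2, np.int64)
        c = np.full((8, 8), 3, np.int64)
        p = pw.physiographic_diversity((a, b, c))
        assert np.allclose(p, 1.0)

    def test_half_half_proportions_closed_form(self):
        # pooled observations: layer1 splits evenly between types 1|2 across
        # the grid, layer2 all type 1, layer3 all type 2 -> p = {0.5, 0.5}
        # with every neighbourhood covering the full grid:
        # d_SW = ln 2, P_DIV = ln2/ln3
        l1 = np.ones((8, 8), np.int64)
        l1[:, 4:] = 2
        l2 = np.ones((8, 8), np.int64)
        l3 = np.full((8, 8), 2, np.int64)
        cfg = DiversityConfig(neighbourhood_radius=15.0)
        p = pw.physiographic_diversity((l1, l2, l3), cfg)
        assert np.allclose(p, np.log(2) / np.log(3))

    def test_permutation_invariant_to_relabelling(self, state64):
        cats = pw.categorize(
            pw.slope_index(state64.elevation), state64.flow.discharge, state64.elevation.z
        )
        perm = tuple(10 - c for c in cats)  # reverse every label set
        a = pw.physiographic_diversity(cats)
        b = pw.physiographic_diversity(perm)
        assert np.allclose(a, b)

    def test_bounded_in_unit_interval(self, state64):
        layers = pw.compute_morphometrics(state64)
        assert layers.p_div.min() >= 0.0 and layers.p_div.max() <= 1.0


class TestEnvironmentalIndex:
    def make_inputs(self, discharge_cms):
        g = pw.GridGeometry(8, 8, cell_size=1.0)
        flow = make_flow(g, discharge_cms)
        wet = np.full(g.shape, 2.0)
        npp = np.full(g.shape, 0.9)
        slope = np.full(g.shape, 0.2)
        return g, flow, wet, npp, slope

    def test_crossing_cost_at_threshold_and_maximum(self):
        q = np.zeros((8, 8))
        q[2, 2] = 80.0
        q[5, 5] = 500.0  # land-wide maximum
        g, flow, wet, npp, slope = self.make_inputs(q)
        env = pw.environmental_index(flow, np.zeros(g.shape, bool), flow.ocean_mask, wet, npp, slope)
        assert env[2, 2] == pytest.approx(0.7)
        assert env[5, 5] == pytest.approx(0.95)

    def test_no_rivers_bounded_by_modest_ramp(self):
        q = np.full((8, 8), 10.0)  # modest flow everywhere, wet fertile terrain
        g, flow, wet, npp, slope = self.make_inputs(q)
        env = pw.environmental_index(flow, np.zeros(g.shape, bool), flow.ocean_mask, wet, npp, slope)
        assert env.max() < 0.7

    def test_ocean_and_lakes_are_barriers(self):
        q = np.zeros((8, 8))
        g = pw.GridGeometry(8, 8)
        ocean = np.zeros(g.shape, bool)
        ocean[0] = True
        lakes = np.zeros(g.shape, bool)
        lakes[4, 4] = True
        flow = make_flow(g, q, ocean)
        env = pw.environmental_index(
            flow, lakes, ocean, np.full(g.shape, 2.0), np.full(g.shape, 0.9), np.zeros(g.shape)
        )
        assert np.all(env[0] == 1.0)
        assert env[4, 4] == 1.0

    def test_arid_flat_cells_high_cost(self):
        g = pw.GridGeometry(8, 8)
        flow = make_flow(g, np.zeros(g.shape))
        precip = np.full(g.shape, 1.0)
        npp = np.full(g.shape, 0.8)
        precip[6:, 6:] = 0.01
        npp[6:, 6:] = 0.01
        slope = np.zeros(g.shape)
        env = pw.environmental_index(flow, np.zeros(g.shape, bool), flow.ocean_mask, precip, npp, slope)
        assert np.all(env[6:, 6:] == pytest.approx(0.92))


class TestBuildResistance:
    def build(self, state, climate):
        layers = pw.compute_morphometrics(state)
        cfg = EnvironmentalConfig()
        npp = climate.npp[0]
        env = pw.environmental_index(
            state.flow, state.lake_mask, state.ocean_mask,
            climate.precipitation[0], npp, layers.slope_index, cfg,
        )
        _, major, corridor = river_masks(state.flow, cfg)
        coast = coastal_mask(state.ocean_mask)
        barrier = state.ocean_mask | state.lake_mask
        return layers, env, npp, coast, corridor, barrier, major

    def test_all_zero_layers_zero_cost(self):
        g = pw.GridGeometry(8, 8)
        zeros = np.zeros(g.shape)
        layers = pw.MorphometricLayers(
            geometry=g, slope_index=zeros, tpi_fine=zeros, tpi_coarse=zeros,
            tpi_s_fine=zeros, tpi_s_coarse=zeros,
            slope_cats=np.ones(g.shape, np.int64), flux_cats=np.ones(g.shape, np.int64),
            tpi_cats=np.ones(g.shape, np.int64), p_div=np.ones(g.shape),
        )
        rmap = pw.build_resistance(
            layers, zeros, np.ones(g.shape), np.zeros(g.shape, bool), np.zeros(g.shape, bool),
            barrier_mask=np.zeros(g.shape, bool),
        )
        assert np.all(rmap.cost == 0.0)

    def test_ocean_pixels_cost_one(self, state64, climate64):
        layers, env, npp, coast, corridor, barrier, major = self.build(state64, climate64)
        rmap = pw.build_resistance(layers, env, npp, coast, corridor, barrier, major)
        assert np.all(rmap.cost[state64.ocean_mask] == 1.0)
        assert rmap.cost.min() >= 0.0 and rmap.cost.max() <= 1.0
        assert np.all(rmap.barrier_mask[state64.ocean_mask])

    def test_coastal_override_lowers_cost(self):
        g = pw.GridGeometry(8, 8)
        high = np.full(g.shape, 0.8)
        layers = pw.MorphometricLayers(
            geometry=g, slope_index=high, tpi_fine=high, tpi_coarse=high,
            tpi_s_fine=high, tpi_s_coarse=high,
            slope_cats=np.ones(g.shape, np.int64), flux_cats=np.ones(g.shape, np.int64),
            tpi_cats=np.ones(g.shape, np.int64), p_div=np.full(g.shape, 0.2),
        )
        coast = np.zeros(g.shape, bool)
        coast[3, 3] = True
        rmap = pw.build_resistance(
            layers, np.zeros(g.shape), np.ones(g.shape), coast, np.zeros(g.shape, bool),
            barrier_mask=np.zeros(g.shape, bool),
        )
        assert rmap.cost[3, 3] == pytest.approx(0.2)
        assert rmap.cost[4, 4] == pytest.approx(0.8)

    def test_layer_monotonicity_before_overrides(self, state64, climate64):
        layers, env, npp, coast, corridor, barrier, major = self.build(state64, climate64)
        none = np.zeros(state64.elevation.geometry.shape, bool)
        base = pw.build_resistance(layers, env, npp, none, none, barrier_mask=none)
        bumped_env = np.clip(env + 0.1, 0, 1)
        bumped = pw.build_resistance(layers, bumped_env, npp, none, none, barrier_mask=none)
        assert np.all(bumped.cost >= base.cost - 1e-12)

    def test_geometry_mismatch_rejected(self, state64, climate64):
        layers, env, npp, coast, corridor, barrier, major = self.build(state64, climate64)
        with pytest.raises(InvalidInputError):
            pw.build_resistance(layers, np.zeros((8, 8)), npp, coast, corridor)


def test_resistance_stack_validity_intervals(state64, climate64):
    maps = pw.resistance_stack([state64], climate64)
    assert len(maps) == 1
    assert maps[0].valid_from == state64.time
    assert maps[0].cost.min() >= 0.0 and maps[0].cost.max() <= 1.0
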