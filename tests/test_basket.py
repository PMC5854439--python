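"""Basket geometry, placement, distance maps, and chart interpolation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from basketmap.basket import basket_with_density, build_basket, \
    chart_interp_matrix, distance_map, interpolate_to_projection, \
    interpolation_matrix, place_basket, projection_grid
from basketmap.phase_mapping import filter_traces, hilbert_phase
from basketmap.ps_detection import wrap_angle


@pytest.fixture(scope="module")
def b88():
    return build_basket(8, 8, 31.0, 4.8)


class TestGeometry:
    def test_electrodes_on_sphere(self, b88):
        r = np.linalg.norm(b88.coords_flat - b88.center, axis=1)
        assert np.abs(r - 15.5).max() < 1e-6

    def test_equator_neighbor_distance(self, b88):
        c = b88.electrode_coords
        d = np.linalg.norm(c[0, 3] - c[1, 3])
        assert d == pytest.approx(11.7, rel=0.03)

    def test_pole_neighbor_distance(self, b88):
        c = b88.electrode_coords
        d = np.linalg.norm(c[0, 0] - c[1, 0])
        assert d == pytest.approx(5.4, rel=0.05)

    def test_along_spline_spacing(self, b88):
        c = b88.electrode_coords
        d = np.linalg.norm(np.diff(c[0], axis=0), axis=1)
        # chord slightly below the 4.8 mm arc spacing
        assert (d < 4.8001).all() and (d > 4.7).all()

    def test_tiny_basket_by_hand(self):
        b = build_basket(4, 2, 20.0, 6.0)
        assert b.coords_flat.shape == (8, 3)
        beta = 3.0 / 10.0  # half the arc span over the radius
        ring_r = 10.0 * np.cos(beta)
        # adjacent splines are a quarter turn apart
        expected = ring_r * np.sqrt(2.0)
        d = np.linalg.norm(b.electrode_coords[0, 0] -
                           b.electrode_coords[1, 0])
        assert d == pytest.approx(expected, abs=1e-9)
        assert b.electrode_ids[:2] == ["A1", "A2"]

    def test_density_variants_share_span(self):
        spans = []
        for ns, ne in ((4, 6), (8, 8), (16, 16)):
            b = basket_with_density(ns, ne)
            lat = b.arc_latitudes()
            spans.append(lat[-1] - lat[0])
        assert np.ptp(spans) < 1e-9

    def test_pole_overrun_rejected(self):
        with pytest.raises(ValueError, match="pole"):
            build_basket(8, 12, 31.0, 4.8)
        with pytest.raises(ValueError, match="splines"):
            build_basket(2, 8)


class TestPlacement:
    def test_identity_placement(self, b88):
        same = place_basket(b88, (0.0, 0.0, 0.0), (0, 0, 1))
        assert np.allclose(same.coords_flat, b88.coords_flat)

    def test_translation_is_rigid(self, b88):
        moved = place_basket(b88, (10.0, 0.0, 0.0))
        shift = np.linalg.norm(moved.coords_flat - b88.coords_flat, axis=1)
        assert np.allclose(shift, 10.0)

    def test_chart_world_consistency_when_tilted(self, b88):
        placed = place_basket(b88, (5.0, -3.0, 20.0), (0.3, 0.2, -0.9))
        xe = np.repeat(placed.longitudes() * placed.radius, 8)
        ye = np.tile(placed.arc_latitudes(), 8)
        world = placed.chart_to_world(xe, ye)
        assert np.abs(world - placed.coords_flat).max() < 1e-9

    def test_penetrating_electrodes_repositioned(self, b88):
        tissue = np.column_stack([np.linspace(0, 40, 50),
                                  np.linspace(0, 40, 50), np.zeros(50)])
        with pytest.warns(UserWarning, match="penetrated"):
            placed = place_basket(b88, (20.0, 20.0, 5.0), (1, 0, 0),
                                  tissue_coords=tissue)
        assert placed.coords_flat[:, 2].min() >= 0.0


class TestDistanceMap:
    def test_electrode_on_surface_zero(self, b88):
        tissue = b88.coords_flat[:1]
        dm = distance_map(b88, tissue)
        assert dm.electrode_to_tissue[0] == 0.0

    def test_concentric_spheres_constant_distance(self, b88):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(40000, 3))
        shell = 20.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        dm = distance_map(b88, shell)
        # slack covers the discrete sampling of the shell (~0.35 mm spacing)
        assert np.abs(dm.electrode_to_tissue - 4.5).max() < 0.1

    def test_matches_brute_force(self, b88, rng):
        tissue = rng.uniform(-30, 30, size=(1000, 3))
        dm = distance_map(b88, tissue)
        brute = np.min(np.linalg.norm(
            b88.coords_flat[:, None, :] - tissue[None, :, :], axis=2),
            axis=1)
        assert np.allclose(dm.electrode_to_tissue, brute)
        # symmetric consistency of the two directions
        assert np.isclose(dm.electrode_to_tissue.min(),
                          dm.tissue_to_electrode.min())

    def test_bucket_fractions_partition(self, b88, rng):
        tissue = rng.uniform(-40, 40, size=(500, 3))
        frac = distance_map(b88, tissue).bucket_fractions()
        assert frac["near"] + frac["mid"] + frac["far"] == pytest.approx(1.0)

    def test_empty_surface_rejected(self, b88):
        with pytest.raises(ValueError, match="empty"):
            distance_map(b88, np.empty((0, 3)))


class TestInterpolation:
    def test_constant_reproduced(self, b88):
        proj = interpolate_to_projection(np.full(64, 2.5), b88, (60, 60))
        assert np.allclose(proj.values, 2.5)

    def test_exact_at_electrode_sites(self, b88, rng):
        vals = rng.normal(size=64)
        xe = np.repeat(b88.longitudes() * b88.radius, 8)
        ye = np.tile(b88.arc_latitudes(), 8)
        w = chart_interp_matrix(b88, xe, ye)
        assert np.abs(w @ vals - vals).max() < 1e-12

    def test_longitude_sawtooth_ramps_and_seam(self, b88):
        vals = np.repeat(np.arange(8.0), 8)
        proj = interpolate_to_projection(vals, b88, (240, 240))
        g = proj.values.reshape(240, 240)
        assert np.allclose(g.std(axis=1), 0.0, atol=1e-12)
        col = g[:, 0]
        # linear ramp between splines 0 and 1 (30 grid cols per spline gap)
        assert np.allclose(np.diff(col[:30]), 1.0 / 30.0)
        # periodic seam: last interval interpolates from 7 back toward 0
        assert col[-1] == pytest.approx(7.0 * (1 - 29 / 30.0) + 0.0,
                                        abs=1e-9)

    def test_grid_stays_between_outer_rings(self, b88):
        x, y = projection_grid(b88, (64, 64))
        lat = b88.arc_latitudes()
        assert y.min() >= lat[0] and y.max() <= lat[-1]

    def test_weight_rows_are_convex_combinations(self, b88):
        w = interpolation_matrix(b88, (120, 120))
        assert np.allclose(np.asarray(w.sum(axis=1)).ravel(), 1.0)
        assert w.min() >= -1e-12

    def test_interpolate_then_transform_equals_transform_then_interpolate(
            self, b88, rng):
        # the pipeline order of the method (interpolate raw EGMs, then
        # filter+Hilbert per grid point) against the memory-light
        # implementation (filter+Hilbert electrodes, interpolate analytic
        # signals): identical phase by linearity
        from scipy.signal import hilbert
        traces = rng.normal(size=(1200, 64))
        grid = (24, 24)
        w = interpolation_matrix(b88, grid)
        # route A: interpolate first
        grid_traces = (w @ traces.T).T
        a = hilbert(filter_traces(grid_traces, 1000.0), axis=0)
        # route B: transform first
        el = hilbert(filter_traces(traces, 1000.0), axis=0)
        b = (w @ el.T).T
        mid = slice(200, 1000)
        d = wrap_angle(np.angle(a[mid]) - np.angle(b[mid]))
        assert np.abs(d).max() < 1e-8
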