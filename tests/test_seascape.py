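"""Raster derivations: land/water, depths, distances, shelf width, effort."""

import numpy as np
import pytest

from orcasoc import seascape as sea
from conftest import dijkstra_oracle


def grid_from(elev, cell=100.0):
    elev = np.asarray(elev, dtype=float)
    return sea.SeascapeGrid(origin=(0.0, (elev.shape[0] - 1) * cell),
                            cell_size=cell, elevation=elev)


def straight_coast(nrows=20, ncols=30, cell=100.0, land_cols=3, slope=5.0):
    """Land on the east edge, depth increasing linearly westward."""
    elev = np.empty((nrows, ncols))
    for c in range(ncols):
        if c >= ncols - land_cols:
            elev[:, c] = 10.0
        else:
            elev[:, c] = -slope * (ncols - land_cols - c)
    return grid_from(elev, cell)


class TestAsciiIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        elev = rng.normal(-50, 30, (7, 9))
        elev[2, 3] = np.nan
        g = grid_from(elev, cell=250.0)
        path = tmp_path / "g.asc"
        g.write_ascii(path)
        g2 = sea.read_ascii_grid(path)
        assert g2.cell_size == g.cell_size
        assert g2.origin == pytest.approx(g.origin)
        assert np.allclose(g2.elevation, g.elevation, equal_nan=True)


class TestClassifyCells:
    @pytest.mark.parametrize("elev, is_land", [(5.0, True), (-30.0, False),
                                               (1.0, True), (0.99, False)])
    def test_one_meter_threshold(self, elev, is_land):
        g = grid_from([[elev]])
        assert sea.classify_cells(g)[0, 0] == is_land

    def test_nan_is_land_with_warning(self):
        g = grid_from([[np.nan, -5.0]])
        with pytest.warns(UserWarning, match="NaN"):
            mask = sea.classify_cells(g)
        assert mask[0, 0] and not mask[0, 1]

    def test_checkerboard_equals_elementwise_threshold(self):
        rng = np.random.default_rng(1)
        elev = rng.uniform(-10, 10, (12, 12))
        g = grid_from(elev)
        assert (sea.classify_cells(g) == (elev >= 1.0)).all()

    def test_all_water_grid_has_no_shoreline(self):
        g = grid_from(np.full((4, 4), -20.0))
        with pytest.raises(ValueError, match="no land"):
            sea.shoreline_mask(sea.classify_cells(g))


class TestDepthAtPoints:
    def test_sign_flip(self):
        g = grid_from([[-77.2]])
        assert sea.depth_at_points(g, np.array([[0.0, 0.0]]))[0] == pytest.approx(77.2)

    def test_out_of_bounds_point_errors(self):
        g = grid_from([[-10.0]])
        with pytest.raises(ValueError, match="outside"):
            sea.depth_at_points(g, np.array([[60.0, 0.0]]))

    def test_land_point_snaps_to_neighbor_depth(self):
        g = grid_from([[10.0, -42.0]])
        d = sea.depth_at_points(g, np.array([[0.0, 0.0]]))
        assert d[0] == pytest.approx(42.0)

    def test_far_inland_point_errors(self):
        elev = np.full((9, 9), 10.0)
        elev[0, 0] = -5.0
        g = grid_from(elev)
        x, y = g.xy_of(8, 8)
        with pytest.raises(ValueError, match="no water"):
            sea.depth_at_points(g, np.array([[float(x), float(y)]]), snap_tolerance_cells=3)


class TestDistanceToShore:
    def test_straight_coast_ten_cells(self):
        g = straight_coast()
        # shoreline = first land column (col 27); a point 10 cells west of it
        x, y = g.xy_of(10, 17)
        d = sea.distance_to_shore(g, np.array([[float(x), float(y)]]))
        assert d[0] == pytest.approx(1.0)

    def test_point_on_shoreline_cell_is_zero(self):
        g = straight_coast()
        x, y = g.xy_of(5, 27)
        d = sea.distance_to_shore(g, np.array([[float(x), float(y)]]))
        assert d[0] <= 0.05  # within half a cell

    def test_matches_bruteforce_scan_in_convex_bay(self):
        rng = np.random.default_rng(2)
        elev = np.full((25, 25), -30.0)
        # a convex bay: land frame on three sides
        elev[:3, :] = 10.0
        elev[:, :3] = 10.0
        elev[:, -3:] = 10.0
        g = grid_from(elev)
        shore = sea.shoreline_mask(sea.classify_cells(g))
        rc = np.argwhere(shore)
        sx, sy = g.xy_of(rc[:, 0], rc[:, 1])
        for _ in range(20):
            r, c = int(rng.integers(5, 22)), int(rng.integers(5, 20))
            x, y = g.xy_of(r, c)
            expected = np.min(np.hypot(sx - x, sy - y)) / 1000.0
            got = sea.distance_to_shore(g, np.array([[float(x), float(y)]]))[0]
            assert got == pytest.approx(expected)


class TestWaterDistanceToIsobath:
    def test_point_on_isobath_source_is_zero(self):
        g = straight_coast(slope=20.0)  # crosses 200 m within the grid
        depth = np.maximum(0, -g.elevation)
        water = ~sea.classify_cells(g)
        unsigned, signed = sea.isobath_distance_field(g, 200.0)
        src = (depth >= 200) & water
        # at least the shallowest deep column borders shallower water
        rows, cols = np.nonzero(src)
        c_edge = cols.max()
        assert unsigned[0, c_edge] == pytest.approx(0.0)
        assert signed[0, c_edge] >= 0.0

    def test_open_channel_twenty_cells(self):
        # straight coast, 90 m cells; isobath at a known column; a point 20
        # cells straight out from it along open water sits 1.8 km away
        g = straight_coast(nrows=10, ncols=60, cell=90.0, land_cols=3, slope=10.0)
        depth = np.maximum(0, -g.elevation)
        unsigned, signed = sea.isobath_distance_field(g, 200.0)
        src_col = max(c for c in range(60 - 3) if depth[0, c] >= 200)
        target_col = src_col - 20  # 20 cells offshore of the isobath
        assert unsigned[5, target_col] == pytest.approx(1.8)
        assert signed[5, target_col] == pytest.approx(1.8)

    def test_barrier_detour_matches_dijkstra_oracle(self):
        """A U-shaped peninsula forces the water path around it."""
        elev = np.full((30, 30), -50.0)
        elev[:, 0] = -300.0  # deep trench = isobath sources on the west edge
        # peninsula: a land finger from the north
        elev[0:20, 10:13] = 10.0
        elev[29, :] = 10.0  # some land so shoreline exists
        g = grid_from(elev, cell=100.0)
        water = ~sea.classify_cells(g)
        depth = np.maximum(0, -g.elevation)
        sources = [(r, 0) for r in range(30) if water[r, 0]]
        oracle = dijkstra_oracle(water, sources, 100.0)
        unsigned, _ = sea.isobath_distance_field(g, 200.0)
        got = unsigned[water] * 1000.0
        assert np.allclose(got, oracle[water])
        # east of the peninsula the water path exceeds the straight line
        r, c = 5, 20
        straight = np.hypot(*(np.array(g.xy_of(r, c)) - np.array(g.xy_of(r, 0))))
        assert oracle[r, c] > straight

    def test_water_distance_dominates_euclidean_to_sources(self):
        elev = np.full((20, 20), -50.0)
        elev[:, 0] = -300.0
        elev[5:15, 8:10] = 10.0
        g = grid_from(elev, cell=100.0)
        water = ~sea.classify_cells(g)
        unsigned, _ = sea.isobath_distance_field(g, 200.0)
        src = np.argwhere(water & (np.maximum(0, -g.elevation) >= 200))
        for r, c in np.argwhere(water)[::7]:
            eu = np.min(np.hypot(src[:, 0] - r, src[:, 1] - c)) * 100.0
            assert unsigned[r, c] * 1000.0 >= eu - 1e-9

    def test_disconnected_pond_flagged_infinite(self):
        elev = np.full((12, 12), -50.0)
        elev[:, 0] = -300.0  # deep trench: the only isobath sources
        elev[:, 5:8] = 10.0  # land wall isolating the eastern pond
        g = grid_from(elev, cell=100.0)
        x, y = g.xy_of(6, 10)
        with pytest.warns(UserWarning, match="disconnected"):
            unsigned, _ = sea.water_distance_to_isobath(g, np.array([[float(x), float(y)]]))
        assert np.isinf(unsigned[0])


class TestShelfWidthProfile:
    def test_straight_shelf_constant_width(self):
        # 100 m cells; land at east; 200 m isobath 40 cells offshore => 4 km
        g = straight_coast(nrows=40, ncols=60, cell=100.0, land_cols=3, slope=5.0)
        # depth = 5*(57-c); crosses 200 at c = 17
        prof = sea.shelf_width_profile(g, level_m=200.0, spacing_m=500.0)
        widths = np.array([w for _, w in prof])
        assert len(widths) > 3
        assert np.allclose(widths, widths.mean(), atol=0.15)
        assert widths.mean() == pytest.approx((57 - 17) * 0.1, abs=0.2)

    def test_no_isobath_warns_empty(self):
        g = straight_coast(slope=0.5)  # never reaches 200 m
        with pytest.warns(UserWarning, match="no isobath"):
            assert sea.shelf_width_profile(g) == []

    def test_huge_spacing_single_sample_per_contour(self):
        g = straight_coast(nrows=40, ncols=60, cell=100.0, slope=5.0)
        prof = sea.shelf_width_profile(g, spacing_m=1e6)
        assert len(prof) == 1


class TestEffortGrid:
    def test_thirty_km_track_gives_eleven_points(self):
        track = np.array([[0.0, 0.0], [30_000.0, 0.0]])
        pts = sea.resample_track(track, 3000.0)
        assert len(pts) == 11
        assert pts[0] == pytest.approx([0.0, 0.0])
        assert pts[-1] == pytest.approx([30_000.0, 0.0])

    def test_degenerate_track_contributes_single_vertex(self):
        pts = sea.resample_track(np.array([[5.0, 5.0]]), 3000.0)
        assert len(pts) == 1

    def test_points_in_one_cell(self):
        sightings = np.tile([[1000.0, 1000.0]], (10, 1))
        counts, _, _ = sea.effort_grid([], sightings, cell_km=5.0)
        assert counts.sum() == 10
        assert (counts == 10).sum() == 1

    def test_origin_shift_conserves_total(self):
        rng = np.random.default_rng(3)
        sightings = rng.uniform(0, 50_000, (40, 2))
        tracks = [rng.uniform(0, 50_000, (3, 2)) for _ in range(4)]
        c1, _, _ = sea.effort_grid(tracks, sightings, origin=(0.0, 0.0))
        c2, _, _ = sea.effort_grid(tracks, sightings, origin=(-2500.0, -2500.0))
        assert c1.sum() == c2.sum()


class TestProjection:
    def test_lonlat_round_trip(self):
        rng = np.random.default_rng(4)
        lon = rng.uniform(-126, -121, 20)
        lat = rng.uniform(34, 49, 20)
        x, y = sea.lonlat_to_xy(lon, lat, -125.0, 40.0)
        lon2, lat2 = sea.xy_to_lonlat(x, y, -125.0, 40.0)
        assert np.allclose(lon, lon2) and np.allclose(lat, lat2)

    def test_one_degree_latitude_is_111_km(self):
        _, y = sea.lonlat_to_xy(np.array([-125.0]), np.array([41.0]), -125.0, 40.0)
        assert y[0] == pytest.approx(111_195, rel=0.01)
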