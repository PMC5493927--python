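"""Hiking speeds, cost graphs, Dijkstra surfaces, contour routing, rasters.

The independent oracle for shortest-path checks builds the edge list with a
naive double loop and runs networkx Bellman-Ford; analytic oracles use
uniform terrain where the optimal route is a straight lattice line.
"""

import math

import networkx as nx
import numpy as np
import pytest

from punapipe.travelcost import (DemRaster, HikingFunction, TOBLER,
                                 build_cost_graph, hiking_speed, isochrones,
                                 read_ascii_grid, synth_dem, time_to_contour,
                                 travel_time_surface, write_ascii_grid)

SPEED_FLAT = 6.0 * math.exp(-3.5 * 0.05)  # km/h on level ground


class TestHikingSpeed:
    def test_peak_speed_on_gentle_descent(self):
        assert hiking_speed(-0.05) == pytest.approx(6.0)

    def test_level_ground(self):
        assert hiking_speed(0.0) == pytest.approx(SPEED_FLAT)
        assert SPEED_FLAT == pytest.approx(5.037, abs=0.001)

    def test_uphill_slower_than_level(self):
        assert hiking_speed(0.10) < hiking_speed(0.0)

    def test_strictly_positive_everywhere(self):
        for s in (-5, -1, 0, 1, 5):
            assert hiking_speed(s) > 0


def _oracle_times(dem, f, source, connectivity=8):
    """Naive double-loop edge construction + networkx Bellman-Ford."""
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    if connectivity == 16:
        offsets += [(-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1)]
    g = nx.DiGraph()
    nr, nc = dem.elevation.shape
    for r in range(nr):
        for c in range(nc):
            if not np.isfinite(dem.elevation[r, c]):
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nr and 0 <= c2 < nc):
                    continue
                if not np.isfinite(dem.elevation[r2, c2]):
                    continue
                dist_m = dem.cell_size * math.hypot(dr, dc)
                slope = (dem.elevation[r2, c2] - dem.elevation[r, c]) / dist_m
                speed = f.max_speed * math.exp(-f.slope_sensitivity * abs(slope + f.slope_offset))
                g.add_edge((r, c), (r2, c2), weight=(dist_m / 1000.0) / speed)
    lengths = nx.single_source_bellman_ford_path_length(g, source)
    out = np.full((nr, nc), np.inf)
    for (r, c), t in lengths.items():
        out[r, c] = t
    return out


class TestTravelTimeSurface:
    def test_source_time_is_zero(self):
        dem = synth_dem("plane", {"grade": 0.0, "n_rows": 5, "n_cols": 5})
        surf = travel_time_surface(dem, TOBLER, (2, 2))
        assert surf.times[2, 2] == 0.0
        assert np.all(surf.times >= 0)

    def test_flat_axis_route_matches_closed_form(self):
        dem = synth_dem("plane", {"grade": 0.0, "n_rows": 5, "n_cols": 25,
                                  "cell_size": 500.0})
        surf = travel_time_surface(dem, TOBLER, (2, 0))
        assert surf.times[2, 20] == pytest.approx(10.0 / SPEED_FLAT, rel=1e-12)

    def test_inclined_plane_anisotropic_closed_forms(self):
        # 10% grade falling along +x; downhill at peak speed, uphill slower
        dem = synth_dem("plane", {"grade": 0.1, "n_rows": 5, "n_cols": 25,
                                  "cell_size": 500.0})
        down = travel_time_surface(dem, TOBLER, (2, 0)).times[2, 20]
        up = travel_time_surface(dem, TOBLER, (2, 20)).times[2, 0]
        assert down == pytest.approx(10.0 / hiking_speed(-0.1), rel=1e-9)
        assert up == pytest.approx(10.0 / hiking_speed(0.1), rel=1e-9)
        assert up > down

    def test_matches_bellman_ford_oracle_on_random_grids(self, rng):
        for trial in range(5):
            elev = 3500 + rng.normal(0, 40, (9, 11)).cumsum(axis=1)
            elev[rng.random((9, 11)) < 0.08] = np.nan
            elev[0, 0] = 3500.0
            dem = DemRaster(elev, 250.0)
            surf = travel_time_surface(dem, TOBLER, (0, 0))
            oracle = _oracle_times(dem, TOBLER, (0, 0))
            got = np.where(np.isnan(surf.times), np.inf, surf.times)
            assert got == pytest.approx(oracle, rel=1e-9)

    def test_triangle_property(self, rng):
        elev = 3800 + rng.normal(0, 30, (12, 12))
        dem = DemRaster(elev, 300.0)
        surf = travel_time_surface(dem, TOBLER, (0, 0))
        graph = build_cost_graph(dem, TOBLER, 8).toarray()
        t = surf.times.ravel()
        for u in range(t.size):
            for v in np.nonzero(graph[u])[0]:
                assert t[v] <= t[u] + graph[u, v] + 1e-12

    def test_16_connectivity_never_slower(self, rng):
        elev = 3800 + rng.normal(0, 50, (15, 15))
        dem = DemRaster(elev, 400.0)
        t8 = travel_time_surface(dem, TOBLER, (7, 7), connectivity=8).times
        t16 = travel_time_surface(dem, TOBLER, (7, 7), connectivity=16).times
        assert np.all(t16 <= t8 + 1e-12)

    def test_predecessor_links_consistent(self):
        dem = synth_dem("cone", {"apex": 4000.0, "grade": 0.08,
                                 "n_rows": 21, "n_cols": 21, "cell_size": 400.0})
        surf = travel_time_surface(dem, TOBLER, (10, 10))
        graph = build_cost_graph(dem, TOBLER, 8)
        pred = surf.predecessor.ravel()
        t = surf.times.ravel()
        for v in range(t.size):
            if pred[v] >= 0:
                assert t[v] == pytest.approx(t[pred[v]] + graph[pred[v], v], rel=1e-9)

    def test_flat_terrain_times_follow_octagonal_metric(self):
        dem = synth_dem("plane", {"grade": 0.0, "n_rows": 13, "n_cols": 13,
                                  "cell_size": 500.0})
        surf = travel_time_surface(dem, TOBLER, (6, 6))
        rows, cols = np.indices(dem.elevation.shape)
        dr, dc = np.abs(rows - 6), np.abs(cols - 6)
        octagonal_km = 0.5 * (np.maximum(dr, dc) + (math.sqrt(2) - 1) * np.minimum(dr, dc))
        assert surf.times == pytest.approx(octagonal_km / SPEED_FLAT, rel=1e-9)

    def test_raising_a_cell_on_flat_terrain_never_helps(self, rng):
        # monotone regime: on level ground any raise keeps slopes >= -offset,
        # and no other cell's arrival time may decrease
        dem = synth_dem("plane", {"grade": 0.0, "n_rows": 9, "n_cols": 9,
                                  "cell_size": 500.0})
        base = travel_time_surface(dem, TOBLER, (4, 4)).times
        for _ in range(5):
            r, c = rng.integers(0, 9, 2)
            elev = dem.elevation.copy()
            elev[r, c] += rng.uniform(1.0, 25.0)
            bumped = travel_time_surface(DemRaster(elev, 500.0), TOBLER, (4, 4)).times
            diff = bumped - base
            diff[r, c] = 0.0
            assert np.all(diff >= -1e-12)

    def test_nodata_cells_unreachable(self):
        elev = np.full((3, 5), 3800.0)
        elev[:, 2] = np.nan  # wall splits the grid
        dem = DemRaster(elev, 500.0)
        surf = travel_time_surface(dem, TOBLER, (1, 0))
        assert np.all(np.isnan(surf.times[:, 2]))
        assert np.all(np.isinf(surf.times[:, 3:]))


class TestTimeToContour:
    def test_source_below_contour(self):
        dem = synth_dem("plane", {"grade": 0.0, "base": 2000.0})
        res = time_to_contour(dem, TOBLER, (3, 3), 2500.0)
        assert res.reached and res.hours == 0.0
        assert res.path == [(3, 3)] and res.one_way_km == 0.0

    def test_cone_descent_matches_continuum_oracle_within_2pct(self):
        # apex 3000 m, 5% radial grade: the 2500 m contour is a 10 km circle
        # walked at peak speed; fine cells keep the lattice detour under 2%
        dem = synth_dem("cone", {"apex": 3000.0, "grade": 0.05, "n_rows": 181,
                                 "n_cols": 181, "cell_size": 125.0})
        res = time_to_contour(dem, TOBLER, (90, 90), 2500.0)
        oracle_h = 10.0 / hiking_speed(-0.05)
        assert res.reached
        assert res.hours == pytest.approx(oracle_h, rel=0.02)

    def test_round_trip_is_twice_one_way(self):
        dem = synth_dem("plane", {"grade": 0.05, "base": 2600.0,
                                  "n_rows": 5, "n_cols": 30, "cell_size": 500.0})
        res = time_to_contour(dem, TOBLER, (2, 0), 2500.0)
        assert res.reached
        assert res.round_trip_km == pytest.approx(2 * res.one_way_km)

    def test_no_cell_below_contour(self):
        dem = synth_dem("plane", {"grade": 0.0, "base": 4000.0})
        res = time_to_contour(dem, TOBLER, (0, 0), 2500.0)
        assert not res.reached and res.hours is None


class TestIsochrones:
    def test_bands_partition_reachable_cells(self):
        dem = synth_dem("cone", {"apex": 4000.0, "grade": 0.06,
                                 "n_rows": 31, "n_cols": 31, "cell_size": 500.0})
        surf = travel_time_surface(dem, TOBLER, (15, 15))
        bands = isochrones(surf, 0.5)
        finite = np.isfinite(surf.times)
        assert np.all(bands[finite] >= 0)
        assert np.all(bands[finite] == np.floor(surf.times[finite] / 0.5))

    def test_bad_interval_rejected(self):
        dem = synth_dem("plane", {})
        surf = travel_time_surface(dem, TOBLER, (0, 0))
        with pytest.raises(ValueError):
            isochrones(surf, 0.0)


class TestAsciiGrid:
    def test_roundtrip_preserves_grid(self, tmp_path):
        dem = synth_dem("ridge", {"n_rows": 8, "n_cols": 6, "cell_size": 30.0})
        p = tmp_path / "dem.asc"
        write_ascii_grid(dem.elevation, dem, p, fmt="%.10g")
        back = read_ascii_grid(p)
        assert back.elevation == pytest.approx(dem.elevation)
        assert back.cell_size == dem.cell_size
        assert (back.xllcorner, back.yllcorner) == (dem.xllcorner, dem.yllcorner)
        assert back.crs_kind == "planar_metres"

    def test_nodata_sentinel_roundtrip(self, tmp_path):
        elev = np.full((3, 3), 3000.0)
        elev[1, 1] = np.nan
        dem = DemRaster(elev, 100.0)
        p = tmp_path / "dem.asc"
        write_ascii_grid(dem.elevation, dem, p)
        back = read_ascii_grid(p)
        assert np.isnan(back.elevation[1, 1])

    def test_header_errors_reported(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n1 2\n")
        with pytest.raises(ValueError, match="nrows"):
            read_ascii_grid(p)

    def test_geographic_autodetect_and_latitude_narrowing(self, tmp_path):
        elev = np.full((4, 4), 4000.0)
        dem = DemRaster(elev, 1 / 120.0, -70.0, -17.0, -9999.0, "geographic_degrees")
        p = tmp_path / "geo.asc"
        write_ascii_grid(dem.elevation, dem, p)
        back = read_ascii_grid(p)
        assert back.crs_kind == "geographic_degrees"
        # east-west edges are shorter than north-south by ~cos(latitude)
        from punapipe.travelcost import _offset_distances_m
        ew = _offset_distances_m(back, 0, 1)[1]
        ns = _offset_distances_m(back, 1, 0)[1]
        assert ew / ns == pytest.approx(math.cos(math.radians(16.97)), abs=0.01)
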