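"""Terrain-adjusted travel-time surfaces, contour routing, and isochrones.

An elevation raster (Arc/Info ASCII Grid) is turned into a directed graph on
cell centres (8- or 16-connectivity); each edge u->v costs
``distance(u, v) / speed(slope)`` hours, where slope is rise/run and speed
comes from an exponential hiking function — Tobler's by default::

    speed = max_speed * exp(-slope_sensitivity * |slope + slope_offset|)
          = 6 * exp(-3.5 * |s + 0.05|)  km/h

(fastest, 6 km/h, on a gentle -5% descent; walking is anisotropic, so the
graph is directed).  Single-source minimum travel times are computed with
Dijkstra's algorithm; from them the module extracts the minimum-time route to
the nearest cell below an elevation contour (2500 m by default — the
conventional high-elevation boundary) and discrete isochrone bands.

Planar rasters use Euclidean cell-centre distances; geographic (degree)
rasters use great-circle distances on the authalic sphere, with the
latitude-dependent narrowing of east-west spacing handled per row.

Grid convention: cells are addressed (row, col) with row 0 at the north
(top) edge; the header's origin is the lower-left corner, per the ASCII grid
standard.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "DemRaster",
    "HikingFunction",
    "TravelTimeSurface",
    "ContourResult",
    "TOBLER",
    "hiking_speed",
    "build_cost_graph",
    "travel_time_surface",
    "time_to_contour",
    "isochrones",
    "synth_dem",
    "read_ascii_grid",
    "write_ascii_grid",
    "path_geojson",
    "isochrones_geojson",
    "write_summary_csv",
]

_EARTH_RADIUS_M = 6_371_007.2  # authalic sphere
_NO_PRED = -9999


@dataclass
class HikingFunction:
    """Exponential slope-dependent walking-speed model (km/h)."""

    max_speed: float = 6.0
    slope_sensitivity: float = 3.5
    slope_offset: float = 0.05

    def __post_init__(self) -> None:
        if self.max_speed <= 0:
            raise ValueError(f"max_speed must be > 0, got {self.max_speed}")


#: Tobler's hiking function: 6 km/h peak at a -5% grade
TOBLER = HikingFunction()


def hiking_speed(slope: float, f: HikingFunction = TOBLER) -> float:
    """Walking speed (km/h) at a given rise/run slope; strictly positive."""
    slope = np.asarray(slope, dtype=float)
    if not np.all(np.isfinite(slope)):
        raise ValueError("slope must be finite")
    out = f.max_speed * np.exp(-f.slope_sensitivity * np.abs(slope + f.slope_offset))
    return float(out) if out.ndim == 0 else out


@dataclass
class DemRaster:
    """Elevation grid with georeferencing minimal enough for cost analysis."""

    elevation: np.ndarray  # (n_rows, n_cols), metres; NaN where nodata
    cell_size: float       # metres (planar) or decimal degrees (geographic)
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata_value: float = -9999.0
    crs_kind: str = "planar_metres"  # or geographic_degrees

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.crs_kind not in ("planar_metres", "geographic_degrees"):
            raise ValueError(f"unknown crs_kind {self.crs_kind!r}")

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.elevation)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of a cell centre; row 0 is the north edge."""
        x = self.xllcorner + (col + 0.5) * self.cell_size
        y = self.yllcorner + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) containing a coordinate; raises outside the grid."""
        col = int(math.floor((x - self.xllcorner) / self.cell_size))
        row = self.n_rows - 1 - int(math.floor((y - self.yllcorner) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"coordinate ({x}, {y}) outside raster extent")
        return row, col


def read_ascii_grid(path, crs_kind: str = "auto") -> DemRaster:
    """Read an Arc/Info ASCII Grid (ncols/nrows/xllcorner/yllcorner/cellsize/
    NODATA_value header, row-major data, row 0 = north).

    ``crs_kind="auto"`` treats the raster as geographic when the cell size is
    below 1 and the origin lies within [-180, 180] x [-90, 90].
    """
    header: dict[str, float] = {}
    data_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in ("ncols", "nrows", "xllcorner", "yllcorner",
                                          "xllcenter", "yllcenter", "cellsize",
                                          "nodata_value"):
                header[key] = float(parts[1])
            else:
                data_lines.append(parts)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing header key {req}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cs = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        xll, yll = header["xllcenter"] - cs / 2, header["yllcenter"] - cs / 2
    else:
        raise ValueError(f"{path}: missing xllcorner/yllcorner")
    nodata = header.get("nodata_value", -9999.0)
    flat = np.array([float(v) for parts in data_lines for v in parts], dtype=float)
    if flat.size != nrows * ncols:
        raise ValueError(f"{path}: expected {nrows * ncols} values, got {flat.size}")
    elev = flat.reshape(nrows, ncols)
    elev[elev == nodata] = np.nan
    if crs_kind == "auto":
        geographic = cs < 1.0 and -180 <= xll <= 180 and -90 <= yll <= 90
        crs_kind = "geographic_degrees" if geographic else "planar_metres"
    return DemRaster(elev, cs, xll, yll, nodata, crs_kind)


def write_ascii_grid(grid: np.ndarray, dem: DemRaster, path,
                     fmt: str = "%.6g") -> None:
    """Write an array in the same ASCII grid dialect/georeferencing as ``dem``."""
    arr = np.asarray(grid, dtype=float)
    if arr.shape != dem.elevation.shape:
        raise ValueError("grid shape does not match the raster")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {dem.n_cols}\n")
        fh.write(f"nrows {dem.n_rows}\n")
        fh.write(f"xllcorner {dem.xllcorner!r}\n")
        fh.write(f"yllcorner {dem.yllcorner!r}\n")
        fh.write(f"cellsize {dem.cell_size!r}\n")
        fh.write(f"NODATA_value {dem.nodata_value!r}\n")
        out = np.where(np.isfinite(arr), arr, dem.nodata_value)
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")


_OFFSETS_8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
_OFFSETS_16 = _OFFSETS_8 + [(-2, -1), (-2, 1), (-1, -2), (-1, 2),
                            (1, -2), (1, 2), (2, -1), (2, 1)]


def _offset_distances_m(dem: DemRaster, dr: int, dc: int) -> np.ndarray:
    """Distance (m) of the (dr, dc) move from each source row (length n_rows)."""
    if dem.crs_kind == "planar_metres":
        d = dem.cell_size * math.hypot(dr, dc)
        return np.full(dem.n_rows, d)
    # geographic: great-circle between cell centres, per source row
    rows = np.arange(dem.n_rows)
    lat1 = np.deg2rad(dem.yllcorner + (dem.n_rows - rows - 0.5) * dem.cell_size)
    lat2 = np.deg2rad(dem.yllcorner + (dem.n_rows - (rows + dr) - 0.5) * dem.cell_size)
    dlon = np.deg2rad(abs(dc) * dem.cell_size)
    cosang = (np.sin(lat1) * np.sin(lat2)
              + np.cos(lat1) * np.cos(lat2) * np.cos(dlon))
    return _EARTH_RADIUS_M * np.arccos(np.clip(cosang, -1.0, 1.0))


def build_cost_graph(dem: DemRaster, f: HikingFunction = TOBLER,
                     connectivity: int = 8) -> sparse.csr_matrix:
    """Directed cell-to-cell cost graph; edge weights in hours.

    Edges touching nodata cells are excluded.  The graph is anisotropic:
    u->v and v->u generally differ because the slope sign flips.
    """
    if connectivity not in (8, 16):
        raise ValueError(f"connectivity must be 8 or 16, got {connectivity}")
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_16
    nrows, ncols = dem.elevation.shape
    n = nrows * ncols
    valid = dem.valid_mask()
    idx = np.arange(n).reshape(nrows, ncols)
    rows_out, cols_out, weights = [], [], []
    for dr, dc in offsets:
        src_r = slice(max(0, -dr), min(nrows, nrows - dr))
        dst_r = slice(max(0, dr), min(nrows, nrows + dr))
        src_c = slice(max(0, -dc), min(ncols, ncols - dc))
        dst_c = slice(max(0, dc), min(ncols, ncols + dc))
        ok = valid[src_r, src_c] & valid[dst_r, dst_c]
        if not ok.any():
            continue
        dist_m = _offset_distances_m(dem, dr, dc)[src_r][:, None]
        dist_m = np.broadcast_to(dist_m, ok.shape)
        delev = dem.elevation[dst_r, dst_c] - dem.elevation[src_r, src_c]
        slope = np.where(ok, delev / dist_m, 0.0)
        speed = f.max_speed * np.exp(-f.slope_sensitivity * np.abs(slope + f.slope_offset))
        hours = (dist_m / 1000.0) / speed
        rows_out.append(idx[src_r, src_c][ok])
        cols_out.append(idx[dst_r, dst_c][ok])
        weights.append(hours[ok])
    if not rows_out:
        return sparse.csr_matrix((n, n))
    return sparse.csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(n, n))


@dataclass
class TravelTimeSurface:
    """Per-cell minimum travel time from a source, with predecessor links."""

    times: np.ndarray        # hours, (n_rows, n_cols); inf unreachable, NaN nodata
    predecessor: np.ndarray  # flat cell index of predecessor; _NO_PRED at source/unreachable
    source: tuple[int, int]
    dem: DemRaster
    hiking: HikingFunction
    connectivity: int

    def unreachable_mask(self) -> np.ndarray:
        return np.isinf(self.times)

    def path_to(self, cell: tuple[int, int]) -> list[tuple[int, int]]:
        """Cell sequence source -> cell along predecessor links."""
        ncols = self.dem.n_cols
        flat = cell[0] * ncols + cell[1]
        if not np.isfinite(self.times[cell]):
            raise ValueError(f"cell {cell} is unreachable")
        rev = [flat]
        pred = self.predecessor.ravel()
        while pred[rev[-1]] != _NO_PRED:
            rev.append(int(pred[rev[-1]]))
        return [(i // ncols, i % ncols) for i in reversed(rev)]


def travel_time_surface(dem: DemRaster, f: HikingFunction = TOBLER,
                        source_cell: tuple[int, int] = (0, 0),
                        connectivity: int = 8) -> TravelTimeSurface:
    """Single-source minimum travel times (hours) over the cost graph."""
    r, c = source_cell
    if not (0 <= r < dem.n_rows and 0 <= c < dem.n_cols):
        raise ValueError(f"source cell {source_cell} outside the raster")
    if not np.isfinite(dem.elevation[r, c]):
        raise ValueError(f"source cell {source_cell} is nodata")
    graph = build_cost_graph(dem, f, connectivity)
    src_flat = r * dem.n_cols + c
    times, pred = dijkstra(graph, directed=True, indices=src_flat,
                           return_predecessors=True)
    times = times.reshape(dem.elevation.shape)
    times[~dem.valid_mask()] = np.nan
    return TravelTimeSurface(times=times, predecessor=pred, source=(r, c),
                             dem=dem, hiking=f, connectivity=connectivity)


@dataclass
class ContourResult:
    """Minimum-time descent to the first cell below an elevation contour."""

    reached: bool
    hours: Optional[float] = None
    target_cell: Optional[tuple[int, int]] = None
    path: list[tuple[int, int]] = field(default_factory=list)
    one_way_km: Optional[float] = None

    @property
    def round_trip_km(self) -> Optional[float]:
        return None if self.one_way_km is None else 2.0 * self.one_way_km


def _path_length_km(dem: DemRaster, path: Sequence[tuple[int, int]]) -> float:
    total = 0.0
    for (r1, c1), (r2, c2) in zip(path[:-1], path[1:]):
        dr, dc = r2 - r1, c2 - c1
        total += float(_offset_distances_m(dem, dr, dc)[r1])
    return total / 1000.0


def time_to_contour(dem: DemRaster, f: HikingFunction = TOBLER,
                    source_cell: tuple[int, int] = (0, 0),
                    contour_elevation: float = 2500.0,
                    connectivity: int = 8,
                    surface: Optional[TravelTimeSurface] = None) -> ContourResult:
    """Minimum travel time to any cell strictly below the contour elevation.

    Returns the time (h), the minimum-time path (via predecessor links), and
    its one-way length in km; ``reached=False`` when no cell lies below the
    contour.  Ties on time resolve to the lowest flat cell index.
    """
    if surface is None:
        surface = travel_time_surface(dem, f, source_cell, connectivity)
    below = dem.elevation < contour_elevation  # NaN compares False
    if not below.any():
        return ContourResult(reached=False)
    times = np.where(below, surface.times, np.inf)
    flat = int(np.argmin(times))
    if not np.isfinite(times.ravel()[flat]):
        return ContourResult(reached=False)
    cell = (flat // dem.n_cols, flat % dem.n_cols)
    path = surface.path_to(cell)
    return ContourResult(reached=True, hours=float(surface.times[cell]),
                         target_cell=cell, path=path,
                         one_way_km=_path_length_km(dem, path))


def isochrones(surface: TravelTimeSurface, interval: float = 10.0) -> np.ndarray:
    """Label each reachable cell with its travel-time band floor(time/interval).

    Bands partition the reachable cells; unreachable and nodata cells get -1.
    """
    if not (np.isfinite(interval) and interval > 0):
        raise ValueError(f"interval must be finite and > 0, got {interval}")
    bands = np.full(surface.times.shape, -1, dtype=int)
    finite = np.isfinite(surface.times)
    bands[finite] = np.floor(surface.times[finite] / interval).astype(int)
    return bands


def synth_dem(kind: str, params: Optional[dict] = None, seed: int = 0) -> DemRaster:
    """Synthetic terrain with closed-form travel-time structure.

    Kinds (all planar metres, default 60x60 cells of 500 m):

    * ``plane`` — elevation falls linearly along +x at ``grade`` (rise/run)
      from ``base`` m; travel along a grid row has constant slope ``-grade``.
    * ``cone`` — apex of ``apex`` m at the grid centre descending radially at
      ``grade``; every radial direction has slope ``-grade``.
    * ``ridge`` — a north-south Gaussian ridge of height ``amp`` over ``base``.

    ``noise_sd`` metres of seeded Gaussian roughness may be added (default 0
    so analytic oracles hold exactly).
    """
    p = {"n_rows": 60, "n_cols": 60, "cell_size": 500.0, "base": 3800.0,
         "grade": 0.05, "apex": 4000.0, "amp": 400.0, "ridge_width_m": 3000.0,
         "noise_sd": 0.0}
    p.update(params or {})
    nr, nc, cs = int(p["n_rows"]), int(p["n_cols"]), float(p["cell_size"])
    cols = np.arange(nc)[None, :]
    rows = np.arange(nr)[:, None]
    if kind == "plane":
        elev = p["base"] - p["grade"] * cs * np.broadcast_to(cols, (nr, nc)).astype(float)
    elif kind == "cone":
        cr, cc = (nr - 1) / 2.0, (nc - 1) / 2.0
        r_m = cs * np.hypot(rows - cr, cols - cc)
        elev = p["apex"] - p["grade"] * r_m
    elif kind == "ridge":
        cc = (nc - 1) / 2.0
        x_m = cs * (cols - cc)
        elev = p["base"] + p["amp"] * np.exp(-0.5 * (x_m / p["ridge_width_m"]) ** 2)
        elev = np.broadcast_to(elev, (nr, nc)).astype(float)
    else:
        raise ValueError(f"unknown terrain kind {kind!r}")
    elev = np.array(elev, dtype=float)
    if p["noise_sd"] > 0:
        elev = elev + np.random.default_rng(seed).normal(0.0, p["noise_sd"], elev.shape)
    return DemRaster(elev, cs, 0.0, 0.0, -9999.0, "planar_metres")


def path_geojson(dem: DemRaster, path: Sequence[tuple[int, int]]) -> dict:
    """Minimum-time route as a GeoJSON LineString of cell centres."""
    from shapely.geometry import LineString, Point, mapping

    pts = [dem.cell_center(r, c) for r, c in path]
    geom = Point(pts[0]) if len(pts) == 1 else LineString(pts)
    return {"type": "Feature", "properties": {"n_cells": len(pts)},
            "geometry": mapping(geom)}


def isochrones_geojson(surface: TravelTimeSurface, interval: float = 10.0) -> dict:
    """Isochrone bands as a GeoJSON FeatureCollection of merged cell polygons."""
    from shapely import unary_union
    from shapely.geometry import box, mapping

    dem = surface.dem
    bands = isochrones(surface, interval)
    half = dem.cell_size / 2.0
    features = []
    for band in sorted(set(bands[bands >= 0].tolist())):
        cells = np.argwhere(bands == band)
        boxes = []
        for r, c in cells:
            x, y = dem.cell_center(int(r), int(c))
            boxes.append(box(x - half, y - half, x + half, y + half))
        features.append({
            "type": "Feature",
            "properties": {"band": int(band),
                           "t_lo_h": band * interval, "t_hi_h": (band + 1) * interval},
            "geometry": mapping(unary_union(boxes)),
        })
    return {"type": "FeatureCollection", "features": features}


def write_summary_csv(result: ContourResult, path) -> None:
    """One-row CSV: minimum time (h), one-way and round-trip path length (km)."""
    pd.DataFrame([{
        "reached": result.reached,
        "min_time_h": result.hours,
        "one_way_km": result.one_way_km,
        "round_trip_km": result.round_trip_km,
    }]).to_csv(path, index=False)
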