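"""Seascape rasters and barrier-aware habitat covariates.

The seascape is an elevation grid (meters relative to a mean-high-water
datum; negative = below water).  Cells with elevation >= 1 m are land, all
others water.  From it we derive, per encounter point:

* water depth (nearest-cell sampling, positive down),
* Euclidean distance to the nearest shoreline (land cells bordering water),
* *water* distance to the 200 m isobath — a multi-source shortest path over
  water cells only (8-connectivity, sqrt(2) diagonal steps) so that land acts
  as a barrier, signed negative inshore of the isobath,
* continental-shelf width sampled every 3 km along the isobath,
* and a fishnet grid of relative survey effort.

Grid convention (used everywhere): cell-center registered, 0-based
(row, col), row 0 at the grid's north edge, y increasing northward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "SeascapeGrid",
    "read_ascii_grid",
    "classify_cells",
    "shoreline_mask",
    "depth_at_points",
    "distance_to_shore",
    "shore_distance_field",
    "isobath_distance_field",
    "water_distance_to_isobath",
    "shelf_width_profile",
    "resample_track",
    "effort_grid",
    "lonlat_to_xy",
    "xy_to_lonlat",
]

EARTH_RADIUS_M = 6_371_000.0
LAND_THRESHOLD_M = 1.0  # elevation >= 1 m is land; ties at exactly 1 m are land


@dataclass
class SeascapeGrid:
    """Elevation raster with planar cell-center coordinates.

    ``origin`` is the (x, y) of the center of cell (0, 0) — the north-west
    corner cell; ``cell_size`` in meters; ``elevation`` in meters relative
    to the mean-high-water datum (negative = below water).
    """

    origin: tuple[float, float]
    cell_size: float
    elevation: np.ndarray  # (nrows, ncols)
    crs: str = "local-planar"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.elevation = np.asarray(self.elevation, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        x0, y0 = self.origin
        col = int(round((x - x0) / self.cell_size))
        row = int(round((y0 - y) / self.cell_size))
        nrows, ncols = self.shape
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({x}, {y}) outside grid bounds")
        return row, col

    def xy_of(self, row: int | np.ndarray, col: int | np.ndarray):
        x0, y0 = self.origin
        return x0 + np.asarray(col) * self.cell_size, y0 - np.asarray(row) * self.cell_size

    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        """Write as an ESRI ASCII grid (plain-text raster interchange)."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xll = x0 - self.cell_size / 2
        yll = y0 - (nrows - 1) * self.cell_size - self.cell_size / 2
        body = self.elevation.copy()
        body[~np.isfinite(body)] = nodata
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {float(xll)!r}\n")
            fh.write(f"yllcorner {float(yll)!r}\n")
            fh.write(f"cellsize {float(self.cell_size)!r}\n")
            fh.write(f"NODATA_value {float(nodata)!r}\n")
            for r in range(nrows):
                fh.write(" ".join(repr(float(v)) for v in body[r]) + "\n")


def read_ascii_grid(path: str | Path, crs: str = "local-planar") -> SeascapeGrid:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    elev = np.array(rows, dtype=float)
    if elev.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared dimensions")
    if "nodata_value" in header:
        elev[elev == header["nodata_value"]] = np.nan
    cell = header["cellsize"]
    x0 = header["xllcorner"] + cell / 2
    y0 = header["yllcorner"] + (int(header["nrows"]) - 1) * cell + cell / 2
    return SeascapeGrid(origin=(x0, y0), cell_size=cell, elevation=elev, crs=crs)


def classify_cells(grid: SeascapeGrid) -> np.ndarray:
    """Boolean land mask: elevation >= 1 m is land, else water.

    NaN cells are treated as land with a warning (conservative for
    barrier-aware distances).
    """
    elev = grid.elevation
    nan_mask = ~np.isfinite(elev)
    if nan_mask.any():
        warnings.warn(f"{nan_mask.sum()} NaN cells treated as land", stacklevel=2)
    return np.where(nan_mask, True, elev >= LAND_THRESHOLD_M)


def shoreline_mask(land: np.ndarray) -> np.ndarray:
    """Land cells with at least one water 4-neighbor."""
    if not land.any():
        raise ValueError("no land in grid: shoreline undefined")
    water = ~land
    has_water_neighbor = np.zeros_like(land)
    has_water_neighbor[:-1, :] |= water[1:, :]
    has_water_neighbor[1:, :] |= water[:-1, :]
    has_water_neighbor[:, :-1] |= water[:, 1:]
    has_water_neighbor[:, 1:] |= water[:, :-1]
    return land & has_water_neighbor


def _depth(grid: SeascapeGrid) -> np.ndarray:
    return np.maximum(0.0, -np.nan_to_num(grid.elevation, nan=0.0))


def _snap_to_water(
    grid: SeascapeGrid, land: np.ndarray, row: int, col: int, tolerance_cells: int
) -> tuple[int, int]:
    water_rc = np.argwhere(~land)
    if water_rc.size == 0:
        raise ValueError("grid has no water cells")
    d2 = (water_rc[:, 0] - row) ** 2 + (water_rc[:, 1] - col) ** 2
    k = int(np.argmin(d2))
    if d2[k] > tolerance_cells**2:
        raise ValueError(
            f"cell ({row}, {col}) is on land with no water within {tolerance_cells} cells"
        )
    return int(water_rc[k, 0]), int(water_rc[k, 1])


def depth_at_points(
    grid: SeascapeGrid,
    points: np.ndarray,
    snap_tolerance_cells: int = 3,
) -> np.ndarray:
    """Water depth (m, positive down) at planar (x, y) points.

    Nearest-cell sampling; points falling on a land cell are snapped to the
    nearest water cell within ``snap_tolerance_cells`` (default 3), else an
    error is raised.  Points outside the grid raise immediately.
    """
    land = classify_cells(grid)
    depth = _depth(grid)
    out = np.empty(len(points))
    for k, (x, y) in enumerate(np.atleast_2d(points)):
        row, col = grid.cell_of(x, y)
        if land[row, col]:
            row, col = _snap_to_water(grid, land, row, col, snap_tolerance_cells)
        out[k] = depth[row, col]
    return out


def distance_to_shore(grid: SeascapeGrid, points: np.ndarray) -> np.ndarray:
    """Euclidean distance (km) from each planar point to the nearest shoreline cell."""
    land = classify_cells(grid)
    shore = shoreline_mask(land)
    rc = np.argwhere(shore)
    sx, sy = grid.xy_of(rc[:, 0], rc[:, 1])
    tree = cKDTree(np.column_stack([sx, sy]))
    d, _ = tree.query(np.atleast_2d(points))
    return d / 1000.0


def shore_distance_field(grid: SeascapeGrid) -> np.ndarray:
    """Per-cell Euclidean distance (km) from cell center to the nearest shoreline cell."""
    shore = shoreline_mask(classify_cells(grid))
    d_cells = ndimage.distance_transform_edt(~shore)
    return d_cells * grid.cell_size / 1000.0


def _isobath_sources(depth: np.ndarray, water: np.ndarray, level_m: float) -> np.ndarray:
    """Water cells at/below the isobath depth adjacent (4-conn) to shallower water."""
    deep = water & (depth >= level_m)
    shallow = water & (depth < level_m)
    nb = np.zeros_like(deep)
    nb[:-1, :] |= shallow[1:, :]
    nb[1:, :] |= shallow[:-1, :]
    nb[:, :-1] |= shallow[:, 1:]
    nb[:, 1:] |= shallow[:, :-1]
    return deep & nb


_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def isobath_distance_field(
    grid: SeascapeGrid, level_m: float = 200.0
) -> tuple[np.ndarray, np.ndarray]:
    """Barrier-aware water distance (km) from every water cell to the isobath.

    Multi-source shortest path over water cells with 8-connectivity; step
    cost is ``cell_size`` for orthogonal moves and ``cell_size * sqrt(2)``
    for diagonals, the grid-metric analogue of cost-accumulation around land
    barriers.  Returns ``(unsigned_km, signed_km)`` 2-D fields: signed is
    negative inshore of the isobath (local depth < level), positive
    offshore, NaN on land, +inf in water disconnected from any isobath cell.
    """
    land = classify_cells(grid)
    water = ~land
    depth = _depth(grid)
    sources = _isobath_sources(depth, water, level_m)
    nrows, ncols = grid.shape
    idx = -np.ones((nrows, ncols), dtype=np.int64)
    wr, wc = np.nonzero(water)
    idx[wr, wc] = np.arange(len(wr))
    n_nodes = len(wr)
    if not sources.any():
        warnings.warn("no isobath cells in grid", stacklevel=2)
        field = np.full((nrows, ncols), np.nan)
        field[water] = np.inf
        return field, field.copy()

    rows_l, cols_l, data_l = [], [], []
    for dr, dc in _OFFSETS8:
        r2 = wr + dr
        c2 = wc + dc
        ok = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols)
        ok[ok] &= water[r2[ok], c2[ok]]
        step = grid.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        rows_l.append(idx[wr[ok], wc[ok]])
        cols_l.append(idx[r2[ok], c2[ok]])
        data_l.append(np.full(ok.sum(), step))
    graph = sparse.csr_matrix(
        (np.concatenate(data_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n_nodes, n_nodes),
    )
    src_idx = idx[sources]
    dist = dijkstra(graph, directed=False, indices=src_idx, min_only=True)

    unsigned = np.full((nrows, ncols), np.nan)
    unsigned[water] = dist / 1000.0
    sign = np.where(depth < level_m, -1.0, 1.0)
    signed = unsigned * sign
    return unsigned, signed


def water_distance_to_isobath(
    grid: SeascapeGrid,
    points: np.ndarray,
    level_m: float = 200.0,
    snap_tolerance_cells: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the barrier-aware isobath distance at planar points.

    Returns ``(unsigned_km, signed_km)`` per point.  Points in water bodies
    disconnected from the isobath get +inf with a warning; they should be
    excluded from summaries.
    """
    unsigned_f, signed_f = isobath_distance_field(grid, level_m)
    land = classify_cells(grid)
    unsigned = np.empty(len(points))
    signed = np.empty(len(points))
    for k, (x, y) in enumerate(np.atleast_2d(points)):
        row, col = grid.cell_of(x, y)
        if land[row, col]:
            row, col = _snap_to_water(grid, land, row, col, snap_tolerance_cells)
        unsigned[k] = unsigned_f[row, col]
        signed[k] = signed_f[row, col]
    if np.isinf(unsigned).any():
        warnings.warn(
            f"{int(np.isinf(unsigned).sum())} points in water disconnected from the isobath",
            stacklevel=2,
        )
    return unsigned, signed


def shelf_width_profile(
    grid: SeascapeGrid, level_m: float = 200.0, spacing_m: float = 3000.0
) -> list[tuple[tuple[float, float], float]]:
    """Shelf width sampled along the isobath.

    The isobath is traced as marching-squares contours of the depth field at
    ``level_m``, resampled at fixed ``spacing_m`` arc length (sample 0 at
    each contour's start; a contour shorter than the spacing yields a single
    sample); each sample's Euclidean distance to the nearest shoreline cell
    is the local shelf width.  Returns ``[((x, y), width_km), ...]``.
    """
    depth = _depth(grid)
    contours = measure.find_contours(depth, level_m)
    if not contours:
        warnings.warn("no isobath contour found in grid", stacklevel=2)
        return []
    shore = shoreline_mask(classify_cells(grid))
    rc = np.argwhere(shore)
    sx, sy = grid.xy_of(rc[:, 0], rc[:, 1])
    tree = cKDTree(np.column_stack([sx, sy]))

    out: list[tuple[tuple[float, float], float]] = []
    for contour in contours:
        x, y = grid.xy_of(contour[:, 0], contour[:, 1])
        pts = np.column_stack([x, y])
        samples = resample_track(pts, spacing_m)
        widths, _ = tree.query(samples)
        for (px, py), w in zip(samples, widths):
            out.append(((float(px), float(py)), float(w / 1000.0)))
    return out


def resample_track(vertices: np.ndarray, step_m: float) -> np.ndarray:
    """Points every ``step_m`` of arc length along an ordered polyline.

    Includes the start; the last sample is the largest multiple of
    ``step_m`` not exceeding the track length (so a 30 km track at 3 km
    yields 11 points, endpoints included).  A degenerate zero-length track
    contributes its single vertex.
    """
    v = np.atleast_2d(np.asarray(vertices, dtype=float))
    if len(v) == 1:
        return v.copy()
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total == 0:
        return v[:1].copy()
    targets = np.arange(0.0, total + 1e-9, step_m)
    xs = np.interp(targets, cum, v[:, 0])
    ys = np.interp(targets, cum, v[:, 1])
    return np.column_stack([xs, ys])


def effort_grid(
    tracks: list[np.ndarray],
    sighting_points: np.ndarray,
    cell_km: float = 5.0,
    resample_km: float = 3.0,
    origin: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative-effort fishnet: counts of track samples + sightings per cell.

    Track lines are resampled to points every ``resample_km`` of arc length
    and appended to the sighting points; counts are binned into a square
    fishnet of ``cell_km`` cells.  Returns ``(counts, x_edges, y_edges)``
    with counts indexed [ix, iy].  Total counts equal the number of points
    regardless of grid origin.
    """
    pts = [resample_track(t, resample_km * 1000.0) for t in tracks]
    sight = np.atleast_2d(np.asarray(sighting_points, dtype=float)) if len(sighting_points) else np.empty((0, 2))
    all_pts = np.vstack([p for p in pts if len(p)] + [sight]) if (pts or len(sight)) else np.empty((0, 2))
    if len(all_pts) == 0:
        raise ValueError("no effort points")
    cell = cell_km * 1000.0
    if origin is None:
        origin = (
            np.floor(all_pts[:, 0].min() / cell) * cell,
            np.floor(all_pts[:, 1].min() / cell) * cell,
        )
    nx_bins = int(np.ceil((all_pts[:, 0].max() - origin[0]) / cell)) + 1
    ny_bins = int(np.ceil((all_pts[:, 1].max() - origin[1]) / cell)) + 1
    x_edges = origin[0] + np.arange(nx_bins + 1) * cell
    y_edges = origin[1] + np.arange(ny_bins + 1) * cell
    counts, _, _ = np.histogram2d(all_pts[:, 0], all_pts[:, 1], bins=[x_edges, y_edges])
    return counts, x_edges, y_edges


def covariate_table(
    records,
    grid: SeascapeGrid,
    lon0: float,
    lat0: float,
    retained_ids: set[str] | None = None,
    level_m: float = 200.0,
    snap_tolerance_cells: int = 3,
):
    """Per-identification habitat covariates for a set of daily encounters.

    One row per (encounter, individual): water depth, distance to shore,
    unsigned and signed water distance to the ``level_m`` isobath, and the
    encounter position.  Encounter lon/lat are projected with the local
    equirectangular transform about (lon0, lat0).  If ``retained_ids`` is
    given, only those individuals produce rows.
    """
    import pandas as pd  # local import keeps module import light

    lon = np.array([r.lon for r in records])
    lat = np.array([r.lat for r in records])
    x, y = lonlat_to_xy(lon, lat, lon0, lat0)
    pts = np.column_stack([x, y])
    depth = depth_at_points(grid, pts, snap_tolerance_cells)
    shore = distance_to_shore(grid, pts)
    unsigned, signed = water_distance_to_isobath(grid, pts, level_m, snap_tolerance_cells)
    rows = []
    for k, rec in enumerate(records):
        for ind in sorted(rec.individuals):
            if retained_ids is not None and ind not in retained_ids:
                continue
            rows.append(
                {
                    "encounter_id": rec.encounter_id,
                    "individual": ind,
                    "depth_m": depth[k],
                    "dist_shore_km": shore[k],
                    "dist_shelf_km": unsigned[k],
                    "signed_shelf_km": signed[k],
                    "lat": rec.lat,
                    "lon": rec.lon,
                }
            )
    return pd.DataFrame(rows)


def lonlat_to_xy(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection (meters) about (lon0, lat0).

    Adequate over regional extents; the synthetic seascape is natively
    planar so this only matters when ingesting decimal-degree encounter
    tables.
    """
    lam = np.radians(np.asarray(lon) - lon0)
    phi = np.radians(np.asarray(lat) - lat0)
    x = EARTH_RADIUS_M * np.cos(np.radians(lat0)) * lam
    y = EARTH_RADIUS_M * phi
    return x, y


def xy_to_lonlat(
    x: np.ndarray, y: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`lonlat_to_xy`."""
    lon = lon0 + np.degrees(np.asarray(x) / (EARTH_RADIUS_M * np.cos(np.radians(lat0))))
    lat = lat0 + np.degrees(np.asarray(y) / EARTH_RADIUS_M)
    return lon, lat
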