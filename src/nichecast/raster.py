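"""Gridded raster containers, vector regions and their text I/O.

All layers live on a shared geographic (WGS84) grid of square degree cells.
The grid origin is the outer (north-west) corner of cell ``(0, 0)``; row
indices increase southward, column indices eastward, and a cell's value
refers to its center.  Rasters are read and written as single-band ESRI
ASCII grids (``.asc``), a plain-text georeferenced format; polygons as
GeoJSON.  Cell areas use the authalic sphere (R = 6371.0088 km) via the
exact spherical-quadrangle formula, accurate to <0.3 % of an ellipsoidal
computation at the scales handled here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geojson_shape, mapping as _geojson_mapping
from shapely.geometry import MultiPolygon, Polygon

EARTH_RADIUS_KM = 6371.0088  # authalic sphere


@dataclass(frozen=True)
class Grid:
    """Geographic raster grid (EPSG:4326, degree cells).

    ``origin_lon``/``origin_lat`` locate the north-west outer corner.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_lon + (col + 0.5) * self.cell_size,
            self.origin_lat - (row + 0.5) * self.cell_size,
        )

    def cell_index(self, lon: float | np.ndarray, lat: float | np.ndarray):
        """Row/col of the cell containing each lon/lat point."""
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size).astype(int)
        return row, col


@dataclass
class RasterLayer:
    """One named variable on a :class:`Grid` with a nodata mask."""

    grid: Grid
    values: np.ndarray
    nodata_mask: np.ndarray
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.nodata_mask.shape != self.grid.shape:
            raise ValueError("values/mask shape must match grid")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError(f"layer {self.name!r} has non-finite values outside nodata")

    @property
    def data_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def copy(self, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, self.values.copy(), self.nodata_mask.copy(),
                           name if name is not None else self.name)


class RasterStack:
    """Ordered, name-addressable set of layers on one grid.

    All layers share the grid and (after :func:`align_stack`) a common
    nodata footprint.
    """

    def __init__(self, layers: Sequence[RasterLayer]):
        layers = list(layers)
        if not layers:
            raise ValueError("a stack needs at least one layer")
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        grid = layers[0].grid
        for l in layers[1:]:
            if l.grid != grid:
                raise ValueError("all layers of a stack must share one grid")
        self.layers = layers

    @property
    def grid(self) -> Grid:
        return self.layers[0].grid

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def combined_mask(self) -> np.ndarray:
        m = np.zeros(self.grid.shape, dtype=bool)
        for l in self.layers:
            m |= l.nodata_mask
        return m

    def env_table(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Variable values at the given cells, one column per layer."""
        return pd.DataFrame({l.name: l.values[rows, cols] for l in self.layers})

    def data_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col arrays of cells valid in every layer."""
        ok = ~self.combined_mask
        return np.nonzero(ok)

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])


@dataclass
class RegionPolygons:
    """Closed lon/lat polygons with an optional attribute table."""

    polygons: list[Polygon]
    attributes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for p in self.polygons:
            minx, miny, maxx, maxy = p.bounds
            if minx < -180 or maxx > 180 or miny < -90 or maxy > 90:
                raise ValueError("polygon coordinates outside [-180,180]x[-90,90]")

    def union(self):
        return shapely.union_all(self.polygons) if self.polygons else MultiPolygon([])

    def contains_points(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Boolean membership of each point in any polygon (boundary counts)."""
        if not self.polygons:
            return np.zeros(np.shape(lon), dtype=bool)
        geom = self.union()
        return shapely.intersects(geom, shapely.points(np.asarray(lon), np.asarray(lat)))


@dataclass
class CellAreaLayer:
    """Per-cell spherical surface area in km² on a grid."""

    grid: Grid
    area_km2: np.ndarray

    def __post_init__(self) -> None:
        self.area_km2 = np.asarray(self.area_km2, dtype=float)
        if self.area_km2.shape != self.grid.shape:
            raise ValueError("area shape must match grid")
        if np.any(self.area_km2 <= 0):
            raise ValueError("cell areas must be positive")


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)

_NODATA = -9999.0


def write_raster(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (plain text, EPSG:4326)."""
    g = layer.grid
    path = Path(path)
    vals = np.where(layer.nodata_mask, _NODATA, layer.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_lon!r}\n")
        fh.write(f"yllcorner {g.origin_lat - g.n_rows * g.cell_size!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA:g}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def read_raster(path: str | Path, name: str | None = None) -> RasterLayer:
    """Read a single-band ESRI ASCII grid raster.

    A sidecar ``.prj`` file, if present, must describe a geographic CRS;
    a projected CRS raises with the offending definition named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    prj = path.with_suffix(".prj")
    if prj.exists():
        wkt = prj.read_text()
        if "PROJCS" in wkt.upper():
            raise ValueError(f"raster {path} is in a projected CRS: {wkt.strip()[:80]}...")
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)
    try:
        n_cols = int(header["ncols"])
        n_rows = int(header["nrows"])
        cell = header["cellsize"]
        xll = header["xllcorner"]
        yll = header["yllcorner"]
    except KeyError as e:  # pragma: no cover - malformed input
        raise ValueError(f"missing ASCII-grid header field in {path}: {e}")
    nodata = header.get("nodata_value", _NODATA)
    if vals.shape != (n_rows, n_cols):
        raise ValueError(f"raster {path}: data shape {vals.shape} != header {(n_rows, n_cols)}")
    grid = Grid(xll, yll + n_rows * cell, cell, n_rows, n_cols)
    mask = vals == nodata
    vals = np.where(mask, 0.0, vals)
    return RasterLayer(grid, vals, mask, name or path.stem)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# polygon and occurrence I/O


def read_polygons(path: str | Path) -> RegionPolygons:
    """Read (Multi)Polygon features from a GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        features = doc["features"]
    elif doc.get("type") == "Feature":
        features = [doc]
    else:  # bare geometry
        features = [{"type": "Feature", "geometry": doc, "properties": {}}]
    polys: list[Polygon] = []
    rows = []
    for feat in features:
        geom = _geojson_shape(feat["geometry"])
        props = feat.get("properties") or {}
        if isinstance(geom, Polygon):
            polys.append(geom)
            rows.append(props)
        elif isinstance(geom, MultiPolygon):
            for g in geom.geoms:
                polys.append(g)
                rows.append(props)
        else:
            raise ValueError(f"unsupported geometry type {geom.geom_type} in {path}")
    attrs = pd.DataFrame(rows) if any(rows) else None
    return RegionPolygons(polys, attrs)


def write_polygons(region: RegionPolygons, path: str | Path) -> None:
    features = []
    for i, poly in enumerate(region.polygons):
        props = {}
        if region.attributes is not None and i < len(region.attributes):
            props = {k: _jsonable(v) for k, v in region.attributes.iloc[i].items()}
        features.append({"type": "Feature", "geometry": _geojson_mapping(poly),
                         "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def read_occurrences_csv(path: str | Path) -> pd.DataFrame:
    """Read an occurrence table; requires lon/lat columns, keeps year/basis."""
    df = pd.read_csv(path)
    missing = {"lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV {path} missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# operations


def align_stack(layers: Iterable[RasterLayer]) -> RasterStack:
    """Assemble layers into a stack with a unified nodata footprint.

    Layers must already share a grid; the combined mask (union of the
    per-layer masks) is imposed on every layer so all later per-cell
    operations see a single footprint.
    """
    layers = [l.copy() for l in layers]
    if not layers:
        raise ValueError("no layers to align")
    grid = layers[0].grid
    for l in layers[1:]:
        if (l.grid.cell_size != grid.cell_size):
            raise ValueError(
                f"incompatible cell sizes {l.grid.cell_size} vs {grid.cell_size}: "
                "resample explicitly before aligning")
        if l.grid != grid:
            raise ValueError("layers cover different grids; crop/resample first")
    union = np.zeros(grid.shape, dtype=bool)
    for l in layers:
        union |= l.nodata_mask
    for l in layers:
        l.nodata_mask = union.copy()
        l.values = np.where(union, 0.0, l.values)
    return RasterStack(layers)


def mask_to_region(stack: RasterStack, region: RegionPolygons) -> RasterStack:
    """Restrict a stack to cells whose centers fall inside the region.

    Cell membership is decided by the cell center (boundary inclusive);
    cells outside every polygon become nodata.  Raises if no data cell
    remains (empty calibration region).
    """
    grid = stack.grid
    lon = grid.lon_centers()
    lat = grid.lat_centers()
    lon2, lat2 = np.meshgrid(lon, lat)
    inside = region.contains_points(lon2.ravel(), lat2.ravel()).reshape(grid.shape)
    new_layers = []
    for l in stack.layers:
        mask = l.nodata_mask | ~inside
        new_layers.append(RasterLayer(l.grid, np.where(mask, 0.0, l.values), mask, l.name))
    out = RasterStack(new_layers)
    if not np.any(~out.combined_mask):
        raise ValueError("region covers no data cell centers (empty calibration area)")
    return out


def cell_areas(grid: Grid) -> CellAreaLayer:
    """Spherical area of every cell: A = R² Δλ (sin φ_top − sin φ_bot)."""
    dlam = math.radians(grid.cell_size)
    lat_top = np.radians(grid.origin_lat - np.arange(grid.n_rows) * grid.cell_size)
    lat_bot = np.radians(grid.origin_lat - (np.arange(grid.n_rows) + 1) * grid.cell_size)
    band = EARTH_RADIUS_KM ** 2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))
    area = np.repeat(band[:, None], grid.n_cols, axis=1)
    return CellAreaLayer(grid, area)
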