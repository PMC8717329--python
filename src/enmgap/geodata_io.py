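"""Raster/vector/occurrence I/O and grid geometry.

Rasters are square-celled geographic (lon/lat, WGS84) grids registered by
their upper-left corner, row 0 northernmost, cell-center coordinate
convention.  On disk they are ESRI ASCII grids (plain text, lossless for
float64 when written with 17 significant digits).  Polygon layers are
GeoJSON; occurrence tables are CSV with the header
``species,lon,lat,elevation,source``.

Internally, missing cells are NaN; the nodata sentinel only exists on disk.
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
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "RasterGrid",
    "ClimateStack",
    "PolygonLayer",
    "AlignmentError",
    "FormatError",
    "GeometryError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_raster_stack",
    "write_raster_stack",
    "cell_area_km2",
    "rasterize",
    "read_occurrences",
    "write_occurrences",
    "read_polygon_layer",
    "write_polygon_layer",
    "OCCURRENCE_COLUMNS",
]

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "elevation", "source"]

#: km spanned by one degree on a sphere of radius 6371 km (equatorial
#: convention used throughout for cell areas and buffer distances).
KM_PER_DEGREE = 111.320
EARTH_RADIUS_KM = 6371.0


class AlignmentError(ValueError):
    """Raster layers do not share a common grid."""


class FormatError(ValueError):
    """Unreadable or malformed raster/vector file."""


class GeometryError(ValueError):
    """Invalid, unrepairable geometry."""


@dataclass(frozen=True)
class RasterGrid:
    """Georeferencing of a lon/lat raster (upper-left registered).

    ``x_origin``/``y_origin`` are the coordinates of the upper-left corner
    of the upper-left cell; ``resolution`` is the square cell size in
    degrees.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    resolution: float
    nodata: float = -9999.0
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row's cell centers (row 0 = northernmost)."""
        return self.y_origin - (np.arange(self.n_rows) + 0.5) * self.resolution

    def lon_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.resolution

    def cell_index(self, lon, lat):
        """(row, col) of the cell containing each point; -1 marks off-grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_origin) / self.resolution).astype(int)
        row = np.floor((self.y_origin - lat) / self.resolution).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def cell_center(self, row, col):
        """(lon, lat) of cell centers."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x_origin + (col + 0.5) * self.resolution
        lat = self.y_origin - (row + 0.5) * self.resolution
        return lon, lat


@dataclass
class ClimateStack:
    """Ordered, grid-aligned named layers (bio1..bio19 semantics)."""

    grid: RasterGrid
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    period_label: str = "current"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, arr in self.layers.items():
            if name in seen:
                raise ValueError(f"duplicate layer name {name!r}")
            seen.add(name)
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise AlignmentError(
                    f"layer {name!r} shape {arr.shape} does not match grid {self.grid.shape}"
                )
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def valid_mask(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Cells finite in every (selected) layer."""
        names = self.names if names is None else list(names)
        mask = np.ones(self.grid.shape, dtype=bool)
        for name in names:
            mask &= np.isfinite(self.layers[name])
        return mask

    def env_table(self, mask: np.ndarray, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Layer values at masked cells, one row per cell (row-major order)."""
        names = self.names if names is None else list(names)
        return pd.DataFrame({n: self.layers[n][mask] for n in names})

    def subset(self, names: Sequence[str]) -> "ClimateStack":
        return ClimateStack(
            grid=self.grid,
            layers={n: self.layers[n] for n in names},
            period_label=self.period_label,
        )


@dataclass
class PolygonLayer:
    """Classified polygon features (degrees, WGS84)."""

    features: list[tuple[BaseGeometry, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        repaired = []
        for geom, label in self.features:
            if not label:
                raise ValueError("class_label must be non-empty")
            if not geom.is_valid:
                geom = shapely.make_valid(geom)
                if not geom.is_valid or geom.is_empty:
                    raise GeometryError("unrepairable geometry in polygon layer")
            repaired.append((geom, label))
        self.features = repaired

    def geometries(self, class_label: str | None = None) -> list[BaseGeometry]:
        return [g for g, lab in self.features if class_label is None or lab == class_label]

    @property
    def class_labels(self) -> list[str]:
        return sorted({lab for _, lab in self.features})


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path) -> tuple[RasterGrid, np.ndarray]:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        n_header = 0
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or parts[0].lower() not in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                break
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
            pos = fh.tell()
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise FormatError(f"{path}: not an ESRI ASCII grid (missing header keys)")
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(path, skiprows=n_header, dtype=float, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise FormatError(f"{path}: data shape {data.shape} != header ({n_rows}, {n_cols})")
    res = header["cellsize"]
    grid = RasterGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * res,
        resolution=res,
        nodata=nodata,
    )
    data = np.where(data == nodata, np.nan, data)
    return grid, data


def write_ascii_grid(path: str | Path, grid: RasterGrid, data: np.ndarray) -> None:
    data = np.asarray(data, dtype=float)
    if data.shape != grid.shape:
        raise AlignmentError(f"data shape {data.shape} does not match grid {grid.shape}")
    out = np.where(np.isfinite(data), data, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin - grid.n_rows * grid.resolution!r}\n")
        fh.write(f"cellsize {grid.resolution!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, out, fmt="%.17g")


def read_raster_stack(
    paths: Sequence[str | Path],
    names: Sequence[str],
    period_label: str = "current",
) -> ClimateStack:
    """Read aligned single-band rasters into one stack.

    Raises :class:`AlignmentError` naming the first layer whose
    georeferencing differs from the first layer's.
    """
    if len(paths) != len(names):
        raise ValueError("paths and names must have equal length")
    if not paths:
        raise ValueError("at least one raster required")
    layers: dict[str, np.ndarray] = {}
    ref_grid: RasterGrid | None = None
    for path, name in zip(paths, names):
        grid, data = read_ascii_grid(path)
        if ref_grid is None:
            ref_grid = grid
        else:
            if (
                grid.shape != ref_grid.shape
                or not math.isclose(grid.resolution, ref_grid.resolution, rel_tol=1e-12)
                or not math.isclose(grid.x_origin, ref_grid.x_origin, abs_tol=1e-9)
                or not math.isclose(grid.y_origin, ref_grid.y_origin, abs_tol=1e-9)
            ):
                raise AlignmentError(f"layer {name!r} ({path}) is not aligned with {names[0]!r}")
        layers[name] = data
    assert ref_grid is not None
    # harmonize nodata: internal representation is NaN; keep first sentinel
    return ClimateStack(grid=ref_grid, layers=layers, period_label=period_label)


def write_raster_stack(directory: str | Path, stack: ClimateStack) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, data in stack.layers.items():
        path = directory / f"{name}.asc"
        write_ascii_grid(path, stack.grid, data)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def cell_area_km2(grid: RasterGrid) -> np.ndarray:
    """Per-cell area in km² (spherical cosine approximation).

    area(row) = (111.320·res) · (111.320·res·cos(lat_center(row))),
    constant across columns.
    """
    if not grid.crs.upper().endswith("4326"):
        raise ValueError("cell areas require a geographic (WGS84) grid")
    lat = grid.lat_centers()
    width = KM_PER_DEGREE * grid.resolution * np.cos(np.radians(lat))
    height = KM_PER_DEGREE * grid.resolution
    return np.repeat((height * width)[:, None], grid.n_cols, axis=1)


def rasterize(polygons: PolygonLayer, grid: RasterGrid, class_label: str | None = None) -> np.ndarray:
    """Binary mask: 1 iff the cell center lies inside any polygon."""
    geoms = polygons.geometries(class_label)
    out = np.zeros(grid.shape, dtype=np.uint8)
    if not geoms:
        return out
    union = shapely.union_all(geoms)
    if union.is_empty:
        return out
    lon = grid.lon_centers()
    lat = grid.lat_centers()
    lon2, lat2 = np.meshgrid(lon, lat)
    shapely.prepare(union)
    inside = shapely.contains_xy(union, lon2.ravel(), lat2.ravel())
    return inside.reshape(grid.shape).astype(np.uint8)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

def _validate_occurrences(df: pd.DataFrame) -> pd.DataFrame:
    for col in OCCURRENCE_COLUMNS:
        if col not in df.columns:
            if col in ("elevation", "source"):
                df[col] = np.nan if col == "elevation" else ""
            else:
                raise FormatError(f"occurrence table missing column {col!r}")
    df = df[OCCURRENCE_COLUMNS].copy()
    df["lon"] = pd.to_numeric(df["lon"])
    df["lat"] = pd.to_numeric(df["lat"])
    df["elevation"] = pd.to_numeric(df["elevation"], errors="coerce")
    if ((df["lon"] < -180) | (df["lon"] > 180)).any():
        raise ValueError("longitude outside [-180, 180]")
    if ((df["lat"] < -90) | (df["lat"] > 90)).any():
        raise ValueError("latitude outside [-90, 90]")
    return df.reset_index(drop=True)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    return _validate_occurrences(pd.read_csv(path))


def write_occurrences(path: str | Path, df: pd.DataFrame) -> None:
    _validate_occurrences(df.copy()).to_csv(path, index=False)


def make_occurrences(records: Iterable[tuple]) -> pd.DataFrame:
    """Build a validated occurrence table from (species, lon, lat[, elev[, source]]) tuples."""
    rows = []
    for rec in records:
        species, lon, lat = rec[0], rec[1], rec[2]
        elev = rec[3] if len(rec) > 3 else np.nan
        source = rec[4] if len(rec) > 4 else ""
        rows.append({"species": species, "lon": lon, "lat": lat, "elevation": elev, "source": source})
    return _validate_occurrences(pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS))


# ---------------------------------------------------------------------------
# Polygon layers (GeoJSON)
# ---------------------------------------------------------------------------

def read_polygon_layer(path: str | Path) -> PolygonLayer:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    features = []
    for feat in gj.get("features", []):
        geom = shapely_shape(feat["geometry"])
        label = str(feat.get("properties", {}).get("class_label", "") or "unclassified")
        features.append((geom, label))
    return PolygonLayer(features=features)


def write_polygon_layer(path: str | Path, layer: PolygonLayer) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": shapely_mapping(geom),
                "properties": {"class_label": label},
            }
            for geom, label in layer.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)
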