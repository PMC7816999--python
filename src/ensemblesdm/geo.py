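"""Grids, rasters and region layers on a geographic (WGS84 lon/lat) grid.

All rasters in the pipeline live on a single north-up rectangular grid of
square cells in degrees.  Cell values are associated with cell centers;
row 0 is the northernmost row.  Rasters are stored as GeoTIFF (one band
per file, NaN as nodata, standard GeoTIFF georeferencing tags); vector
regions are stored as GeoJSON with a ``label`` property.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely import intersects_xy, make_valid

EARTH_RADIUS_KM = 6371.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


class GridMismatchError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """A north-up lon/lat grid of square cells.

    ``origin_lon``/``origin_lat`` are the coordinates of the *outer corner*
    of the top-left cell (west edge, north edge), following raster
    convention.  ``cell_size`` is in degrees.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        lats = self.lat_centers
        if lats.min() < -90.0 - 1e-9 or lats.max() > 90.0 + 1e-9:
            raise ValueError("latitude centers must lie in [-90, 90]")

    @property
    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    @property
    def lat_edges(self) -> np.ndarray:
        """North-to-south latitude edges, length n_rows + 1."""
        return self.origin_lat - np.arange(self.n_rows + 1) * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of the outer grid box."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell-center coordinates, each shaped like the grid."""
        lon, lat = np.meshgrid(self.lon_centers, self.lat_centers)
        return lon, lat

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def cell_areas_km2(self) -> np.ndarray:
        """Per-cell spherical areas (km^2), shaped like the grid.

        Constant along rows, so computed per latitude band and broadcast.
        """
        edges = self.lat_edges
        band = cell_area_km2(edges[1:], edges[:-1], self.cell_size)
        return np.broadcast_to(band[:, None], self.shape).copy()


def cell_area_km2(lat_south, lat_north, cell_width: float):
    """Area of lon/lat cell(s) on the authalic sphere (R = 6371 km).

    A = R^2 * dlambda * (sin(lat_N) - sin(lat_S)); vectorised over latitudes.
    """
    lat_south = np.asarray(lat_south, dtype=float)
    lat_north = np.asarray(lat_north, dtype=float)
    if np.any(lat_south >= lat_north + 1e-15) and cell_width > 0:
        raise ValueError("lat_south must be strictly below lat_north")
    if np.any(lat_south < -90.0 - 1e-9) or np.any(lat_north > 90.0 + 1e-9):
        raise ValueError("latitudes must lie in [-90, 90]")
    if cell_width < 0:
        raise ValueError("cell_width must be non-negative")
    dlam = math.radians(cell_width)
    area = (
        EARTH_RADIUS_KM**2
        * dlam
        * (np.sin(np.radians(lat_north)) - np.sin(np.radians(lat_south)))
    )
    return float(area) if area.ndim == 0 else area


@dataclass
class RasterLayer:
    """One named raster band with a validity mask (True = valid)."""

    grid: GridSpec
    name: str
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match grid {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError(f"layer {self.name!r} has non-finite valid values")

    def masked(self) -> np.ndarray:
        """Values with invalid cells as NaN."""
        out = self.values.astype(float).copy()
        out[~self.mask] = np.nan
        return out


class RasterStack:
    """Ordered collection of co-registered, uniquely named layers."""

    def __init__(self, layers: Sequence[RasterLayer]):
        layers = list(layers)
        if not layers:
            raise ValueError("stack needs at least one layer")
        grid = layers[0].grid
        names = [lyr.name for lyr in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for lyr in layers:
            if not lyr.grid.approx_equal(grid):
                raise GridMismatchError(f"layer {lyr.name!r} is on a different grid")
        self.grid = grid
        self.layers = layers

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.grid.shape, dtype=bool)
        for lyr in self.layers:
            mask &= lyr.mask
        return mask

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def subset(self, names: Iterable[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])

    def table(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_layers) matrix of values at valid (optionally masked) cells."""
        m = self.valid_mask if mask is None else (self.valid_mask & mask)
        return np.column_stack([lyr.values[m] for lyr in self.layers])

    def extract(self, lon, lat) -> np.ndarray:
        """Layer values at the cells containing the given points."""
        rows, cols = point_to_cell(self.grid, lon, lat)
        return np.column_stack([lyr.values[rows, cols] for lyr in self.layers])


def point_to_cell(grid: GridSpec, lon, lat) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the cells containing points; raises if off-grid."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    cols = np.floor((lon - grid.origin_lon) / grid.cell_size).astype(int)
    rows = np.floor((grid.origin_lat - lat) / grid.cell_size).astype(int)
    bad = (rows < 0) | (rows >= grid.n_rows) | (cols < 0) | (cols >= grid.n_cols)
    if np.any(bad):
        raise ValueError(f"{int(bad.sum())} point(s) fall outside the grid")
    return rows, cols


# ---------------------------------------------------------------------------
# Region layers
# ---------------------------------------------------------------------------


@dataclass
class RegionLayer:
    """Labelled polygons with a role: country, protected_area or domain."""

    labels: list[str]
    geometries: list[BaseGeometry]
    role: str = "country"

    def __post_init__(self) -> None:
        if self.role not in {"country", "protected_area", "domain"}:
            raise ValueError(f"unknown region role {self.role!r}")
        if len(self.labels) != len(self.geometries):
            raise ValueError("labels and geometries differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique within a role")
        self.geometries = [
            g if g.is_valid else make_valid(g) for g in self.geometries
        ]

    def __len__(self) -> int:
        return len(self.labels)

    def union(self) -> BaseGeometry:
        from shapely.ops import unary_union

        return unary_union(self.geometries)


def rasterize_regions(regions: RegionLayer, grid: GridSpec) -> np.ndarray:
    """Label raster: cell -> 1-based index of the polygon covering its center.

    0 means no polygon.  A center on a shared border goes to the first
    polygon in layer order, so the result is always a partition.
    """
    if len(regions) == 0:
        raise ValueError("region layer is empty")
    lon, lat = grid.center_mesh()
    out = np.zeros(grid.shape, dtype=np.int32)
    unassigned = np.ones(grid.shape, dtype=bool)
    for idx, geom in enumerate(regions.geometries, start=1):
        # intersects_xy is boundary-inclusive, so border centers resolve
        # to the first polygon in layer order
        take = intersects_xy(geom, lon, lat) & unassigned
        out[take] = idx
        unassigned &= ~take
    return out


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF, one float64 band, NaN nodata)
# ---------------------------------------------------------------------------


def write_raster(path: str | Path, layer: RasterLayer) -> None:
    grid = layer.grid
    geo_keys = [
        1, 1, 0, 3,        # version, revision 1.0, 3 keys
        1024, 0, 1, 2,     # GTModelType = geographic
        1025, 0, 1, 1,     # GTRasterType = PixelIsArea
        2048, 0, 1, 4326,  # GeographicType = WGS84
    ]
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)),
        (_TAG_GEO_KEYS, "H", len(geo_keys), tuple(geo_keys)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(
        str(path),
        layer.masked(),
        extratags=extratags,
        metadata=None,
        photometric="minisblack",
    )


def read_raster(path: str | Path, name: str | None = None) -> RasterLayer:
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path.name}: missing GeoTIFF georeferencing tags")
        if _TAG_GEO_KEYS not in tags:
            raise ValueError(f"{path.name}: missing CRS (GeoKeyDirectory tag)")
        sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        values = page.asarray().astype(float)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            try:
                nodata = float(raw)
            except ValueError:
                nodata = None
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path.name}: non-square cells are not supported")
    n_rows, n_cols = values.shape
    # tiepoint maps raster coordinate (i, j) to model coordinate (x, y)
    origin_lon = tie[3] - tie[0] * sx
    origin_lat = tie[4] + tie[1] * sy
    grid = GridSpec(origin_lon, origin_lat, sx, n_rows, n_cols)
    mask = np.isfinite(values)
    if nodata is not None and math.isfinite(nodata):
        mask &= values != nodata
    return RasterLayer(grid, name or path.stem, values, mask)


def read_raster_stack(paths: Sequence[str | Path], names: Sequence[str] | None = None) -> RasterStack:
    """Read co-registered single-band rasters into a stack.

    Raises :class:`GridMismatchError` naming the first offending file.
    """
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
    if names is None:
        names = [p.stem for p in paths]
    layers = [read_raster(p, n) for p, n in zip(paths, names)]
    grid = layers[0].grid
    for p, lyr in zip(paths, layers):
        if not lyr.grid.approx_equal(grid):
            raise GridMismatchError(
                f"{p.name}: grid does not match {paths[0].name}"
            )
    return RasterStack(layers)


def write_stack(directory: str | Path, stack: RasterStack) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for lyr in stack.layers:
        p = directory / f"{lyr.name}.tif"
        write_raster(p, lyr)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------


def write_regions(path: str | Path, regions: RegionLayer) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"label": lab, "role": regions.role},
            "geometry": mapping(geom),
        }
        for lab, geom in zip(regions.labels, regions.geometries)
    ]
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


def read_regions(path: str | Path, role: str | None = None) -> RegionLayer:
    doc = json.loads(Path(path).read_text())
    labels, geoms = [], []
    file_role = role
    for feat in doc["features"]:
        props = feat.get("properties", {})
        labels.append(str(props.get("label", len(labels) + 1)))
        if file_role is None:
            file_role = props.get("role", "country")
        geoms.append(shape(feat["geometry"]))
    return RegionLayer(labels, geoms, role=file_role or "country")


def grid_box(grid: GridSpec) -> BaseGeometry:
    """Outer bounding box of the grid as a shapely polygon."""
    return box(*grid.bounds)
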