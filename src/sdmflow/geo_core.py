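"""Raster and vector primitives shared by every pipeline stage.

The package works on a single *template grid*: a north-up, row-major
lattice of square(ish) cells in geographic coordinates (WGS84 decimal
degrees).  All derived rasters — suitability surfaces, thresholded
binaries, expert maps — live on that grid, so cellwise algebra between
stages is always safe.

Metric quantities (buffer radii, thinning distances, areas) are computed
in a local equirectangular projection centred on the region of interest:
``x = R cos(lat0) Δlon``, ``y = R Δlat`` with ``R`` the mean Earth radius.
At the national, ~1-km scale this toolkit targets, the distortion of that
projection is far below the tolerances used anywhere in the pipeline.

GeoTIFF round-tripping is implemented directly over :mod:`tifffile` by
reading/writing the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory) plus the GDAL nodata tag, which is sufficient for the
single-band, north-up, EPSG:4326 rasters the pipeline produces.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import (
    MultiPolygon,
    Point,
    Polygon,
    mapping,
    shape,
)
from shapely.ops import unary_union

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEGREE = EARTH_RADIUS_KM * math.pi / 180.0  # ~111.195

__all__ = [
    "Grid",
    "Raster",
    "EnvStack",
    "AccessibleArea",
    "LocalProjection",
    "GridMismatchError",
    "load_stack",
    "buffer_points",
    "convex_hull",
    "mask_raster",
    "default_accessible_area",
    "read_geotiff",
    "write_geotiff",
    "read_geojson",
    "write_geojson",
    "haversine_km",
]


class GridMismatchError(ValueError):
    """Raised when rasters that must share a grid do not."""


# ---------------------------------------------------------------------------
# grid / raster containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid:
    """A north-up geographic raster template.

    Parameters
    ----------
    x0, y0 : float
        Coordinates of the *outer top-left corner* (west edge, north edge).
    dx, dy : float
        Cell width and height in degrees; both positive, rows run south.
    width, height : int
        Number of columns and rows.
    crs : str
        Coordinate reference system identifier; only ``"EPSG:4326"`` is used.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    width: int
    height: int
    crs: str = "EPSG:4326"

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds."""
        return (
            self.x0,
            self.y0 - self.dy * self.height,
            self.x0 + self.dx * self.width,
            self.y0,
        )

    def cell_of(self, lon, lat):
        """Row/col indices of points; half-open cells [edge, edge + step)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - lat) / self.dy).astype(int)
        return row, col

    def contains(self, lon, lat):
        row, col = self.cell_of(lon, lat)
        return (row >= 0) & (row < self.height) & (col >= 0) & (col < self.width)

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x0 + (col + 0.5) * self.dx
        lat = self.y0 - (row + 0.5) * self.dy
        return lon, lat

    def center_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D arrays of cell-centre lon and lat, shape (height, width)."""
        cols = np.arange(self.width)
        rows = np.arange(self.height)
        lon = self.x0 + (cols + 0.5) * self.dx
        lat = self.y0 - (rows + 0.5) * self.dy
        return np.broadcast_to(lon, self.shape).copy(), np.broadcast_to(
            lat[:, None], self.shape
        ).copy()

    def cell_area_km2(self) -> np.ndarray:
        """Per-row cell area in km², broadcast to the grid shape."""
        rows = np.arange(self.height)
        lat = self.y0 - (rows + 0.5) * self.dy
        area_row = (
            self.dx * KM_PER_DEGREE * np.cos(np.radians(lat))
        ) * (self.dy * KM_PER_DEGREE)
        return np.broadcast_to(area_row[:, None], self.shape).copy()

    @property
    def centroid(self) -> tuple[float, float]:
        w, s, e, n = self.bounds
        return ((w + e) / 2.0, (s + n) / 2.0)

    def to_dict(self) -> dict:
        return {
            "x0": self.x0,
            "y0": self.y0,
            "dx": self.dx,
            "dy": self.dy,
            "width": self.width,
            "height": self.height,
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Grid":
        return cls(**{k: d[k] for k in ("x0", "y0", "dx", "dy", "width", "height", "crs")})


@dataclass
class Raster:
    """A single-band raster bound to a :class:`Grid`."""

    grid: Grid
    data: np.ndarray
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            return ~np.isnan(self.data) if self.data.dtype.kind == "f" else np.ones(
                self.data.shape, bool
            )
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return ~np.isnan(self.data)
        return self.data != self.nodata

    def sample(self, lon, lat):
        """Values at point locations; NaN outside the grid or on nodata."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.full(lon.shape, np.nan)
        inside = self.grid.contains(lon, lat)
        row, col = self.grid.cell_of(lon[inside], lat[inside])
        vals = self.data[row, col].astype(float)
        valid = self.valid_mask[row, col]
        vals[~valid] = np.nan
        out[inside] = vals
        return out


class EnvStack:
    """A set of co-registered environmental layers sharing one grid.

    Layers are harmonised on construction: the shared nodata mask is the
    cellwise union of each layer's nodata holes, and every layer is then
    masked to it.
    """

    def __init__(self, grid: Grid, layers: Mapping[str, np.ndarray],
                 nodata: float = float("nan")) -> None:
        if len(layers) == 0:
            raise ValueError("EnvStack needs at least one layer")
        names = list(layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.grid = grid
        self.nodata = nodata
        arrays = {}
        valid = np.ones(grid.shape, dtype=bool)
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != grid.shape:
                raise GridMismatchError(
                    f"layer {name!r} shape {arr.shape} != grid {grid.shape}"
                )
            valid &= ~np.isnan(arr)
            arrays[name] = arr
        self._valid = valid
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in arrays.items():
            out = arr.copy()
            out[~valid] = np.nan
            self.layers[name] = out

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        return self._valid

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def raster(self, name: str) -> Raster:
        return Raster(self.grid, self.layers[name], nodata=float("nan"))

    def subset(self, names: Sequence[str]) -> "EnvStack":
        """A new stack holding only the named layers (e.g. the predictors)."""
        return EnvStack(self.grid, {n: self.layers[n] for n in names})

    def table(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Valid cells as an (n_cells, n_layers) matrix, row-major order."""
        names = list(names) if names is not None else self.names
        cols = [self.layers[n][self._valid] for n in names]
        return np.column_stack(cols)

    def sample(self, lon, lat, names: Sequence[str] | None = None) -> np.ndarray:
        """Env values at points: (n_points, n_layers); NaN where invalid."""
        names = list(names) if names is not None else self.names
        return np.column_stack(
            [Raster(self.grid, self.layers[n]).sample(lon, lat) for n in names]
        )


@dataclass
class AccessibleArea:
    """The accessible region M: background is drawn and predictions clipped here."""

    geometry: Polygon | MultiPolygon
    provenance: str = "default"  # expert-drawn | buffer-derived | default

    def __post_init__(self) -> None:
        if self.geometry.is_empty:
            raise ValueError("accessible area geometry is empty")
        if not self.geometry.is_valid:
            self.geometry = shapely.make_valid(self.geometry)

    def mask_on(self, grid: Grid) -> np.ndarray:
        """Boolean mask of grid cells whose centre falls inside M."""
        return rasterize_geometry(self.geometry, grid)


# ---------------------------------------------------------------------------
# projection helpers
# ---------------------------------------------------------------------------


class LocalProjection:
    """Equirectangular projection (km) around a reference point."""

    def __init__(self, lon0: float, lat0: float) -> None:
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._kx = KM_PER_DEGREE * math.cos(math.radians(self.lat0))
        self._ky = KM_PER_DEGREE

    @classmethod
    def for_points(cls, lon, lat) -> "LocalProjection":
        return cls(float(np.mean(lon)), float(np.mean(lat)))

    @classmethod
    def for_grid(cls, grid: Grid) -> "LocalProjection":
        return cls(*grid.centroid)

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon - self.lon0) * self._kx, (lat - self.lat0) * self._ky

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return x / self._kx + self.lon0, y / self._ky + self.lat0

    def project_geometry(self, geom):
        return shapely.transform(geom, lambda pts: np.column_stack(
            self.forward(pts[:, 0], pts[:, 1])))

    def unproject_geometry(self, geom):
        return shapely.transform(geom, lambda pts: np.column_stack(
            self.inverse(pts[:, 0], pts[:, 1])))


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km (exact on the sphere); broadcasts."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def load_stack(paths: Mapping[str, str] | Sequence[str], *,
               resample: bool = False) -> EnvStack:
    """Load co-registered GeoTIFF layers into an :class:`EnvStack`.

    ``paths`` is either a name→path mapping or a sequence of paths (layer
    names taken from file stems).  All rasters must share the template grid
    exactly; ``resample=True`` nearest-neighbour-resamples later layers onto
    the first layer's grid instead of raising.
    """
    if not isinstance(paths, Mapping):
        import os

        paths = {os.path.splitext(os.path.basename(p))[0]: p for p in paths}
    if not paths:
        raise ValueError("no raster paths given")
    layers: dict[str, np.ndarray] = {}
    template: Grid | None = None
    for name, path in paths.items():
        rast = read_geotiff(path)
        data = np.asarray(rast.data, dtype=float)
        if rast.nodata is not None and not math.isnan(rast.nodata):
            data[data == rast.nodata] = np.nan
        if template is None:
            template = rast.grid
        elif rast.grid != template:
            if rast.grid.crs != template.crs:
                raise GridMismatchError(
                    f"layer {name!r}: CRS {rast.grid.crs} != {template.crs}")
            if not resample:
                raise GridMismatchError(
                    f"layer {name!r} grid differs from template; "
                    "pass resample=True to resample")
            lon, lat = template.center_arrays()
            data = Raster(rast.grid, data).sample(lon.ravel(), lat.ravel()).reshape(
                template.shape)
        layers[name] = data
    assert template is not None
    return EnvStack(template, layers)


def buffer_points(lon, lat, radius_km: float, *, quad_segs: int = 64):
    """Union of metric buffers around points, as WGS84 geometry.

    Buffers are constructed in the local metric projection (so the radius
    is a true ground distance) and mapped back to geographic coordinates.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size == 0:
        raise ValueError("buffer_points requires at least one point")
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    proj = LocalProjection.for_points(lon, lat)
    x, y = proj.forward(lon, lat)
    disks = [Point(xi, yi).buffer(radius_km, quad_segs=quad_segs)
             for xi, yi in zip(x, y)]
    merged = unary_union(disks)
    return proj.unproject_geometry(merged)


def convex_hull(lon, lat) -> Polygon:
    """Minimal convex polygon containing all points (geographic coords).

    Raises ``ValueError`` for fewer than 3 points or collinear input; the
    modeling ladder falls back to the buffer method in that case.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size < 3:
        raise ValueError("convex hull needs at least 3 points")
    hull = shapely.convex_hull(shapely.multipoints(np.column_stack([lon, lat])))
    # exact collinearity gives a LineString; floating-point near-collinearity
    # gives a sliver polygon -- both are degenerate for the modeling ladder
    extent = max(lon.max() - lon.min(), lat.max() - lat.min())
    if hull.geom_type != "Polygon" or hull.area <= 1e-12 * extent ** 2:
        raise ValueError("points are collinear; hull is degenerate")
    return hull


def rasterize_geometry(geom, grid: Grid) -> np.ndarray:
    """Boolean mask of cells whose centre lies inside the geometry."""
    lon, lat = grid.center_arrays()
    shapely.prepare(geom)
    return shapely.contains_xy(geom, lon.ravel(), lat.ravel()).reshape(grid.shape)


def mask_raster(raster: Raster, *, geometry=None,
                landcover: Raster | None = None,
                allowed_classes: Iterable | None = None,
                fill: str = "auto") -> Raster:
    """Mask a raster by a polygon and/or a categorical land-cover raster.

    Cells outside the geometry, or whose land-cover class is not in
    ``allowed_classes``, are set to 0 for integer (binary) rasters and to
    nodata/NaN for float rasters.  Inside values are unchanged.
    """
    if geometry is None and allowed_classes is None:
        raise ValueError("need a geometry or an allowed-class set")
    keep = np.ones(raster.grid.shape, dtype=bool)
    if geometry is not None:
        if geometry.is_empty:
            raise ValueError("mask geometry is empty")
        gmask = rasterize_geometry(geometry, raster.grid)
        if not gmask.any():
            warnings.warn("mask geometry is disjoint from the raster extent; "
                          "output is fully masked", stacklevel=2)
        keep &= gmask
    if allowed_classes is not None:
        allowed = set(allowed_classes)
        if not allowed:
            raise ValueError("allowed-class set is empty")
        if landcover is None:
            raise ValueError("allowed_classes given without a land-cover raster")
        if landcover.grid != raster.grid:
            raise GridMismatchError("land-cover raster not on the template grid")
        keep &= np.isin(landcover.data, list(allowed))
    data = raster.data.copy()
    binary = fill == "zero" or (fill == "auto" and data.dtype.kind in "iub")
    if binary:
        data[~keep] = 0
        return Raster(raster.grid, data, nodata=raster.nodata)
    data = data.astype(float)
    data[~keep] = np.nan
    return Raster(raster.grid, data, nodata=float("nan"))


def default_accessible_area(lon, lat, grid: Grid,
                            radius_km: float = 200.0) -> AccessibleArea:
    """Fallback M when experts draw none: a buffer around the occurrences,
    clipped to the template-grid extent."""
    buf = buffer_points(lon, lat, radius_km)
    w, s, e, n = grid.bounds
    clipped = buf.intersection(shapely.box(w, s, e, n))
    if clipped.is_empty:
        raise ValueError("default accessible area does not intersect the grid")
    return AccessibleArea(clipped, provenance="buffer-derived")


# ---------------------------------------------------------------------------
# GeoTIFF / GeoJSON I/O
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKeyDirectory for plain EPSG:4326, PixelIsArea
_GEO_KEYS_4326 = (
    1, 1, 0, 3,
    1024, 0, 1, 2,     # GTModelType = geographic
    1025, 0, 1, 1,     # GTRasterType = PixelIsArea
    2048, 0, 1, 4326,  # GeographicType = WGS84
)


def write_geotiff(path, raster: Raster) -> None:
    """Write a single-band GeoTIFF (float32 for continuous, uint8 for binary)."""
    grid = raster.grid
    data = raster.data
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
        nodata = raster.nodata if raster.nodata is not None else float("nan")
    else:
        data = data.astype(np.uint8)
        nodata = raster.nodata
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.dx, grid.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, grid.y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS_4326), _GEO_KEYS_4326),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(path, data, extratags=extratags)


def read_geotiff(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        try:
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        x0 = tie[3] - tie[0] * sx
        y0 = tie[4] + tie[1] * sy
        crs = "EPSG:4326"
        if _TAG_GEO_KEYS in tags:
            keys = tags[_TAG_GEO_KEYS].value
            for i in range(4, len(keys), 4):
                if keys[i] == 2048:
                    crs = f"EPSG:{keys[i + 3]}"
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    grid = Grid(x0=x0, y0=y0, dx=sx, dy=sy,
                width=data.shape[1], height=data.shape[0], crs=crs)
    return Raster(grid, data, nodata=nodata)


def write_geojson(path, geometries, properties: Sequence[Mapping] | None = None) -> None:
    """Write geometries (shapely) as a GeoJSON FeatureCollection."""
    if not isinstance(geometries, (list, tuple)):
        geometries = [geometries]
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": dict(p)}
        for g, p in zip(geometries, properties)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path):
    """Read a GeoJSON file; returns (geometries, properties) lists."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
        props = [f.get("properties") or {} for f in doc["features"]]
        return geoms, props
    if doc.get("type") == "Feature":
        return [shape(doc["geometry"])], [doc.get("properties") or {}]
    return [shape(doc)], [{}]
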