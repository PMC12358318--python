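"""Grid and vector data model, GeoTIFF/GeoJSON I/O, terrain derivatives and
the exact Jenks (Fisher) natural-breaks classifier.

Every layer in an analysis lives on one shared, projected, square-celled
grid (row 0 at the top / north; half-open cell extents).  Nothing in the
package resamples: layers that do not align are rejected.  All distances are
meters and all areas are ``cell count x cell_size**2`` reported in km2.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from numba import njit
from scipy import ndimage
from shapely.geometry import mapping as geom_mapping, shape as geom_shape

__all__ = [
    "RasterGrid",
    "VectorLayer",
    "ClassBreaks",
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
    "rasterize",
    "distance_to",
    "terrain",
    "jenks_breaks",
]

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """A single-band georeferenced raster on a projected, square-celled grid.

    ``values`` is row-major with row 0 at the top (north).  Cell ``(r, c)``
    covers the half-open square
    ``[origin_x + c*s, origin_x + (c+1)*s) x (origin_y - (r+1)*s, origin_y - r*s]``
    where ``s`` is ``cell_size`` in meters and ``(origin_x, origin_y)`` is the
    top-left corner of the grid.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 30.0
    nodata: float = -9999.0
    crs_id: str = "EPSG:32650"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data (True = valid)."""
        v = self.values
        mask = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            mask &= np.isfinite(v)
        return mask

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, each shape (nrows, ncols)."""
        s = self.cell_size
        cols = self.origin_x + (np.arange(self.ncols) + 0.5) * s
        rows = self.origin_y - (np.arange(self.nrows) + 0.5) * s
        x, y = np.meshgrid(cols, rows)
        return x, y

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        s = self.cell_size
        return (self.origin_x + (col + 0.5) * s, self.origin_y - (row + 0.5) * s)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing projected point (x, y)."""
        col = int(math.floor((x - self.origin_x) / self.cell_size))
        row = int(math.floor((self.origin_y - y) / self.cell_size))
        return row, col

    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def area_km2(self, mask: np.ndarray | None = None) -> float:
        """Area of the given boolean mask (default: all valid cells), km2."""
        if mask is None:
            mask = self.valid_mask()
        return float(np.count_nonzero(mask)) * self.cell_area_km2()

    # -- derivation helpers ---------------------------------------------
    def like(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """New grid sharing this grid's georeferencing."""
        out = replace(self, values=np.asarray(values))
        if nodata is not None:
            out.nodata = nodata
        return out

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-6)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
            and self.crs_id == other.crs_id
        )

    def require_aligned(self, other: "RasterGrid", what: str = "layer") -> None:
        if not self.aligned_with(other):
            raise ValueError(
                f"{what} is not grid-aligned: {other.shape}@"
                f"({other.origin_x},{other.origin_y},{other.cell_size},{other.crs_id})"
                f" vs {self.shape}@({self.origin_x},{self.origin_y},"
                f"{self.cell_size},{self.crs_id})"
            )


@dataclass
class VectorLayer:
    """Features in the analysis CRS: (shapely geometry, attribute dict) pairs."""

    features: list[tuple[shapely.Geometry, dict]] = field(default_factory=list)
    crs_id: str = "EPSG:32650"

    def __len__(self) -> int:
        return len(self.features)

    def geometries(self) -> list[shapely.Geometry]:
        return [g for g, _ in self.features]

    def union(self) -> shapely.Geometry:
        return shapely.union_all(self.geometries())

    def filter(self, predicate) -> "VectorLayer":
        return VectorLayer(
            [(g, a) for g, a in self.features if predicate(g, a)], self.crs_id
        )


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single-band, square cells, projected CRS)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a single-band GeoTIFF (float32 for float data, int32 for integer)."""
    v = grid.values
    if np.issubdtype(v.dtype, np.integer):
        data = v.astype(np.int32)
    else:
        data = v.astype(np.float32)
    # minimal GeoKey directory: projected model, area raster, citation string
    geokeys = (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3073, 34737, len(grid.crs_id) + 1, 0)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GEO_ASCII_PARAMS, "s", 0, grid.crs_id + "|"),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata))),
    ]
    tifffile.imwrite(str(path), data, extratags=extratags)


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    GeoTIFF carrying pixel-scale, tiepoint and nodata tags with square cells)."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        tags = page.tags
        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tiepoint is None or tags.get(_TAG_GEO_KEY_DIRECTORY) is None:
            raise ValueError(f"{path}: not a georeferenced GeoTIFF (missing CRS/geo tags)")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
        tp = tiepoint.value
        origin_x = float(tp[3]) - float(tp[0]) * sx
        origin_y = float(tp[4]) + float(tp[1]) * sy
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0
        ascii_tag = tags.get(_TAG_GEO_ASCII_PARAMS)
        crs_id = "unknown"
        if ascii_tag is not None:
            crs_id = str(ascii_tag.value).split("|")[0].strip()
        values = page.asarray()
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    return RasterGrid(values=values, origin_x=origin_x, origin_y=origin_y,
                      cell_size=sx, nodata=nodata, crs_id=crs_id)


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def write_vector(layer: VectorLayer, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "crs_id": layer.crs_id,
        "features": [
            {"type": "Feature", "geometry": geom_mapping(g), "properties": attrs}
            for g, attrs in layer.features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_vector(path: str | Path) -> VectorLayer:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    feats = [
        (geom_shape(f["geometry"]), dict(f.get("properties") or {}))
        for f in fc.get("features", [])
    ]
    return VectorLayer(feats, fc.get("crs_id", "unknown"))


# ---------------------------------------------------------------------------
# Rasterization and distance
# ---------------------------------------------------------------------------

def rasterize(features: VectorLayer | Iterable[shapely.Geometry],
              template: RasterGrid) -> np.ndarray:
    """Boolean mask of cells covered by the features.

    Polygons mark cells whose center falls inside; points and lines mark the
    cell containing them (geometries are buffered by half a cell edge so a
    polyline paints a ~1-cell-wide trace).
    """
    geoms = features.geometries() if isinstance(features, VectorLayer) else list(features)
    if not geoms:
        raise ValueError("cannot rasterize an empty feature set")
    x, y = template.cell_centers()
    mask = np.zeros(template.shape, dtype=bool)
    half = 0.5 * template.cell_size
    for g in geoms:
        if g.is_empty:
            continue
        # zero-area geometries get half a cell diagonal so the nearest cell
        # center is covered even for points on cell corners
        gg = g if g.area > 0 else g.buffer(half * math.sqrt(2.0) + 1e-9)
        # bbox pre-filter keeps contains_xy cheap on large grids
        minx, miny, maxx, maxy = gg.bounds
        sel = (x >= minx - half) & (x <= maxx + half) & (y >= miny - half) & (y <= maxy + half)
        if not sel.any():
            continue
        hit = shapely.contains_xy(gg, x[sel], y[sel])
        idx = np.nonzero(sel)
        mask[idx[0][hit], idx[1][hit]] = True
    return mask


def distance_to(features: VectorLayer, template: RasterGrid) -> RasterGrid:
    """Euclidean distance (m) from every cell center to the nearest cell
    center covered by the rasterized features.  Cells on features hold 0."""
    if isinstance(features, VectorLayer) and len(features) == 0:
        raise ValueError("distance_to: empty feature set (distance undefined)")
    mask = rasterize(features, template)
    if not mask.any():
        raise ValueError("distance_to: features rasterized to zero cells")
    dist = ndimage.distance_transform_edt(
        ~mask, sampling=(template.cell_size, template.cell_size)
    )
    return template.like(dist.astype(np.float64))


# ---------------------------------------------------------------------------
# Terrain derivatives
# ---------------------------------------------------------------------------

def terrain(dem: RasterGrid, relief_window: int = 3) -> tuple[RasterGrid, RasterGrid]:
    """Slope (degrees, Horn's 3x3 finite differences) and relief
    (max - min elevation in a square moving window, meters).

    Edges are handled by edge replication.  Output is nodata wherever the DEM
    is nodata.
    """
    if relief_window < 1 or relief_window % 2 == 0:
        raise ValueError("relief_window must be a positive odd integer")
    if dem.nrows < relief_window or dem.ncols < relief_window:
        raise ValueError("grid smaller than the relief window")
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("grid smaller than the 3x3 slope window")

    valid = dem.valid_mask()
    z = np.where(valid, dem.values.astype(np.float64), np.nan)
    # fill nodata with nearest valid value so the stencils stay finite
    if not valid.all():
        if not valid.any():
            raise ValueError("DEM has no valid cells")
        idx = ndimage.distance_transform_edt(~valid, return_distances=False,
                                             return_indices=True)
        z = z[tuple(idx)]

    s = dem.cell_size
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
    dzdx = ndimage.convolve(z, kx[::-1, ::-1], mode="nearest") / (8.0 * s)
    dzdy = ndimage.convolve(z, kx.T[::-1, ::-1], mode="nearest") / (8.0 * s)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    zmax = ndimage.maximum_filter(z, size=relief_window, mode="nearest")
    zmin = ndimage.minimum_filter(z, size=relief_window, mode="nearest")
    relief = zmax - zmin

    slope[~valid] = dem.nodata
    relief[~valid] = dem.nodata
    return dem.like(slope), dem.like(relief)


# ---------------------------------------------------------------------------
# Jenks natural breaks (exact Fisher dynamic program)
# ---------------------------------------------------------------------------

@dataclass
class ClassBreaks:
    """k-class 1-D classification: k-1 ascending interior cut values.

    A break is the maximum data value of its class, so ``value <= breaks[i]``
    assigns class ``i+1`` (classes are 1-based; class k is the highest)."""

    k: int
    breaks: list[float]
    method: str = "jenks"

    def __post_init__(self) -> None:
        if len(self.breaks) != self.k - 1:
            raise ValueError("need exactly k-1 interior breaks")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly ascending")

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Class index in 1..k per finite value (nodata caller-managed)."""
        v = np.asarray(values, dtype=np.float64)
        return np.searchsorted(np.asarray(self.breaks), v, side="left") + 1


@njit(cache=True)
def _fisher_jenks_dp(x: np.ndarray, k: int):  # pragma: no cover - numba
    """Exact O(k n^2) Fisher dynamic program on sorted data.

    Returns (split_starts, objective): split_starts[j] is the 0-based index at
    which class j+1 starts.  Ties take the smallest start index, which yields
    the lowest possible break values during backtracking.
    """
    n = x.shape[0]
    s1 = np.zeros(n + 1)
    s2 = np.zeros(n + 1)
    for i in range(n):
        s1[i + 1] = s1[i] + x[i]
        s2[i + 1] = s2[i] + x[i] * x[i]

    # cost[i, j]: within-class SSD of x[i..j] inclusive
    prev = np.empty(n)          # best objective using 1 class for x[0..j]
    for j in range(n):
        m = j + 1
        sv = s1[m]
        prev[j] = s2[m] - sv * sv / m

    choice = np.zeros((k, n), dtype=np.int64)
    cur = np.empty(n)
    for c in range(1, k):
        for j in range(n):
            if j < c:
                cur[j] = 0.0
                choice[c, j] = j
                continue
            best = np.inf
            arg = c
            for i in range(c, j + 1):
                m = j - i + 1
                sv = s1[j + 1] - s1[i]
                cost = s2[j + 1] - s2[i] - sv * sv / m
                total = prev[i - 1] + cost
                if total < best - 1e-12:
                    best = total
                    arg = i
            cur[j] = best
            choice[c, j] = arg
        for j in range(n):
            prev[j] = cur[j]

    # backtrack
    starts = np.empty(k, dtype=np.int64)
    j = n - 1
    for c in range(k - 1, 0, -1):
        starts[c] = choice[c, j]
        j = starts[c] - 1
    starts[0] = 0
    return starts, prev[n - 1]


def jenks_breaks(values: Sequence[float] | np.ndarray, k: int) -> ClassBreaks:
    """Exact Jenks/Fisher optimal k-class partition of 1-D data.

    Minimizes total within-class sum of squared deviations; deterministic
    (ties resolved toward the lowest break values).  Requires at least k
    distinct finite values.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if k < 2:
        raise ValueError("k must be >= 2")
    distinct = np.unique(v)
    if distinct.size < k:
        raise ValueError(f"need >= {k} distinct values, got {distinct.size}")
    x = np.sort(v)
    starts, _obj = _fisher_jenks_dp(x, k)
    breaks = [float(x[starts[c] - 1]) for c in range(1, k)]
    return ClassBreaks(k=k, breaks=breaks, method="jenks")


def jenks_objective(values: Sequence[float] | np.ndarray, k: int) -> float:
    """Optimal total within-class SSD achieved by :func:`jenks_breaks`."""
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    v = v[np.isfinite(v)]
    _, obj = _fisher_jenks_dp(v, k)
    return float(obj)
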