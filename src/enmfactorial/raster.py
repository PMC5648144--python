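"""Gridded-layer data model and raster I/O.

Environmental predictors, principal-component scores, suitability surfaces
and binary range maps all live on north-up, square-celled geographic grids
(lon/lat degrees).  :class:`GridLayer` carries one such grid together with a
validity mask; :class:`GridStack` bundles co-registered layers and their
joint mask (a cell is usable only where *every* layer has data — the
"empty cells" rule for mixed climate/soil coverage).

GeoTIFF reading and writing is implemented directly over :mod:`tifffile`
using the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory, GDAL_NODATA).  Only single-band, unrotated, square-celled
rasters are supported; anything else is rejected loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "GridLayer",
    "GridStack",
    "read_geotiff",
    "write_geotiff",
    "aggregate_mean",
    "crop_extent",
    "extract_values",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_MODEL_TRANSFORMATION = 34264
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

#: GeoKey directory declaring a geographic (lon/lat) CRS, WGS84, PixelIsArea.
_GEOKEYS_WGS84 = (
    1, 1, 0, 3,          # version, revision, minor, number of keys
    1024, 0, 1, 2,       # GTModelTypeGeoKey = geographic
    1025, 0, 1, 1,       # GTRasterTypeGeoKey = PixelIsArea
    2048, 0, 1, 4326,    # GeographicTypeGeoKey = WGS84
)

_GEO_EPS = 1e-9


@dataclass
class GridLayer:
    """A single north-up raster layer in geographic degrees.

    Cell ``(i, j)`` covers the half-open box
    ``[origin_x + j*s, origin_x + (j+1)*s) x (origin_y - (i+1)*s, origin_y - i*s]``
    with ``s = cell_size``; left/top edges are inclusive so every point maps
    to exactly one cell.  Invalid cells hold NaN in ``values``.
    """

    name: str
    values: np.ndarray
    valid: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    crs_label: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).copy()
        self.valid = np.asarray(self.valid, dtype=bool).copy()
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have identical shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.valid &= np.isfinite(self.values)
        self.values[~self.valid] = np.nan

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of the full grid extent."""
        nr, nc = self.shape
        return (
            self.origin_x,
            self.origin_y - nr * self.cell_size,
            self.origin_x + nc * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon of column centers, lat of row centers)."""
        nr, nc = self.shape
        lon = self.origin_x + (np.arange(nc) + 0.5) * self.cell_size
        lat = self.origin_y - (np.arange(nr) + 0.5) * self.cell_size
        return lon, lat

    def point_to_cell(self, lon, lat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col, inside) under the half-open convention."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        j = np.floor((lon - self.origin_x) / self.cell_size).astype(int)
        i = np.floor((self.origin_y - lat) / self.cell_size).astype(int)
        # top edge (lat == origin_y) belongs to row 0, bottom boundary to the
        # lower row: (origin_y - lat)/s is exact there, floor handles it.
        nr, nc = self.shape
        inside = (i >= 0) & (i < nr) & (j >= 0) & (j < nc)
        return i, j, inside

    def same_geometry(self, other: "GridLayer", tol: float = _GEO_EPS) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def copy(self, **changes) -> "GridLayer":
        out = replace(self, **changes)
        return out


@dataclass
class GridStack:
    """An ordered bundle of co-registered :class:`GridLayer` objects."""

    layers: list[GridLayer]
    joint_valid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("GridStack needs at least one layer")
        ref = self.layers[0]
        for lyr in self.layers[1:]:
            if not ref.same_geometry(lyr) or lyr.crs_label != ref.crs_label:
                raise ValueError(
                    f"layer {lyr.name!r} is not co-registered with {ref.name!r}"
                )
        jv = np.ones(ref.shape, dtype=bool)
        for lyr in self.layers:
            jv &= lyr.valid
        self.joint_valid = jv

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].shape

    @property
    def geometry(self) -> GridLayer:
        return self.layers[0]

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> GridLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "GridStack":
        return GridStack([self[n] for n in names])

    def concat(self, other: "GridStack") -> "GridStack":
        return GridStack(list(self.layers) + list(other.layers))

    def to_matrix(self, where_valid: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid_cells x n_layers matrix, flat indices of those cells)."""
        flat = [l.values.ravel() for l in self.layers]
        mat = np.column_stack(flat)
        if where_valid:
            idx = np.flatnonzero(self.joint_valid.ravel())
            return mat[idx], idx
        return mat, np.arange(mat.shape[0])


# -- GeoTIFF I/O -------------------------------------------------------------

def write_geotiff(layer: GridLayer, path: str | Path) -> Path:
    """Write a layer as a single-band float64 GeoTIFF (NaN nodata)."""
    path = Path(path)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (layer.cell_size, layer.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, layer.origin_x, layer.origin_y, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84),
        (_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(
        path,
        layer.values,
        description=layer.name,
        extratags=extratags,
        photometric="minisblack",
    )
    return path


def _tag_value(page, code):
    tag = page.tags.get(code)
    return None if tag is None else tag.value


def read_geotiff(path: str | Path, name: str | None = None) -> GridLayer:
    """Read a single-band, north-up, square-celled GeoTIFF."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise ValueError(f"{path}: multi-band/multi-page rasters are not supported")
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: multi-sample rasters are not supported")
        values = page.asarray().astype(np.float64)
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a 2-D single-band raster")

        transform = _tag_value(page, _MODEL_TRANSFORMATION)
        if transform is not None:
            t = np.asarray(transform, dtype=float).reshape(4, 4)
            if abs(t[0, 1]) > _GEO_EPS or abs(t[1, 0]) > _GEO_EPS:
                raise ValueError(f"{path}: rotated geotransforms are not supported")
            sx, sy = t[0, 0], -t[1, 1]
            ox, oy = t[0, 3], t[1, 3]
        else:
            scale = _tag_value(page, _MODEL_PIXEL_SCALE)
            tiepoint = _tag_value(page, _MODEL_TIEPOINT)
            if scale is None or tiepoint is None:
                raise ValueError(f"{path}: missing GeoTIFF geotransform tags")
            sx, sy = float(scale[0]), float(scale[1])
            ti = np.asarray(tiepoint, dtype=float)
            # tiepoint maps raster (I,J,K) -> model (X,Y,Z)
            ox = ti[3] - ti[0] * sx
            oy = ti[4] + ti[1] * sy
        if abs(sx - sy) > _GEO_EPS:
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) are not supported")

        nodata = _tag_value(page, _GDAL_NODATA)
        valid = np.isfinite(values)
        if nodata is not None:
            nd = str(nodata).strip().strip("\x00")
            if nd and nd.lower() != "nan":
                valid &= values != float(nd)

        descr = page.tags.get(270)
        layer_name = name or (descr.value if descr is not None else None) or path.stem

    return GridLayer(
        name=str(layer_name),
        values=values,
        valid=valid,
        origin_x=float(ox),
        origin_y=float(oy),
        cell_size=float(sx),
    )


def write_stack(stack: GridStack, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [write_geotiff(l, directory / f"{l.name}.tif") for l in stack.layers]


def read_stack(paths: Iterable[str | Path]) -> GridStack:
    return GridStack([read_geotiff(p) for p in paths])


# -- raster operations -------------------------------------------------------

def aggregate_mean(layer: GridLayer, factor: int) -> GridLayer:
    """Upscale by averaging ``factor`` x ``factor`` blocks of valid cells.

    Trailing partial blocks are averaged over the cells actually present;
    a block with no valid cell yields an invalid coarse cell.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("aggregation factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return layer.copy()
    nr, nc = layer.shape
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:nr, :nc] = layer.values
    blocks = padded.reshape(out_r, factor, out_c, factor)
    with np.errstate(invalid="ignore"):
        counts = np.isfinite(blocks).sum(axis=(1, 3))
        sums = np.nansum(blocks, axis=(1, 3))
    values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return GridLayer(
        name=layer.name,
        values=values,
        valid=counts > 0,
        origin_x=layer.origin_x,
        origin_y=layer.origin_y,
        cell_size=layer.cell_size * factor,
        crs_label=layer.crs_label,
    )


def crop_extent(layer: GridLayer, bbox: tuple[float, float, float, float]) -> GridLayer:
    """Crop to the cells whose centers fall inside ``bbox`` (closed bounds).

    ``bbox`` is (lon_min, lat_min, lon_max, lat_max).
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    lon_c, lat_c = layer.cell_centers()
    jsel = np.flatnonzero((lon_c >= lon_min) & (lon_c <= lon_max))
    isel = np.flatnonzero((lat_c >= lat_min) & (lat_c <= lat_max))
    if jsel.size == 0 or isel.size == 0:
        raise ValueError("crop bbox does not intersect the layer extent")
    i0, i1 = isel[0], isel[-1] + 1
    j0, j1 = jsel[0], jsel[-1] + 1
    return GridLayer(
        name=layer.name,
        values=layer.values[i0:i1, j0:j1],
        valid=layer.valid[i0:i1, j0:j1],
        origin_x=layer.origin_x + j0 * layer.cell_size,
        origin_y=layer.origin_y - i0 * layer.cell_size,
        cell_size=layer.cell_size,
        crs_label=layer.crs_label,
    )


def extract_values(
    stack: GridStack, lon, lat
) -> tuple[np.ndarray, np.ndarray]:
    """Extract per-layer cell values at points.

    Returns ``(X, ok)`` where ``X`` is an ``n_points x n_layers`` matrix and
    ``ok`` flags points that fall inside the extent *and* on a jointly valid
    cell.  Points outside the extent or over invalid cells get NaN rows and
    ``ok = False`` — they are flagged, never dropped.
    """
    geom = stack.geometry
    i, j, inside = geom.point_to_cell(lon, lat)
    n = i.size
    X = np.full((n, len(stack)), np.nan)
    ok = np.zeros(n, dtype=bool)
    ii, jj = i[inside], j[inside]
    for k, lyr in enumerate(stack.layers):
        X[inside, k] = lyr.values[ii, jj]
    ok[inside] = stack.joint_valid[ii, jj]
    return X, ok
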