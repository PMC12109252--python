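"""Shared raster data model: grid geometry, GeoTIFF I/O, resampling, overlay.

Every layer in the pipeline lives on one :class:`GridSpec` — a north-up,
planar-CRS grid with square cells indexed row-major from the top-left corner.
Cell centers sit at ``origin + (index + 0.5) * cell_size`` and point-to-cell
mapping uses half-open cell intervals, so inverse-distance computations are
unambiguous. All distances are planar; no geodesic math anywhere.

GeoTIFF files are read and written through :mod:`tifffile` using the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA). Only single-band,
north-up files are supported; rotated geotransforms are rejected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import AlignmentError, ConfigError, FormatError

#: default nodata sentinels
FLOAT_NODATA = -9999.0
LABEL_NODATA = 255

# GeoTIFF / GDAL TIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_TRANSFORM = 34264
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid in a projected (planar, meter) CRS.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; must be >= 1.
    cell_size : float
        Cell edge length in meters (cells are square). The study design uses
        1 km cells, hence the default.
    origin_x, origin_y : float
        Coordinates of the *top-left corner* of the grid. y decreases
        downward (north-up raster convention).
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1000.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares: (cell_size / 100)**2."""
        return (self.cell_size / 100.0) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center as 2-D arrays."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Map a point to its containing (row, col), or None if outside.

        Cells are half-open: a point on the shared edge of two cells belongs
        to the cell with the larger index (right/down).
        """
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None


@dataclass
class Raster:
    """A single-band numeric field on a :class:`GridSpec`.

    ``nodata`` cells (exact sentinel match) are excluded from every statistic.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: float = FLOAT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise AlignmentError(
                f"values shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the cell is valid (not nodata/NaN)."""
        return (self.values != self.nodata) & ~np.isnan(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.nodata)


class LandUseClass(enum.IntEnum):
    """Land-use/land-cover legend shared across the pipeline."""

    ARABLE = 1
    BROADLEAF_FOREST = 2
    OTHER_FOREST = 3
    GRASSLAND = 4
    WATER = 5
    URBAN = 6
    BARE = 7


#: classes that carry no primary-sector production and get zero allocation mass
NON_PRODUCTIVE_CLASSES = frozenset({LandUseClass.URBAN, LandUseClass.BARE})

LAND_USE_LEGEND: dict[int, str] = {c.value: c.name.lower() for c in LandUseClass}


@dataclass
class LabelRaster:
    """Integer-coded categorical field (admin units, land use, strata)."""

    grid: GridSpec
    labels: np.ndarray
    legend: Mapping[int, str] = field(default_factory=dict)
    nodata: int = LABEL_NODATA

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigError("LabelRaster requires integer labels")
        if self.labels.shape != self.grid.shape:
            raise AlignmentError(
                f"labels shape {self.labels.shape} does not match grid "
                f"{self.grid.shape}"
            )
        if self.legend:
            present = set(np.unique(self.labels[self.labels != self.nodata]).tolist())
            missing = present - set(int(k) for k in self.legend)
            if missing:
                raise ConfigError(f"labels missing from legend: {sorted(missing)}")

    @property
    def mask(self) -> np.ndarray:
        return self.labels != self.nodata

    def copy(self) -> "LabelRaster":
        return LabelRaster(self.grid, self.labels.copy(), dict(self.legend), self.nodata)


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(path, raster: Raster | LabelRaster) -> None:
    """Write a single-band north-up GeoTIFF with nodata tag."""
    if isinstance(raster, LabelRaster):
        values = raster.labels.astype(np.uint8 if raster.labels.max(initial=0) < 256
                                      and raster.labels.min(initial=0) >= 0
                                      else np.int32)
    else:
        values = raster.values
    g = raster.grid
    tifffile.imwrite(
        str(path),
        values,
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, repr(raster.nodata)),
        ],
    )


def _read_page(path):
    try:
        tif = tifffile.TiffFile(str(path))
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"unreadable raster {path!r}: {exc}") from exc
    with tif:
        if len(tif.pages) != 1:
            raise FormatError("multi-page TIFFs are not supported")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise FormatError("multi-band rasters are not supported")
        if _TAG_TRANSFORM in page.tags:
            m = np.asarray(page.tags[_TAG_TRANSFORM].value, dtype=float).reshape(4, 4)
            if m[0, 1] != 0.0 or m[1, 0] != 0.0:
                raise FormatError("rotated geotransforms are not supported")
            scale = (m[0, 0], -m[1, 1])
            origin = (m[0, 3], m[1, 3])
        elif _TAG_PIXEL_SCALE in page.tags and _TAG_TIEPOINT in page.tags:
            sx, sy = page.tags[_TAG_PIXEL_SCALE].value[:2]
            tp = page.tags[_TAG_TIEPOINT].value
            origin = (tp[3] - tp[0] * sx, tp[4] + tp[1] * sy)
            scale = (sx, sy)
        else:
            raise FormatError(f"{path!r} carries no GeoTIFF geotransform tags")
        if scale[0] != scale[1]:
            raise FormatError("non-square cells are not supported")
        nodata = None
        if _TAG_GDAL_NODATA in page.tags:
            nodata = float(page.tags[_TAG_GDAL_NODATA].value)
        values = page.asarray()
    return values, scale[0], origin, nodata


def read_raster(path, nodata: float | None = None) -> Raster:
    """Read a single-band, north-up GeoTIFF into a :class:`Raster`.

    The GridSpec is recovered from the geotransform tags; the nodata sentinel
    comes from the GDAL nodata tag unless overridden.
    """
    values, cell, origin, file_nodata = _read_page(path)
    grid = GridSpec(values.shape[0], values.shape[1], cell, origin[0], origin[1])
    nd = nodata if nodata is not None else (
        file_nodata if file_nodata is not None else FLOAT_NODATA)
    return Raster(grid, values.astype(float), nodata=nd)


def read_label_raster(path, legend: Mapping[int, str] | None = None,
                      nodata: int | None = None) -> LabelRaster:
    """Read an integer-coded GeoTIFF as a :class:`LabelRaster`."""
    values, cell, origin, file_nodata = _read_page(path)
    grid = GridSpec(values.shape[0], values.shape[1], cell, origin[0], origin[1])
    nd = nodata if nodata is not None else (
        int(file_nodata) if file_nodata is not None else LABEL_NODATA)
    return LabelRaster(grid, values.astype(np.int64), legend or {}, nodata=nd)


# ---------------------------------------------------------------------------
# Resampling and overlay
# ---------------------------------------------------------------------------

def resample_to_grid(source: Raster | LabelRaster, target: GridSpec,
                     method: str = "nearest") -> Raster | LabelRaster:
    """Resample ``source`` onto ``target`` (same CRS frame assumed).

    ``nearest`` samples the source at each target cell center (mandatory, and
    enforced, for :class:`LabelRaster`). ``mean``/``sum`` aggregate the source
    cells whose centers fall inside each target cell; ``sum`` conserves the
    global total of valid cells. Target cells receiving no source cell become
    nodata.
    """
    if method not in {"nearest", "mean", "sum"}:
        raise ConfigError(f"unknown resampling method {method!r}")
    is_labels = isinstance(source, LabelRaster)
    if is_labels and method != "nearest":
        raise ConfigError("LabelRaster must be resampled with method='nearest'")
    src_grid = source.grid
    data = source.labels if is_labels else source.values

    if method == "nearest":
        tx, ty = target.cell_centers()
        col = np.floor((tx - src_grid.origin_x) / src_grid.cell_size).astype(int)
        row = np.floor((src_grid.origin_y - ty) / src_grid.cell_size).astype(int)
        inside = ((row >= 0) & (row < src_grid.n_rows)
                  & (col >= 0) & (col < src_grid.n_cols))
        out = np.full(target.shape, source.nodata, dtype=data.dtype)
        out[inside] = data[row[inside], col[inside]]
        if is_labels:
            return LabelRaster(target, out, dict(source.legend), source.nodata)
        return Raster(target, out, source.nodata)

    # mean / sum: scatter source cell centers into target cells
    sx, sy = src_grid.cell_centers()
    tcol = np.floor((sx - target.origin_x) / target.cell_size).astype(int)
    trow = np.floor((target.origin_y - sy) / target.cell_size).astype(int)
    valid = (source.mask & (trow >= 0) & (trow < target.n_rows)
             & (tcol >= 0) & (tcol < target.n_cols))
    flat = trow[valid] * target.n_cols + tcol[valid]
    sums = np.bincount(flat, weights=data[valid].astype(float),
                       minlength=target.n_cells)
    counts = np.bincount(flat, minlength=target.n_cells)
    out = np.full(target.n_cells, float(source.nodata))
    hit = counts > 0
    if method == "sum":
        out[hit] = sums[hit]
    else:
        out[hit] = sums[hit] / counts[hit]
    return Raster(target, out.reshape(target.shape), float(source.nodata))


def hadamard_overlay(layers: Sequence[Raster], weights: Sequence[float]) -> Raster:
    """Cell-wise weighted combination sum_k w_k * L_k of aligned layers.

    Any layer's nodata cell makes the output cell nodata. This is the single
    overlay primitive used to homogenize multi-source layers onto one grid.
    """
    if len(layers) == 0:
        raise ConfigError("at least one layer required")
    if len(layers) != len(weights):
        raise ConfigError("weights must have the same length as layers")
    grid = layers[0].grid
    for lay in layers[1:]:
        if lay.grid != grid:
            raise AlignmentError("all layers must share one GridSpec")
    out = np.zeros(grid.shape)
    valid = np.ones(grid.shape, dtype=bool)
    for lay, w in zip(layers, weights):
        valid &= lay.mask
        out += w * np.where(lay.mask, lay.values, 0.0)
    nodata = layers[0].nodata
    out[~valid] = nodata
    return Raster(grid, out, nodata)
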