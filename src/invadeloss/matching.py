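"""Spatial matching: unify heterogeneous infestation records on one grid.

Two record types feed the per-cell severity coefficient:

* coarse presence-absence (PA) lists of infested administrative units,
  rasterized through host-preference weights on land use, and
* presence-only (PO) occurrence points, interpolated to a continuous
  surface by inverse-distance weighting (power-law, default 1/d^2).

The two layers are combined by a weighted overlay and clipped to [0, 1],
giving the severity coefficient raster used as treatment intensity and
driver-analysis outcome downstream.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, InputError
from .grid import GridSpec, LabelRaster, LandUseClass, Raster, hadamard_overlay

logger = logging.getLogger(__name__)


class OccurrencePoint(NamedTuple):
    """A georeferenced presence-only record (planar meters)."""

    x: float
    y: float
    year: int


def read_occurrences(path) -> list[OccurrencePoint]:
    """Load occurrence points from a CSV with columns x, y, year."""
    df = pd.read_csv(path)
    missing = {"x", "y", "year"} - set(df.columns)
    if missing:
        raise InputError(f"occurrence CSV missing columns {sorted(missing)}")
    return [OccurrencePoint(float(r.x), float(r.y), int(r.year))
            for r in df.itertuples()]


def filter_points_in_extent(points: Iterable[OccurrencePoint],
                            grid: GridSpec) -> list[OccurrencePoint]:
    """Drop points outside the grid extent, logging how many were lost."""
    pts = list(points)
    kept = [p for p in pts if grid.point_to_cell(p.x, p.y) is not None]
    n_drop = len(pts) - len(kept)
    if n_drop:
        logger.warning("dropped %d occurrence point(s) outside grid extent",
                       n_drop)
    return kept


class HostWeightTable(dict):
    """Mapping land-use class -> host-preference weight in [0, 1]."""

    def __init__(self, weights: Mapping[int, float]):
        for cls, w in weights.items():
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"host weight for class {cls} outside [0,1]")
        super().__init__({int(k): float(v) for k, v in weights.items()})


#: host preference of the fall webworm: broadleaf forest and cropland
DEFAULT_HOST_WEIGHTS = HostWeightTable({
    LandUseClass.ARABLE: 0.8,
    LandUseClass.BROADLEAF_FOREST: 1.0,
    LandUseClass.OTHER_FOREST: 0.4,
    LandUseClass.GRASSLAND: 0.2,
    LandUseClass.WATER: 0.0,
    LandUseClass.URBAN: 0.0,
    LandUseClass.BARE: 0.0,
})


def rasterize_presence_absence(admin: LabelRaster,
                               infested_units: Iterable[int],
                               land_use: LabelRaster,
                               host_weights: Mapping[int, float]) -> Raster:
    """Reclassify unit-level presence-absence onto host land-use weights.

    A cell gets ``host_weights[land_use]`` if its administrative unit is in
    ``infested_units`` and 0 otherwise, turning binary unit records into a
    biologically informed [0, 1] surface.
    """
    if admin.grid != land_use.grid:
        raise InputError("admin and land_use must share a grid")
    infested = {int(u) for u in infested_units}
    known = set(int(u) for u in np.unique(admin.labels[admin.mask]))
    unknown = infested - known
    if unknown:
        raise InputError(f"infested unit(s) not present in admin raster: "
                         f"{sorted(unknown)}")
    wmap = np.zeros(256)
    for cls, w in host_weights.items():
        wmap[int(cls)] = w
    out = np.where(np.isin(admin.labels, list(infested)) & land_use.mask,
                   wmap[np.clip(land_use.labels, 0, 255)], 0.0)
    nodata = -9999.0
    out[~(admin.mask & land_use.mask)] = nodata
    return Raster(admin.grid, out, nodata)


class IDWInterpolator(BaseEstimator):
    """Inverse-distance-weighted influence surface for point records.

    The raw influence at a cell center c is sum_p 1 / d(c, p)**power over all
    fitted points; cells that contain a point are assigned the maximum finite
    influence found elsewhere on the grid (the d -> 0 cap), and the surface
    is then min-max normalized to [0, 1].

    Parameters
    ----------
    power : float, default 2.0
        Distance-decay exponent (2 gives the 1/d^2 scheme).
    """

    def __init__(self, power: float = 2.0):
        self.power = power

    def fit(self, points: Sequence[OccurrencePoint], y=None):
        pts = list(points)
        if not pts:
            raise InputError("IDW requires at least one occurrence point")
        self.points_ = pts
        return self

    def _raw(self, grid: GridSpec) -> np.ndarray:
        xs = np.array([p.x for p in self.points_])
        ys = np.array([p.y for p in self.points_])
        cx, cy = grid.cell_centers()
        raw = np.zeros(grid.shape)
        contains = np.zeros(grid.shape, dtype=bool)
        # chunk over points to bound memory on large grids
        for i in range(0, len(xs), 256):
            dx = cx[..., None] - xs[i:i + 256]
            dy = cy[..., None] - ys[i:i + 256]
            d = np.hypot(dx, dy)
            with np.errstate(divide="ignore"):
                raw += np.where(d > 0, d ** -self.power, 0.0).sum(axis=-1)
        for p in self.points_:
            cell = grid.point_to_cell(p.x, p.y)
            if cell is not None:
                contains[cell] = True
        finite_elsewhere = raw[~contains]
        cap = finite_elsewhere.max() if finite_elsewhere.size else 1.0
        raw[contains] = np.maximum(raw[contains], cap)
        return raw

    def predict(self, grid: GridSpec) -> Raster:
        """Evaluate the normalized [0, 1] influence surface on a grid."""
        raw = self._raw(grid)
        lo, hi = raw.min(), raw.max()
        out = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
        return Raster(grid, out, nodata=-9999.0)


def idw_surface(points: Sequence[OccurrencePoint], grid: GridSpec,
                power: float = 2.0) -> Raster:
    """Inverse-distance influence surface, min-max normalized to [0, 1]."""
    return IDWInterpolator(power=power).fit(points).predict(grid)


def severity_overlay(pa: Raster, po: Raster,
                     weights: tuple[float, float] = (0.5, 0.5)) -> Raster:
    """Weighted overlay of the PA and PO layers, clipped to [0, 1].

    severity = clip(w_pa * pa + w_po * po, 0, 1). The default equal weights
    treat both record sources as equally informative.
    """
    if weights[0] < 0 or weights[1] < 0:
        raise ConfigError("overlay weights must be non-negative")
    combined = hadamard_overlay([pa, po], list(weights))
    out = combined.values.copy()
    valid = combined.mask
    out[valid] = np.clip(out[valid], 0.0, 1.0)
    return Raster(combined.grid, out, combined.nodata)


def count_severity_grids(severity: Raster, threshold: float = 0.75):
    """Count cells with severity strictly above ``threshold``.

    Returns (n_cells, area_ha), area in hectares from the grid's cell size.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError("threshold must lie in [0, 1]")
    n = int(np.sum(severity.valid_values() > threshold))
    return n, n * severity.grid.cell_area_ha
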