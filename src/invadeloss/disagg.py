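"""Dasymetric disaggregation of district sectoral output onto grid cells.

District/county gross primary-industry outputs (cultivation, forestry,
animal husbandry, fishery; stored in ten-thousand CNY) are distributed onto
cells in proportion to sector-linked land-use allocation weights: cultivation
draws from arable land, forestry from forest cover, husbandry from grassland
and fishery from water bodies. Urban and bare cells are excluded through
zero-weight masking. Allocation weights are provincial output intensities
(output per unit area on the linked class), which preserves production
intensity gradients instead of spreading value uniformly per pixel.

The transform conserves mass exactly: summing the disaggregated cells of a
unit reproduces its table value (``validate_reconstruction`` checks this).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DerivationError, InputError
from .grid import (
    NON_PRODUCTIVE_CLASSES,
    LabelRaster,
    LandUseClass,
    Raster,
)

logger = logging.getLogger(__name__)

SECTORS = ("cultivation", "forestry", "husbandry", "fishery")

#: strict sector -> land-use linkage; no cross-sector leakage
SECTOR_CLASSES: dict[str, tuple[LandUseClass, ...]] = {
    "cultivation": (LandUseClass.ARABLE,),
    "forestry": (LandUseClass.BROADLEAF_FOREST, LandUseClass.OTHER_FOREST),
    "husbandry": (LandUseClass.GRASSLAND,),
    "fishery": (LandUseClass.WATER,),
}


def validate_sector_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a (unit, year, sector, value) table's integrity contracts."""
    required = {"unit", "year", "sector", "value"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"sector table missing columns {sorted(missing)}")
    if table.duplicated(["unit", "year", "sector"]).any():
        raise InputError("duplicate (unit, year, sector) rows in sector table")
    if (table["value"] < 0).any():
        raise InputError("sector outputs must be non-negative")
    return table


def derive_allocation_weights(
        provincial_outputs: Mapping[str, float],
        provincial_areas: Mapping[int, float]) -> dict[str, dict[int, float]]:
    """Derive sector->class allocation weights from provincial aggregates.

    weight(sector, class) is the provincial output intensity of the sector on
    its linked class(es): sector output divided by the total linked-class
    area. Non-productive classes (urban, bare) are forced to exactly 0.
    """
    weights: dict[str, dict[int, float]] = {}
    for sector in SECTORS:
        out = float(provincial_outputs.get(sector, 0.0))
        linked = SECTOR_CLASSES[sector]
        area = sum(float(provincial_areas.get(int(c), 0.0)) for c in linked)
        row = {int(c): 0.0 for c in LandUseClass}
        if out > 0:
            if area <= 0:
                raise DerivationError(
                    f"sector {sector!r} has output {out} but zero linked area")
            for c in linked:
                row[int(c)] = out / area
        for c in NON_PRODUCTIVE_CLASSES:
            row[int(c)] = 0.0
        weights[sector] = row
    return weights


class DasymetricAllocator(BaseEstimator):
    """Distribute unit totals onto cells by land-use allocation weights.

    ``fit`` precomputes, for every (unit, sector), each cell's share
    weight(sector, class(cell)) / sum of weights over the unit's cells;
    ``transform`` multiplies a sector-output table through those shares.

    Parameters
    ----------
    weights : mapping sector -> {land-use class -> weight >= 0}
    nodata : float
        Sentinel written to cells outside a unit or in units with zero
        allocation mass for the sector.
    """

    def __init__(self, weights: Mapping[str, Mapping[int, float]],
                 nodata: float = -9999.0):
        self.weights = weights
        self.nodata = nodata

    def fit(self, admin: LabelRaster, land_use: LabelRaster):
        if admin.grid != land_use.grid:
            raise InputError("admin and land_use must share a grid")
        self.admin_ = admin
        self.land_use_ = land_use
        self.units_ = [int(u) for u in np.unique(admin.labels[admin.mask])]
        # per-sector cell weight field and per-unit weight totals
        self.cell_weights_ = {}
        self.unit_mass_ = {}
        for sector, wrow in self.weights.items():
            wmap = np.zeros(256)
            for cls, w in wrow.items():
                if w < 0:
                    raise InputError("allocation weights must be >= 0")
                wmap[int(cls)] = w
            field = np.where(land_use.mask,
                             wmap[np.clip(land_use.labels, 0, 255)], 0.0)
            self.cell_weights_[sector] = field
            self.unit_mass_[sector] = {
                u: float(field[admin.labels == u].sum()) for u in self.units_}
        return self

    def transform(self, table: pd.DataFrame) -> dict[str, dict[int, Raster]]:
        """Disaggregate a (unit, year, sector, value) table.

        Returns ``{sector: {year: Raster}}``. Units whose allocation mass for
        a sector is zero keep nodata cells and trigger a warning.
        """
        validate_sector_table(table)
        unknown = set(table["unit"]) - set(self.units_)
        if unknown:
            raise InputError(f"table unit(s) absent from admin raster: "
                             f"{sorted(unknown)}")
        admin = self.admin_
        out: dict[str, dict[int, Raster]] = {}
        for (sector, year), grp in table.groupby(["sector", "year"]):
            field = self.cell_weights_[sector]
            values = np.full(admin.grid.shape, self.nodata)
            for row in grp.itertuples():
                unit_mask = admin.labels == row.unit
                mass = self.unit_mass_[sector][int(row.unit)]
                if mass <= 0:
                    if row.value > 0:
                        logger.warning(
                            "unit %s has zero %s allocation mass; %s output "
                            "left unallocated", row.unit, sector, row.value)
                    continue
                values[unit_mask] = row.value * field[unit_mask] / mass
            out.setdefault(sector, {})[int(year)] = Raster(
                admin.grid, values, self.nodata)
        return out


def disaggregate_outputs(table: pd.DataFrame, admin: LabelRaster,
                         land_use: LabelRaster,
                         weights: Mapping[str, Mapping[int, float]]
                         ) -> dict[str, dict[int, Raster]]:
    """One-shot dasymetric disaggregation; see :class:`DasymetricAllocator`."""
    return DasymetricAllocator(weights).fit(admin, land_use).transform(table)


def validate_reconstruction(cell_rasters: Mapping[str, Mapping[int, Raster]],
                            table: pd.DataFrame,
                            admin: LabelRaster) -> pd.DataFrame:
    """Absolute percentage error of unit totals rebuilt from cells.

    For each (unit, year, sector) present in the table, the disaggregated
    cells of the unit are summed and compared with the table value:
    ape = |sum - value| / value. A zero table value with nonzero cells is
    reported as infinite error. Returns a DataFrame with columns unit, year,
    sector, reconstructed, value, ape; the ``.attrs`` carry max/mean ape.
    """
    validate_sector_table(table)
    rows = []
    for rec in table.itertuples():
        sector_years = cell_rasters.get(rec.sector, {})
        raster = sector_years.get(int(rec.year))
        if raster is None:
            continue
        unit_mask = (admin.labels == rec.unit) & raster.mask
        total = float(raster.values[unit_mask].sum())
        if rec.value > 0:
            ape = abs(total - rec.value) / rec.value
        else:
            ape = 0.0 if total == 0 else float("inf")
        rows.append((rec.unit, int(rec.year), rec.sector, total,
                     float(rec.value), ape))
    report = pd.DataFrame(rows, columns=["unit", "year", "sector",
                                         "reconstructed", "value", "ape"])
    if len(report):
        report.attrs["max_ape"] = float(report["ape"].max())
        report.attrs["mean_ape"] = float(report["ape"].mean())
    return report
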