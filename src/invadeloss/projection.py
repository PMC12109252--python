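"""Potential-loss projection from habitat suitability and DID coefficients.

A habitat-suitability raster (any [0,1] surface from an upstream species
distribution model) is classified into unsuitable / low / medium-high / high
zones; the projection then assumes a full outbreak over the medium-high and
high zones and multiplies each sector's per-cell loss coefficient |beta|
(from the DID fit) by the count of eligible cells whose land use is linked
to that sector, times an optional area-scaling constant that converts
between the coefficient's reference area and the grid's cell area.

95% bounds propagate beta +/- 1.96 SE through the same linear map (delta
method), so the interval width is exactly 2 * 1.96 * SE * cells * scaling.
Sectors whose coefficient is not significant at the 5% level are excluded by
default (a pest that measurably harms forestry need not harm fisheries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .did import DIDFit
from .disagg import SECTOR_CLASSES
from .grid import LabelRaster, Raster

SUITABILITY_CLASSES = {0: "unsuitable", 1: "low", 2: "medium_high", 3: "high"}
DEFAULT_THRESHOLDS = (0.25, 0.5, 0.75)


@dataclass
class SuitabilityClassMap:
    """Classified suitability zones plus the thresholds that made them."""

    classes: LabelRaster
    thresholds: tuple[float, float, float]


@dataclass
class LossProjection:
    """Sectoral potential-loss point estimates with 95% intervals."""

    sectors: pd.DataFrame           # sector, point, lower95, upper95, cells
    total: float
    total_lower95: float
    total_upper95: float
    scenario: str = ""
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    area_scaling: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        df = self.sectors.copy()
        df.insert(0, "scenario", self.scenario)
        total = pd.DataFrame([{
            "scenario": self.scenario, "sector": "total",
            "point": self.total, "lower95": self.total_lower95,
            "upper95": self.total_upper95,
            "cells": int(df["cells"].sum())}])
        return pd.concat([df, total], ignore_index=True)


def classify_suitability(suitability: Raster,
                         thresholds: tuple[float, float, float]
                         = DEFAULT_THRESHOLDS) -> SuitabilityClassMap:
    """Partition [0,1] suitability into four zones by half-open intervals.

    [0, t1) unsuitable, [t1, t2) low, [t2, t3) medium-high, [t3, 1] high.
    """
    t1, t2, t3 = thresholds
    if not 0.0 < t1 < t2 < t3 < 1.0:
        raise ConfigError("thresholds must satisfy 0 < t1 < t2 < t3 < 1")
    vals = suitability.valid_values()
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise InputError("suitability values must lie in [0, 1]")
    classes = np.digitize(suitability.values, thresholds).astype(np.int64)
    nodata = 255
    classes[~suitability.mask] = nodata
    labels = LabelRaster(suitability.grid, classes,
                         dict(SUITABILITY_CLASSES), nodata=nodata)
    return SuitabilityClassMap(labels, tuple(thresholds))


def project_losses(classes: SuitabilityClassMap, land_use: LabelRaster,
                   fits: Mapping[str, DIDFit], area_scaling: float = 1.0,
                   alpha: float = 0.05, scenario: str = "",
                   include_nonsignificant: bool = False) -> LossProjection:
    """Project full-outbreak sectoral losses over suitable zones.

    For each included sector:
        point  = |beta| * area_scaling * n_eligible_cells
        bounds = |beta| -/+ 1.96 * SE, through the same map

    where eligible cells are medium-high/high-suitability cells whose
    land-use class is linked to the sector. Sectors with p >= alpha are
    skipped unless ``include_nonsignificant``.
    """
    if classes.classes.grid != land_use.grid:
        raise InputError("suitability classes and land use must share a grid")
    if area_scaling <= 0:
        raise ConfigError("area_scaling must be positive")
    eligible_zone = np.isin(classes.classes.labels, (2, 3))
    rows = []
    var_total = 0.0
    for sector, fit in fits.items():
        if fit is None:
            raise InputError(f"missing DID fit for sector {sector!r}")
        if not include_nonsignificant and fit.pvalue >= alpha:
            continue
        linked = [int(c) for c in SECTOR_CLASSES[sector]]
        cells = int(np.sum(eligible_zone & np.isin(land_use.labels, linked)
                           & land_use.mask))
        scale = area_scaling * cells
        point = abs(fit.beta) * scale
        half = 1.96 * fit.se * scale
        rows.append({"sector": sector, "point": point,
                     "lower95": point - half, "upper95": point + half,
                     "cells": cells})
        var_total += half ** 2
    sectors = pd.DataFrame(rows, columns=["sector", "point", "lower95",
                                          "upper95", "cells"])
    total = float(sectors["point"].sum()) if len(sectors) else 0.0
    # total interval: sector half-widths combined in quadrature
    # (independent coefficient estimates)
    half_total = float(np.sqrt(var_total))
    return LossProjection(sectors, total, total - half_total,
                          total + half_total, scenario=scenario,
                          thresholds=classes.thresholds,
                          area_scaling=area_scaling)
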