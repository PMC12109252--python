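"""Synthetic study-system generator with known ground truth.

Emulates the data a provincial invasion study would assemble — a categorical
landscape, contiguous administrative districts, a pest wavefront spreading
from a point of entry faster along transport corridors, presence-only
occurrence points, driver rasters, a habitat-suitability surface, and a
district x year x sector economic panel whose treatment effects, fixed
effects and noise level are planted and recorded — so that every downstream
stage (severity mapping, disaggregation, driver detection, staggered DID,
loss projection) can be tested against a known answer.

Default scenario conditions mirror the study system: 1-km cells, a landscape
of 45% arable / 32% forest with the remainder split among grassland, water,
urban and bare land, invasion years 2011-2022 with staggered district
infestation, per-cell sectoral treatment effects equal to the reported DID
coefficients (forestry -0.163, cultivation -0.021, husbandry +0.005,
fishery -0.034 output units per cell-year), and Gaussian panel noise with
s.d. 0.5.

All randomness flows from one master seed; each generator draws from its own
child stream so stages can be re-run independently and still reproduce.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .errors import ConfigError
from .grid import (
    LAND_USE_LEGEND,
    GridSpec,
    LabelRaster,
    LandUseClass,
    Raster,
)

#: land-cover composition of the emulated province (shares sum to 1)
DEFAULT_LAND_SHARES: dict[LandUseClass, float] = {
    LandUseClass.ARABLE: 0.45,
    LandUseClass.BROADLEAF_FOREST: 0.20,
    LandUseClass.OTHER_FOREST: 0.12,
    LandUseClass.GRASSLAND: 0.08,
    LandUseClass.WATER: 0.07,
    LandUseClass.URBAN: 0.06,
    LandUseClass.BARE: 0.02,
}

#: per-cell annual treatment effects planted in the panel (output units)
DEFAULT_BETA_TRUE: dict[str, float] = {
    "cultivation": -0.021,
    "forestry": -0.163,
    "husbandry": 0.005,
    "fishery": -0.034,
}

#: sectoral baseline output levels (ten-thousand CNY per district-year)
DEFAULT_ALPHA: dict[str, float] = {
    "cultivation": 60.0,
    "forestry": 25.0,
    "husbandry": 18.0,
    "fishery": 12.0,
}


@dataclass
class ScenarioConfig:
    """Full parameterization of one synthetic invasion scenario."""

    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(100, 100, 1000.0))
    n_units: int = 50
    years: tuple[int, int] = (2011, 2022)
    beta_true: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_TRUE))
    sigma_noise: float = 0.5
    spread_origin: tuple[int, int] = (10, 10)
    spread_rate: float = 3.0            # cells / year off-corridor
    corridor_strength: float = 3.0      # speed multiplier on road corridors
    host_classes: tuple[LandUseClass, ...] = (
        LandUseClass.ARABLE, LandUseClass.BROADLEAF_FOREST)
    land_shares: Mapping[LandUseClass, float] = field(
        default_factory=lambda: dict(DEFAULT_LAND_SHARES))
    occurrences_per_year: int = 60
    fe_unit_sd: float = 5.0             # s.d. of planted district effects
    fe_year_sd: float = 2.0             # s.d. of planted year effects
    theta_true: float = 1.5             # planted control-covariate coefficient

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ConfigError("need at least 2 administrative units")
        if self.n_units > self.grid.n_cells:
            raise ConfigError("more units than grid cells")
        if self.years[1] < self.years[0]:
            raise ConfigError("year range is reversed")
        if self.sigma_noise < 0 or self.corridor_strength < 0:
            raise ConfigError("noise s.d. and corridor strength must be >= 0")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def rng(self, stage: str) -> np.random.Generator:
        """Child generator for a named stage, derived from the master seed."""
        key = zlib.crc32(stage.encode("utf-8"))  # stable across processes
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class SpreadSchedule:
    """First infestation year per unit (None = never infested)."""

    first_infestation_year: dict[int, int | None]

    def infested_by(self, year: int) -> set[int]:
        return {u for u, y in self.first_infestation_year.items()
                if y is not None and y <= year}

    def never_treated(self) -> set[int]:
        return {u for u, y in self.first_infestation_year.items() if y is None}


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to mean 0 / s.d. 1."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / f.std()


def generate_landscape(config: ScenarioConfig):
    """Generate (land_use, admin, drivers) on the configured grid.

    Land cover is carved out of a spatially autocorrelated field by rank
    thresholds, so realized class shares match the configured proportions to
    within one cell. Administrative units are the Voronoi regions of
    ``n_units`` random seed cells (convex, hence contiguous). Drivers include
    a corridor-shaped road-density field passing through the spread origin, a
    smooth population-density field, and smooth rainfall/slope/altitude/
    nightlight/wind/waterway/built-environment surfaces.

    Returns
    -------
    land_use : LabelRaster
    admin : LabelRaster
    drivers : dict[str, Raster]
    """
    g = config.grid
    shares = dict(config.land_shares)
    total = sum(shares.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ConfigError(f"land shares sum to {total}, expected 1")

    rng = config.rng("landscape")

    # --- land use by rank-thresholding a correlated field -------------------
    base = _smooth_field(rng, g.shape, sigma=max(2.0, min(g.shape) / 20))
    order = np.argsort(base, axis=None, kind="stable")
    labels = np.empty(g.n_cells, dtype=np.int64)
    start = 0
    classes = list(shares)
    for i, cls in enumerate(classes):
        count = (round(sum(shares[c] for c in classes[: i + 1]) * g.n_cells)
                 - start)
        labels[order[start:start + count]] = int(cls)
        start += count
    labels[order[start:]] = int(classes[-1])
    land_use = LabelRaster(g, labels.reshape(g.shape), dict(LAND_USE_LEGEND))

    # --- admin units: Voronoi of random distinct seed cells -----------------
    seed_cells = rng.choice(g.n_cells, size=config.n_units, replace=False)
    srow, scol = np.divmod(seed_cells, g.n_cols)
    rows, cols = np.indices(g.shape)
    d2 = ((rows[..., None] - srow) ** 2 + (cols[..., None] - scol) ** 2)
    admin_labels = np.argmin(d2, axis=-1).astype(np.int64) + 1  # units 1..n
    admin = LabelRaster(g, admin_labels,
                        {i + 1: f"unit_{i + 1}" for i in range(config.n_units)})

    # --- drivers ------------------------------------------------------------
    r0, c0 = config.spread_origin
    rows_f, cols_f = rows.astype(float), cols.astype(float)
    # corridor: line through the origin toward the opposite corner
    dr, dc = (g.n_rows - 1 - r0, g.n_cols - 1 - c0)
    norm = math.hypot(dr, dc) or 1.0
    # perpendicular distance (in cells) to the corridor line
    perp = np.abs((rows_f - r0) * (dc / norm) - (cols_f - c0) * (dr / norm))
    road = np.exp(-0.5 * (perp / (min(g.shape) / 12)) ** 2)
    road = np.clip(road + 0.15 * _smooth_field(rng, g.shape, 3.0), 0, None)
    road /= road.max()

    pop = np.exp(0.8 * _smooth_field(rng, g.shape, max(3.0, min(g.shape) / 15)))
    pop = pop / pop.max()

    def smooth01(sigma):
        f = _smooth_field(rng, g.shape, sigma)
        return (f - f.min()) / (f.max() - f.min())

    gradient = (rows_f / max(g.n_rows - 1, 1))
    drivers = {
        "road_density": Raster(g, road),
        "population_density": Raster(g, pop),
        "nighttime_lights": Raster(g, np.clip(
            0.7 * pop + 0.3 * smooth01(4.0), 0, 1)),
        "rainfall": Raster(g, 0.6 * gradient + 0.4 * smooth01(6.0)),
        "slope": Raster(g, smooth01(2.0)),
        "altitude": Raster(g, smooth01(8.0)),
        "wind": Raster(g, smooth01(10.0)),
        "waterways": Raster(g, (land_use.labels == LandUseClass.WATER)
                            .astype(float)),
        "built_environment": Raster(g, (land_use.labels == LandUseClass.URBAN)
                                    .astype(float)),
    }
    return land_use, admin, drivers


def simulate_spread(config: ScenarioConfig, land_use: LabelRaster,
                    admin: LabelRaster, drivers: Mapping[str, Raster]):
    """Deterministic wavefront spread plus severity and occurrence sampling.

    The front travels at ``spread_rate * (1 + corridor_strength * road)``
    cells per year; cell arrival times are geodesic travel times from
    ``spread_origin`` (minimum-cost paths with diagonal moves weighted by
    their geometric length). Severity at year t is a logistic ramp in years
    since arrival, so it crosses 0.5 half a year after the front passes. A
    unit's first infestation year is the first year any of its cells exceeds
    severity 0.5. Occurrence points are sampled cell-wise with probability
    proportional to severity and jittered uniformly within the cell.

    Returns (schedule, severity_by_year, occurrences) where occurrences is a
    DataFrame with columns x, y, year.
    """
    g = config.grid
    road = drivers["road_density"].values
    speed = config.spread_rate * (1.0 + config.corridor_strength * road)
    with np.errstate(divide="ignore"):
        cost = np.where(speed > 0, 1.0 / speed, np.inf)  # years per cell step

    if np.isfinite(cost).any() and config.spread_rate > 0:
        mcp = MCP_Geometric(cost)
        arrival, _ = mcp.find_costs([config.spread_origin])
    else:
        arrival = np.full(g.shape, np.inf)
        arrival[config.spread_origin] = 0.0

    y0, y1 = config.years
    steepness = 1.5
    severity_by_year: dict[int, Raster] = {}
    occ_rng = config.rng("occurrences")
    records = []
    first_year: dict[int, int | None] = {
        int(u): None for u in np.unique(admin.labels[admin.mask])}
    for year in config.year_list:
        t = year - y0
        with np.errstate(over="ignore"):
            sev = 1.0 / (1.0 + np.exp(-steepness * (t - arrival - 0.5)))
        sev = np.clip(np.where(np.isfinite(arrival), sev, 0.0), 0.0, 1.0)
        severity_by_year[year] = Raster(g, sev)
        # schedule: first year any cell of the unit exceeds 0.5
        hot = sev > 0.5
        for u in np.unique(admin.labels[hot & admin.mask]):
            u = int(u)
            if first_year[u] is None:
                first_year[u] = year
        # occurrences ~ severity
        total = sev.sum()
        if total > 0 and config.occurrences_per_year > 0:
            p = (sev / total).ravel()
            cells = occ_rng.choice(g.n_cells, size=config.occurrences_per_year,
                                   p=p)
            rr, cc = np.divmod(cells, g.n_cols)
            jit = occ_rng.uniform(0, 1, size=(2, len(cells)))
            x = g.origin_x + (cc + jit[0]) * g.cell_size
            y = g.origin_y - (rr + jit[1]) * g.cell_size
            for xi, yi in zip(x, y):
                records.append((xi, yi, year))
    occurrences = pd.DataFrame(records, columns=["x", "y", "year"])
    return SpreadSchedule(first_year), severity_by_year, occurrences


def generate_panel(config: ScenarioConfig, schedule: SpreadSchedule,
                   admin: LabelRaster, land_use: LabelRaster):
    """Build the district x year x sector economic panel with planted truth.

    For each unit i, year t and sector s:

        Y = alpha_s + mu_i + gamma_t + theta * W_it
            + beta_s * host_cells_i * D_it + eps,   eps ~ N(0, sigma_noise)

    where D_it = 1 from the unit's first infestation year onward (absorbing)
    and host_cells_i counts the unit's cells in the configured host classes
    (the treated-cell exposure that converts the per-cell beta into a
    district-level effect).

    Returns (panel, truth): panel is a DataFrame with columns unit, year,
    sector, y, D, exposure, w_climate; truth is a dict holding the planted
    beta, theta, alpha, mu (per unit) and gamma (per year).
    """
    units = sorted(int(u) for u in np.unique(admin.labels[admin.mask]))
    missing = [u for u in units if u not in schedule.first_infestation_year]
    if missing:
        raise ConfigError(f"schedule missing units {missing}")
    rng = config.rng("panel")

    host = np.isin(land_use.labels, [int(c) for c in config.host_classes])
    exposure = {u: int(np.sum(host & (admin.labels == u))) for u in units}

    mu = {u: float(m) for u, m in
          zip(units, config.fe_unit_sd * rng.standard_normal(len(units)))}
    years = config.year_list
    gamma = {t: float(gm) for t, gm in
             zip(years, config.fe_year_sd * rng.standard_normal(len(years)))}
    # center planted effects so they are identified relative to the intercept
    mu_bar = float(np.mean(list(mu.values())))
    gamma_bar = float(np.mean(list(gamma.values())))
    mu = {u: m - mu_bar for u, m in mu.items()}
    gamma = {t: gm - gamma_bar for t, gm in gamma.items()}

    w = rng.standard_normal((len(units), len(years)))
    sectors = list(config.beta_true)
    rows = []
    for ui, u in enumerate(units):
        fy = schedule.first_infestation_year[u]
        for ti, t in enumerate(years):
            d = int(fy is not None and t >= fy)
            for s in sectors:
                eps = float(rng.normal(0.0, config.sigma_noise)) \
                    if config.sigma_noise > 0 else 0.0
                y = (DEFAULT_ALPHA.get(s, 10.0) + mu[u] + gamma[t]
                     + config.theta_true * w[ui, ti]
                     + config.beta_true[s] * exposure[u] * d + eps)
                rows.append((u, t, s, y, d, exposure[u], w[ui, ti]))
    panel = pd.DataFrame(
        rows, columns=["unit", "year", "sector", "y", "D", "exposure",
                       "w_climate"])
    truth = {
        "beta": dict(config.beta_true),
        "theta": config.theta_true,
        "alpha": {s: DEFAULT_ALPHA.get(s, 10.0) for s in sectors},
        "mu": mu,
        "gamma": gamma,
        "exposure": exposure,
        "sigma_noise": config.sigma_noise,
    }
    return panel, truth


def generate_suitability(config: ScenarioConfig,
                         drivers: Mapping[str, Raster],
                         land_use: LabelRaster) -> Raster:
    """Smooth habitat-suitability surface in [0, 1].

    Suitability follows smoothed host land-use density (the pest needs host
    plants) modulated by a mild random field; a landscape with no host cells
    is entirely unsuitable.
    """
    g = config.grid
    host = np.isin(land_use.labels, [int(c) for c in config.host_classes])
    dens = ndimage.gaussian_filter(host.astype(float), sigma=3.0)
    if dens.max() <= 0:
        return Raster(g, np.zeros(g.shape))
    dens = dens / dens.max()
    rng = config.rng("suitability")
    mod = _smooth_field(rng, g.shape, 5.0)
    mod = (mod - mod.min()) / (mod.max() - mod.min())
    return Raster(g, np.clip(dens * (0.7 + 0.3 * mod), 0.0, 1.0))


def staggered_schedule(config: ScenarioConfig,
                       rng: np.random.Generator | None = None,
                       frac_never: float = 0.25) -> SpreadSchedule:
    """Draw a staggered adoption schedule directly, without the wavefront.

    Used for panel-recovery experiments where only the treatment timing
    matters: a ``frac_never`` share of units stays never-infested (controls),
    the rest receive a first infestation year uniform over the interior of
    the study window.
    """
    rng = rng if rng is not None else config.rng("schedule")
    y0, y1 = config.years
    units = list(range(1, config.n_units + 1))
    n_never = max(1, int(round(frac_never * len(units))))
    never = set(rng.choice(units, size=n_never, replace=False).tolist())
    sched: dict[int, int | None] = {}
    for u in units:
        sched[u] = None if u in never else int(rng.integers(y0 + 1, y1 + 1))
    return SpreadSchedule(sched)
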