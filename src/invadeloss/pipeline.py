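"""End-to-end orchestration: simulate -> spatialize -> disaggregate ->
geodetect -> did -> project, driven by one TOML config and one master seed.

Each stage reads and writes only files under the run directory, so stages
can be re-run individually. A manifest (JSON) echoes every effective
parameter, the seed and the package version, making runs replayable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .disagg import (
    DasymetricAllocator,
    derive_allocation_weights,
    validate_reconstruction,
)
from .did import annual_losses, counterfactual_outputs, fit_by_sector
from .errors import ConfigError
from .geodetector import GeoDetector
from .grid import GridSpec, LandUseClass, write_raster
from .matching import (
    DEFAULT_HOST_WEIGHTS,
    OccurrencePoint,
    count_severity_grids,
    idw_surface,
    rasterize_presence_absence,
    severity_overlay,
)
from .projection import classify_suitability, project_losses
from .spatial_stats import SpatialWeights, morans_i
from .synth import (
    ScenarioConfig,
    SpreadSchedule,
    generate_landscape,
    generate_panel,
    generate_suitability,
    simulate_spread,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "spatialize", "disaggregate", "geodetect", "did",
          "project")


@dataclass
class PipelineConfig:
    """Every tunable of an end-to-end run, with replayable defaults."""

    seed: int = 0
    grid_rows: int = 100
    grid_cols: int = 100
    cell_size: float = 1000.0
    n_units: int = 50
    years: tuple[int, int] = (2011, 2022)
    host_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_HOST_WEIGHTS))
    overlay_weights: tuple[float, float] = (0.5, 0.5)
    idw_power: float = 2.0
    severity_threshold: float = 0.75
    n_classes: int = 5
    discretization: str = "quantile"
    cov_type: str = "cluster"
    suitability_thresholds: tuple[float, float, float] = (0.25, 0.5, 0.75)
    area_scaling: float = 1.0
    deflator: Mapping[int, float] | None = None
    stages: tuple[str, ...] = STAGES
    scenario_label: str = "synthetic-baseline"

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {}
        for key, value in raw.items():
            if not hasattr(cls, key) and key not in cls.__dataclass_fields__:
                raise ConfigError(f"unknown config key {key!r}")
            if key in ("years", "overlay_weights", "suitability_thresholds",
                       "stages"):
                value = tuple(value)
            if key in ("host_weights", "deflator"):
                value = {int(k): float(v) for k, v in value.items()}
            kwargs[key] = value
        return cls(**kwargs)

    def scenario(self) -> ScenarioConfig:
        return ScenarioConfig(
            seed=self.seed,
            grid=GridSpec(self.grid_rows, self.grid_cols, self.cell_size),
            n_units=self.n_units,
            years=tuple(self.years),
        )

    def to_manifest(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Mapping):
                v = {str(kk): vv for kk, vv in v.items()}
            elif isinstance(v, tuple):
                v = list(v)
            out[k] = v
        return out


def _toml_escape(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    return '"' + str(value).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_flat_toml(path, data: Mapping) -> None:
    """Minimal TOML emitter for flat/1-level-nested mappings of scalars."""
    lines = []
    tables = []
    for key, value in data.items():
        if isinstance(value, Mapping):
            tables.append((key, value))
        elif isinstance(value, (list, tuple)):
            lines.append(f"{key} = [{', '.join(_toml_escape(v) for v in value)}]")
        else:
            lines.append(f"{key} = {_toml_escape(value)}")
    for key, table in tables:
        lines.append("")
        lines.append(f"[{key}]")
        for k, v in table.items():
            lines.append(f'"{k}" = {_toml_escape(v)}')
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages, writing all artifacts under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    scen = config.scenario()

    # ---- simulate ---------------------------------------------------------
    land_use, admin, drivers = generate_landscape(scen)
    schedule, severity_by_year, occurrences = simulate_spread(
        scen, land_use, admin, drivers)
    panel, truth = generate_panel(scen, schedule, admin, land_use)
    suitability = generate_suitability(scen, drivers, land_use)
    if "simulate" in stages:
        write_raster(out / "land_use.tif", land_use)
        write_raster(out / "admin.tif", admin)
        for name, r in drivers.items():
            write_raster(out / f"driver_{name}.tif", r)
        write_raster(out / "suitability.tif", suitability)
        _write_csv(occurrences, out / "occurrences.csv")
        sched_df = pd.DataFrame(
            sorted((u, "" if y is None else y)
                   for u, y in schedule.first_infestation_year.items()),
            columns=["unit", "first_year"])
        _write_csv(sched_df, out / "schedule.csv")
        _write_csv(panel, out / "panel.csv")
        write_flat_toml(out / "ground_truth.toml", {
            "sigma_noise": truth["sigma_noise"],
            "theta": truth["theta"],
            "beta": truth["beta"],
            "alpha": truth["alpha"],
            "mu": {str(k): v for k, v in truth["mu"].items()},
            "gamma": {str(k): v for k, v in truth["gamma"].items()},
            "exposure": {str(k): v for k, v in truth["exposure"].items()},
        })

    # ---- spatialize -------------------------------------------------------
    severity_final = None
    if "spatialize" in stages:
        counts = []
        for year in scen.year_list:
            infested = schedule.infested_by(year)
            pa = rasterize_presence_absence(
                admin, infested, land_use, config.host_weights)
            pts = [OccurrencePoint(r.x, r.y, int(r.year))
                   for r in occurrences[occurrences["year"] == year]
                   .itertuples()]
            if pts:
                po = idw_surface(pts, scen.grid, power=config.idw_power)
                severity = severity_overlay(pa, po, config.overlay_weights)
            else:
                severity = severity_overlay(pa, pa, (config.overlay_weights[0],
                                                     0.0))
            write_raster(out / f"severity_{year}.tif", severity)
            n, ha = count_severity_grids(severity, config.severity_threshold)
            try:
                mi = morans_i(severity, SpatialWeights("queen"))
            except Exception:
                mi = float("nan")
            counts.append((year, len(infested), n, ha, mi))
            severity_final = severity
        _write_csv(pd.DataFrame(
            counts, columns=["year", "infested_units", "severe_cells",
                             "severe_area_ha", "morans_i"]),
            out / "severity_summary.csv")

    # ---- disaggregate -----------------------------------------------------
    sector_table = panel.rename(columns={"y": "value"})[
        ["unit", "year", "sector", "value"]].copy()
    sector_table["value"] = sector_table["value"].clip(lower=0.0)
    class_areas = {int(c): float(np.sum(land_use.labels == int(c)))
                   for c in LandUseClass}
    provincial = sector_table.groupby("sector")["value"].sum().to_dict()
    weights = derive_allocation_weights(provincial, class_areas)
    if "disaggregate" in stages:
        allocator = DasymetricAllocator(weights).fit(admin, land_use)
        rasters = allocator.transform(sector_table)
        last = max(scen.year_list)
        for sector, by_year in rasters.items():
            write_raster(out / f"output_{sector}_{last}.tif", by_year[last])
        report = validate_reconstruction(rasters, sector_table, admin)
        _write_csv(report, out / "reconstruction_check.csv")

    # ---- geodetect (diagnostic; not on the critical path) ------------------
    if "geodetect" in stages:
        outcome_year = max(scen.year_list)
        totals = (sector_table[sector_table["year"] == outcome_year]
                  .groupby("unit")["value"].sum())
        outcome_vals = totals.reindex(
            admin.labels.ravel()).to_numpy().reshape(admin.grid.shape)
        from .grid import Raster
        outcome = Raster(admin.grid, outcome_vals)
        factors = dict(drivers)
        if severity_final is not None:
            factors["infestation"] = severity_final
        det = GeoDetector(n_classes=config.n_classes,
                          method=config.discretization).fit(factors, outcome)
        q_df = pd.DataFrame({"factor": det.q_.index, "q": det.q_.values})
        _write_csv(q_df, out / "geodetector_q.csv")
        _write_csv(det.interactions_, out / "geodetector_interactions.csv")

    # ---- did --------------------------------------------------------------
    fits = None
    if "did" in stages or "project" in stages:
        fits = fit_by_sector(panel, controls=("w_climate",),
                             exposure_col="exposure",
                             cov_type=config.cov_type)
    if "did" in stages:
        report = pd.DataFrame([
            {"sector": s, **f.summary_row()} for s, f in fits.items()])
        _write_csv(report, out / "did_coefficients.csv")
        losses = []
        for s, f in fits.items():
            cf = counterfactual_outputs(f, panel[panel["sector"] == s],
                                        exposure_col="exposure")
            losses.append(annual_losses(cf, config.deflator))
        _write_csv(pd.concat(losses, ignore_index=True),
                   out / "annual_losses.csv")

    # ---- project ----------------------------------------------------------
    if "project" in stages:
        cmap = classify_suitability(suitability,
                                    config.suitability_thresholds)
        proj = project_losses(cmap, land_use, fits,
                              area_scaling=config.area_scaling,
                              scenario=config.scenario_label)
        _write_csv(proj.to_frame(), out / "loss_projection.csv")

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_manifest(),
    }
    payload = json.dumps(manifest, sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(payload.encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return out
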