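import numpy as np
import pytest

from invadeloss import GridSpec, LabelRaster, Raster
from invadeloss.grid import LAND_USE_LEGEND
from invadeloss.synth import (
    ScenarioConfig,
    generate_landscape,
    generate_panel,
    simulate_spread,
    staggered_schedule,
)


@pytest.fixture
def grid10():
    return GridSpec(10, 10, 1000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def scenario():
    """A small but fully featured synthetic scenario, shared read-only."""
    return ScenarioConfig(seed=7, grid=GridSpec(40, 40, 1000.0), n_units=16,
                          years=(2011, 2016))


@pytest.fixture(scope="session")
def landscape(scenario):
    return generate_landscape(scenario)


@pytest.fixture(scope="session")
def spread(scenario, landscape):
    land_use, admin, drivers = landscape
    return simulate_spread(scenario, land_use, admin, drivers)


@pytest.fixture(scope="session")
def noiseless_panel():
    """Staggered panel with planted effects and zero noise (exact recovery)."""
    cfg = ScenarioConfig(seed=11, grid=GridSpec(20, 20, 1000.0), n_units=25,
                         years=(2011, 2018), sigma_noise=0.0)
    land_use, admin, _ = generate_landscape(cfg)
    schedule = staggered_schedule(cfg)
    panel, truth = generate_panel(cfg, schedule, admin, land_use)
    return panel, truth


def make_label_raster(grid, labels, legend=None):
    labels = np.asarray(labels, dtype=np.int64)
    return LabelRaster(grid, labels, legend or {int(v): str(v)
                                                for v in np.unique(labels)})


def make_land_use(grid, labels):
    return LabelRaster(grid, np.asarray(labels, dtype=np.int64),
                       dict(LAND_USE_LEGEND))


@pytest.fixture
def checkerboard():
    g = GridSpec(8, 8, 1000.0)
    vals = np.indices(g.shape).sum(axis=0) % 2
    return Raster(g, vals.astype(float))
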