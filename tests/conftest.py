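import numpy as np
import pytest

from refugia import GridSpec, Raster, ScenarioConfig, SuitabilityGrid


@pytest.fixture
def small_grid() -> GridSpec:
    """A 5x4 coarse grid with 2-fold fine subdivision, 10 km cells."""
    return GridSpec(n_cols=5, n_rows=4, fine_factor=2)


@pytest.fixture
def small_scenario() -> ScenarioConfig:
    """A fast scenario for generator unit tests."""
    return ScenarioConfig(
        seed=7,
        n_species=3,
        n_pas=40,
        n_landcover_classes=4,
        landcover_nuclei_per_class=10,
    )


def make_suitability(values, species_id="spX", period="current", fine_factor=1):
    values = np.asarray(values, dtype=float)
    grid = GridSpec(
        n_cols=values.shape[1], n_rows=values.shape[0], fine_factor=fine_factor
    )
    return SuitabilityGrid(species_id, period, grid, values)


def make_raster(values, grid=None):
    values = np.asarray(values)
    if grid is None:
        grid = GridSpec(n_cols=values.shape[1], n_rows=values.shape[0], fine_factor=1)
    return Raster(values, grid)
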