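import numpy as np
import pytest

from ensemblesdm.geo import GridSpec, RasterLayer, RasterStack
from ensemblesdm.synthetic import generate_climate_scenarios, make_virtual_species, sample_presences

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "suite",
        derandomize=True,
        max_examples=25,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """10x10 grid of 0.5-degree cells near the equator."""
    return GridSpec(origin_lon=30.0, origin_lat=2.5, cell_size=0.5, n_rows=10, n_cols=10)


@pytest.fixture(scope="session")
def tiny_world():
    """A seeded 40x40 virtual world with 4 layers (1 informative) for model tests."""
    grid = GridSpec(origin_lon=30.0, origin_lat=0.0, cell_size=0.1, n_rows=40, n_cols=40)
    scen = generate_climate_scenarios(
        grid, n_layers=4, smoothness=5.0, collinearity=0.9, n_gcm=2, shift=0.8, seed=7
    )
    species = make_virtual_species(
        scen.current, {"BIO3": 0.5}, {"BIO3": 0.6}, ["BIO3"]
    )
    occ = sample_presences(species, 60, seed=11)
    return scen, species, occ


def constant_layer(grid: GridSpec, name: str, value: float) -> RasterLayer:
    return RasterLayer(grid, name, np.full(grid.shape, value))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
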