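import numpy as np
import pandas as pd
import pytest

from enmgap.geodata_io import RasterGrid, ClimateStack, cell_area_km2
from enmgap.synthetic_data import IslandSpec, make_island_climate


def small_island_spec(seed: int = 7) -> IslandSpec:
    """A 60x75 island that keeps tests fast (<1 s to generate)."""
    return IslandSpec(
        n_rows=60,
        n_cols=75,
        seed=seed,
        elevation_peaks=((35, 30, 2400.0, 9.0), (22, 45, 1500.0, 7.0), (42, 48, 900.0, 8.0)),
    )


@pytest.fixture(scope="session")
def island_spec():
    return small_island_spec()


@pytest.fixture(scope="session")
def world(island_spec):
    return make_island_climate(island_spec)


@pytest.fixture(scope="session")
def stack(world):
    return world[0]


@pytest.fixture(scope="session")
def elevation(world):
    return world[1]


@pytest.fixture(scope="session")
def zones(world):
    return world[2]


@pytest.fixture(scope="session")
def land(stack):
    return stack.valid_mask()


@pytest.fixture(scope="session")
def areas(stack):
    return cell_area_km2(stack.grid)


@pytest.fixture()
def toy_grid():
    """10x10 unit grid with 0.1-degree cells at the equator."""
    return RasterGrid(n_rows=10, n_cols=10, x_origin=0.0, y_origin=1.0, resolution=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_stack_1d(values: dict[str, list[float]]) -> ClimateStack:
    """A 1-row stack whose cells carry the given per-layer value sequences."""
    n = len(next(iter(values.values())))
    grid = RasterGrid(n_rows=1, n_cols=n, x_origin=0.0, y_origin=0.1, resolution=0.1)
    layers = {k: np.asarray(v, dtype=float).reshape(1, n) for k, v in values.items()}
    return ClimateStack(grid=grid, layers=layers)
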