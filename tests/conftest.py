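import numpy as np
import pandas as pd
import pytest

from flywaysdm.raster import Grid, OccurrenceSet, RasterLayer, RasterStack
from flywaysdm.synthetic import (
    LandscapeConfig,
    TrueGroup,
    generate_env_stack,
    make_true_suitability,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    return Grid(nrows=20, ncols=25, cellsize=300.0, x_origin=1000.0, y_origin=2000.0)


@pytest.fixture(scope="session")
def env_stack() -> RasterStack:
    """A 64x64 synthetic environmental stack, shared across tests."""
    return generate_env_stack(LandscapeConfig(nrows=64, ncols=64, n_env_layers=5, seed=42))


@pytest.fixture(scope="session")
def structured_species(env_stack):
    """One species driven almost entirely by env1, with its occurrences."""
    group = TrueGroup("g1", {"env1": 2.0, "env2": 0.5}, intercept=-3.0)
    truth = make_true_suitability(env_stack, group)
    occ = sample_occurrences(truth, 300, seed=7, species="sp1", group="g1")
    return group, truth, occ


def random_layer(grid: Grid, seed: int, kind: str = "continuous") -> RasterLayer:
    rng = np.random.default_rng(seed)
    return RasterLayer(grid, f"rnd{seed}", rng.standard_normal(grid.shape), kind)


def occurrences_from_cells(grid: Grid, rows, cols, species="sp", group="g") -> OccurrenceSet:
    x, y = grid.cell_center(np.asarray(rows), np.asarray(cols))
    return OccurrenceSet(
        pd.DataFrame({"species": species, "group": group, "x": x, "y": y}), grid
    )
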