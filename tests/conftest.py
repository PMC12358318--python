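import numpy as np
import pytest

import panlink as pl


@pytest.fixture(scope="session")
def weights():
    return pl.compute_weights(pl.default_matrix())


@pytest.fixture(scope="session")
def small_bundle():
    """60x60 coastal landscape with one planted corridor, no barrier."""
    cfg = pl.LandscapeConfig(nrows=60, ncols=60, seed=11, n_pa=4,
                             planted_corridors=[(1, 2)])
    return pl.generate(cfg)


@pytest.fixture(scope="session")
def small_surface(small_bundle, weights):
    return pl.compute_resistance(small_bundle, weights)


@pytest.fixture(scope="session")
def small_patches(small_bundle, small_surface):
    return pl.label_patches(small_bundle.pa_polygons, small_surface.grid,
                            valid_mask=small_surface.grid.valid_mask())


@pytest.fixture(scope="session")
def small_paths(small_patches, small_surface):
    paths, fields = pl.least_cost_paths(small_patches, small_surface)
    return paths, fields


def uniform_grid(nrows=10, ncols=10, value=1.0, cell_size=30.0):
    return pl.RasterGrid(np.full((nrows, ncols), float(value)),
                         cell_size=cell_size)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
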