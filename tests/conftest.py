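import numpy as np
import pytest
import shapely

from sdmflow.geo_core import AccessibleArea, EnvStack, Grid, Raster
from sdmflow.synthetic_data import make_landscape, make_species


@pytest.fixture(scope="session")
def landscape():
    """A 60x60 synthetic landscape: env1, env2, dem, landcover."""
    return make_landscape(seed=7, size=60, n_vars=2)


@pytest.fixture(scope="session")
def env_stack(landscape):
    return landscape.subset(["env1", "env2"])


@pytest.fixture(scope="session")
def species(env_stack):
    return make_species(env_stack, {"env1": (1.0, 0.5), "env2": (-1.0, 0.5)},
                        cutoff=0.5)


@pytest.fixture(scope="session")
def region_box(landscape):
    return shapely.box(*landscape.grid.bounds)


@pytest.fixture
def small_grid():
    return Grid(x0=-74.0, y0=5.0, dx=0.01, dy=0.01, width=10, height=10)


def presence_sample(species, n, seed):
    """Draw presence points proportional to true suitability (helper)."""
    rng = np.random.default_rng(seed)
    grid = species.true_suitability.grid
    w = np.where(np.isnan(species.true_suitability.data), 0.0,
                 species.true_suitability.data).ravel()
    p = w / w.sum()
    idx = rng.choice(p.size, size=n, p=p)
    rows, cols = np.divmod(idx, grid.width)
    lon, lat = grid.cell_center(rows, cols)
    return np.column_stack([lon, lat])


@pytest.fixture(scope="session")
def presences(species):
    return presence_sample(species, 100, seed=11)


@pytest.fixture(scope="session")
def whole_area(env_stack):
    return AccessibleArea(shapely.box(*env_stack.grid.bounds),
                          provenance="default")
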