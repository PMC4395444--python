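import numpy as np
import pytest

import mycogeo as mg


@pytest.fixture(scope="session")
def us_grid():
    return mg.build_grid(mg.DEFAULT_DOMAIN, 20, 20)


@pytest.fixture(scope="session")
def small_world():
    return mg.make_world(m=30, endemic_fraction=0.7, seed=7)


@pytest.fixture(scope="session")
def small_samples(small_world):
    return mg.simulate_samples(small_world, n=120, seed=8)


@pytest.fixture(scope="session")
def small_atlas(small_samples, us_grid):
    return mg.fit_atlas(small_samples, us_grid)


def random_instance(rng, n_max=25, m_max=5, n_cells_max=50):
    """A random tiny geolocation problem for oracle-equivalence checks."""
    n = int(rng.integers(3, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    n_cells = int(rng.integers(2, n_cells_max + 1))
    lats = rng.uniform(25, 49, n)
    lons = rng.uniform(-124, -68, n)
    glats = rng.uniform(25, 49, n_cells)
    glons = rng.uniform(-124, -68, n_cells)
    Y = rng.integers(0, 2, (n, m)).astype(np.int8)
    rho = float(rng.uniform(30, 2000))
    return {
        "lats": lats, "lons": lons, "glats": glats, "glons": glons,
        "Y": Y, "rho": rho,
        "sources": [mg.GeoCoordinate(a, b) for a, b in zip(lats, lons)],
        "grid_points": list(zip(glats, glons)),
    }
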