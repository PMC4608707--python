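import numpy as np
import pandas as pd
import pytest

from fawnscape.landscape import CategoricalRaster, build_grid, label_patches
from fawnscape.synthetic import gen_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """60x60 patchy landscape with roads and water, fixed seed."""
    return gen_landscape(7, 60, 60)


@pytest.fixture(scope="session")
def small_patches(small_landscape):
    raster, _, _ = small_landscape
    return label_patches(raster)


@pytest.fixture(scope="session")
def small_grid(small_landscape, small_patches):
    raster, roads, water = small_landscape
    return build_grid(raster, roads, water, patches=small_patches)


def make_cox_data(seed, n=300, beta=0.7, frailty_var=0.0, n_groups=30,
                  binary=False, tied_days=True):
    """Counting-process survival data from an exponential PH model."""
    rng = np.random.default_rng(seed)
    x = (rng.integers(0, 2, n).astype(float) if binary else rng.normal(size=n))
    g = rng.integers(0, n_groups, n)
    yr = rng.integers(0, 3, n)
    b = rng.normal(0, np.sqrt(frailty_var), n_groups)
    lam = 0.05 * np.exp(beta * x + b[g])
    t = rng.exponential(1 / lam)
    c = rng.uniform(5, 40, n)
    stop = np.minimum(t, c)
    if tied_days:
        stop = np.ceil(stop)
    event = (t <= c).astype(int)
    return pd.DataFrame({"start": 0.0, "stop": stop, "event": event,
                         "x": x, "fawn_id": g, "year": yr})


@pytest.fixture
def cox_data():
    return make_cox_data


def uniform_raster(n=10, cls=1, pixel=30.0):
    return CategoricalRaster(np.full((n, n), cls), (0.0, 0.0), pixel)
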