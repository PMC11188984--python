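import logging

import numpy as np
import pandas as pd
import pytest

from habscape import synth
from habscape.grids import Grid, Raster
from habscape.occurrences import SampleTable

logging.disable(logging.INFO)


@pytest.fixture
def grid5():
    return Grid(5, 5, 1.0)


@pytest.fixture
def grid10():
    return Grid(10, 10, 1.0)


@pytest.fixture(scope="session")
def pack():
    """Shared 80x80 synthetic landscape (session-scoped for speed)."""
    truth = synth.LandscapeTruth(
        master_seed=123,
        beta_true={"intercept": -3.0, "frac_grass": 6.0, "frac_shrub": 3.0},
    )
    return synth.make_landscape(truth, Grid(80, 80, 100.0))


@pytest.fixture(scope="session")
def covariates(pack):
    return synth.landscape_covariates(pack)


@pytest.fixture(scope="session")
def suitability(pack, covariates):
    return synth.true_suitability(pack, covariates)


def separable_table(n=200, seed=0):
    """Toy table where presences sit at high values of a single covariate."""
    rng = np.random.default_rng(seed)
    x_pres = rng.uniform(0.6, 1.0, n)
    x_back = rng.uniform(0.0, 0.4, n)
    df = pd.DataFrame(
        {
            "point_id": np.arange(2 * n),
            "label": ["presence"] * n + ["background"] * n,
            "lon": 0.0,
            "lat": 0.0,
            "month": 6,
            "x": np.concatenate([x_pres, x_back]),
        }
    )
    return SampleTable(df, ["x"], source_tag="toy")


def table_from_arrays(X, y, names, source_tag="toy"):
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "month", 6)
    df.insert(0, "lat", 0.0)
    df.insert(0, "lon", 0.0)
    df.insert(0, "label", np.where(np.asarray(y) == 1, "presence", "background"))
    df.insert(0, "point_id", np.arange(len(df)))
    return SampleTable(df, list(names), source_tag=source_tag)


def raster_from(values, cell_size=1.0):
    arr = np.asarray(values, dtype=float)
    return Raster(Grid(arr.shape[0], arr.shape[1], cell_size), arr)
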