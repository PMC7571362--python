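import numpy as np
import pandas as pd
import pytest

from microgbd.draws import ID_COLS, make_draws
from microgbd.synthetic import WorldConfig, generate_world


@pytest.fixture(scope="session")
def world():
    """Default desk-scale world, shared across tests (read-only)."""
    return generate_world(WorldConfig(), seed=11)


@pytest.fixture(scope="session")
def small_world():
    """A shorter world (8 years) for pipeline smoke tests."""
    return generate_world(WorldConfig(year_end=1997), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def cells_frame(n_loc=2, n_years=3, n_ages=2):
    """A tiny rectangular cell frame for draw-matrix tests."""
    idx = pd.MultiIndex.from_product(
        [[f"L{i}" for i in range(n_loc)],
         range(2000, 2000 + n_years),
         [f"a{i}" for i in range(n_ages)],
         ["male", "female"]],
        names=ID_COLS,
    )
    return idx.to_frame(index=False)


@pytest.fixture()
def tiny_draws(rng):
    cells = cells_frame()
    vals = rng.uniform(10, 100, size=(len(cells), 4))
    return make_draws(cells, vals)
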