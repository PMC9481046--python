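import logging

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from popdis import (
    CityConfig,
    ExperimentContext,
    OccupancyWeights,
    ZoneSet,
    generate_city,
    run_all,
)

logging.getLogger("popdis").setLevel(logging.ERROR)


SMALL_CONFIG = dict(
    width=1200.0,
    height=1200.0,
    n_l2=2,
    n_l1_per_l2=2,
    blocks_per_l1=2,
    seed=7,
)


@pytest.fixture(scope="session")
def small_city():
    """A compact city (16 sections, 64 blocks) for fast unit-level checks."""
    return generate_city(CityConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_ctx(small_city):
    return ExperimentContext(small_city)


@pytest.fixture(scope="session")
def default_city():
    """The standard study conditions (default config), fixed seed."""
    return generate_city(seed=1)


@pytest.fixture(scope="session")
def default_ctx(default_city):
    return ExperimentContext(default_city)


@pytest.fixture(scope="session")
def default_run(default_city, default_ctx):
    """Full 36-experiment matrix on the default city (shared by the
    acceptance checks that inspect the consolidated table)."""
    table, results = run_all(
        default_city, base_seed=1, occupancy=None, context=default_ctx
    )
    return table, results


def random_allocation_fixture(rng):
    """A tiny random disaggregation instance: SZ partition + buildings.

    Returns (sz ZoneSet, buildings DataFrame with floors/land_use) small
    enough for brute-force oracles.
    """
    ncol = rng.integers(1, 3)
    nrow = rng.integers(2, 4)
    w, h = 400.0, 400.0
    cells = []
    for r in range(nrow):
        for c in range(ncol):
            cells.append(box(c * w / ncol, r * h / nrow,
                             (c + 1) * w / ncol, (r + 1) * h / nrow))
    sz = ZoneSet(
        "L2",
        pd.DataFrame(
            {"unit_id": [f"Z{i}" for i in range(len(cells))],
             "geometry": cells,
             "pop": rng.integers(0, 500, len(cells)).astype(float)}
        ),
    )
    n = int(rng.integers(3, 11))
    xs = rng.uniform(5, w - 25, n)
    ys = rng.uniform(5, h - 25, n)
    ws = rng.uniform(4, 20, n)
    hs = rng.uniform(4, 20, n)
    buildings = pd.DataFrame(
        {
            "building_id": [f"B{i}" for i in range(n)],
            "geometry": [box(x, y, x + bw, y + bh)
                         for x, y, bw, bh in zip(xs, ys, ws, hs)],
            "floors": rng.integers(1, 6, n),
            "land_use": rng.choice(["R", "C", "O"], n),
        }
    )
    buildings["area"] = shapely.area(
        np.asarray(buildings["geometry"], dtype=object)
    )
    return sz, buildings
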