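import numpy as np
import pandas as pd
import pytest

from mesopred import grids, simulate


@pytest.fixture(scope="session")
def landscape():
    """Small deterministic landscape with truth occurrence surfaces."""
    L = grids.gen_landscape(42, extent=(96, 96))
    simulate._occurrence_truth(L, 42)
    return L


@pytest.fixture(scope="session")
def coyote_track(landscape):
    xmin, xmax, ymin, ymax = landscape.extent
    return simulate.sim_coyote_track(
        landscape,
        ((xmin + xmax) / 2, (ymin + ymax) / 2),
        400,
        selection_betas={"herbaceous": 0.5},
        seed=7,
    )


def make_fixes(animal_id, species, times, xy):
    """Fix table from explicit timestamps and coordinates."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    idx = pd.DatetimeIndex(times)
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "species": species,
            "t": idx,
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )


def hourly(start, n):
    return pd.date_range(start, periods=n, freq="h", tz="UTC")
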