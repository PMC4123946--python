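from __future__ import annotations

import numpy as np
import pytest

from lulctraj import LandCoverMap, SimulationConfig, build_stack, simulate_stack
from lulctraj.codes import GRID_DTYPE


def stack_from_sequences(sequences, start_year=2000, pixel_area_ha=1.0, dates=None):
    """Build a stack whose pixels follow the given per-pixel label sequences.

    ``sequences`` is a list of equal-length label lists; the stack has one
    row and one column per sequence. Dates default to annual July 1st.
    """
    arr = np.array(sequences, dtype=GRID_DTYPE).T  # (n_dates, n_pix)
    n, npix = arr.shape
    if dates is None:
        dates = [int(f"{start_year + k}0701") for k in range(n)]
    maps = [
        LandCoverMap(grid=arr[k].reshape(1, npix), date=dates[k], pixel_area_ha=pixel_area_ha)
        for k in range(n)
    ]
    return build_stack(maps)


@pytest.fixture(scope="session")
def sim_default():
    """A moderate simulated landscape under the default study conditions."""
    config = SimulationConfig(shape=(60, 60), seed=11)
    stack, truth = simulate_stack(config)
    return config, stack, truth
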