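import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from toxarray.io import ArrayScan, SPOT_COLUMNS
from toxarray.simulate import SimulationConfig, simulate_experiment


def make_scan(rows, array_id="a1", dye_orientation="standard"):
    """Build an ArrayScan from (spot_id, gene, fg1, bg1, fg2, bg2, flag) rows."""
    return ArrayScan(
        array_id=array_id,
        data=pd.DataFrame(rows, columns=SPOT_COLUMNS),
        dye_orientation=dye_orientation,
    )


@pytest.fixture
def small_config():
    return SimulationConfig(n_genes=300, n_arrays=2, seed=11)


@pytest.fixture
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
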