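import numpy as np
import pandas as pd
import pytest

from covnet import (RegionTable, SimulationConfig, default_region_table,
                    simulate_cohort)
from covnet.pipeline import preprocess_cohort


@pytest.fixture(scope="session")
def table():
    return default_region_table()


@pytest.fixture()
def toy_table():
    """4 regions, 2 homologue pairs, all cortical, valid sphere coordinates."""
    s = np.sqrt(1 - 0.36)
    df = pd.DataFrame({
        "name": ["left_a", "right_a", "left_b", "right_b"],
        "hemisphere": ["left", "right", "left", "right"],
        "class": ["cortical"] * 4,
        "homologue": [1, 0, 3, 2],
        "x": [-70.0, 70.0, -42.0, 42.0],
        "y": [0.0, 0.0, 56.0, 56.0],
        "z": [0.0, 0.0, 0.0, 0.0],
        "sx": [-1.0, 1.0, -0.6, 0.6],
        "sy": [0.0, 0.0, s, s],
        "sz": [0.0, 0.0, 0.0, 0.0],
    })
    return RegionTable(df)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def cohort_pre(table, sim_config):
    """One standard synthetic cohort, preprocessed (shared across tests)."""
    raw = simulate_cohort(sim_config, seed=1, table=table)
    return preprocess_cohort(raw, table)
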