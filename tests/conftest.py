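import numpy as np
import pandas as pd
import pytest

from harborair import flux as flux_mod
from harborair import properties as props_mod
from harborair import synth


@pytest.fixture(scope="session")
def table():
    return props_mod.default_table()


@pytest.fixture(scope="session")
def cfg():
    return synth.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def met(cfg):
    return synth.generate_met(cfg)


@pytest.fixture(scope="session")
def water(cfg, table):
    return synth.generate_water_samples(cfg, table)


@pytest.fixture(scope="session")
def worst_case_132(water):
    wc = flux_mod.select_worst_case(water, 3)
    return wc / wc.sum() * 132.0


@pytest.fixture()
def calm_met():
    """Constant single-hour meteorology for hand calculations."""
    return pd.DataFrame({
        "timestamp": pd.to_datetime(["2022-08-01 12:00"]),
        "u10": [4.0], "wind_dir": [270.0], "t_air": [23.0],
        "t_water": [23.0], "pressure": [101.325],
    })
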