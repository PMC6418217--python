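import numpy as np
import pandas as pd
import pytest

from glacierlake import synth
from glacierlake.core import SampleTable


@pytest.fixture()
def scenario_config():
    return synth.ScenarioConfig(seed=1)


@pytest.fixture()
def sample_table():
    """A small mixed table with censored trace analytes."""
    df = pd.DataFrame([
        # compartment, site, date, depth_m, species, value, units, censored
        ("lake_column", "deep", "2015-08-05", 250.0, "TFe", 7.0, "ug/L", True),
        ("lake_column", "deep", "2015-08-05", 250.0, "TDP", 1.8, "ug/L", True),
        ("lake_column", "deep", "2015-08-05", 200.0, "TFe", 495.0, "ug/L", False),
        ("glacial_delta", "r1", "2015-07-15", np.nan, "SO4", 12.5, "mg/L", False),
        ("snowpack", "s1", "2015-05-20", np.nan, "SO4", 1.82, "mg/L", False),
    ], columns=["compartment", "site", "date", "depth_m", "species",
                "value", "units", "censored"])
    return SampleTable(df)


@pytest.fixture()
def melt_season(scenario_config):
    """A deterministic melt hydrograph (no event noise)."""
    cfg = synth.ScenarioConfig(seed=1, event_noise_sd=0.0)
    return synth.gen_melt_hydrograph(cfg, 2015), cfg
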