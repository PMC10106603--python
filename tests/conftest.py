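import numpy as np
import pandas as pd
import pytest

from yieldcast.simulate import (config_with_seed, default_configs,
                                generate_linear_response_trial, generate_trial)
from yieldcast.trial import TrialTable


@pytest.fixture(scope="session")
def case2_table():
    """Seven-experiment replicated multi-environment table (348 plots)."""
    return generate_trial(config_with_seed(default_configs()["case2_2021"], 0))


@pytest.fixture(scope="session")
def case1_table():
    """Unreplicated landrace/modern panel (354 plots)."""
    return generate_trial(config_with_seed(default_configs()["case1_2017"], 0))


@pytest.fixture(scope="session")
def linear_table():
    """Table whose yield depends only on NDVI and DH (strong signal)."""
    return generate_linear_response_trial(300, {"ndvi": 1.2, "dh": 0.8},
                                          noise_sd=0.5, seed=0)


@pytest.fixture()
def small_table():
    """Hand-built 10-plot table with one absent NDVI and one absent EARS."""
    rng = np.random.default_rng(7)
    df = pd.DataFrame({
        "plot_id": [f"p{i}" for i in range(10)],
        "genotype_id": [f"g{i % 5}" for i in range(10)],
        "germplasm_class": ["landrace"] * 5 + ["modern"] * 5,
        "experiment_id": ["E1"] * 6 + ["E2"] * 4,
        "water_regime": ["rainfed"] * 10,
        "sowing_date": ["2020-11-15"] * 10,
        "replicate": [1, 2] * 5,
        "gy": rng.uniform(3, 11, 10).round(3),
        "ndvi": rng.uniform(0.4, 0.9, 10).round(4),
        "dh": rng.uniform(125, 145, 10).round(1),
        "ph": rng.uniform(70, 130, 10).round(1),
        "ears": rng.uniform(300, 550, 10).round(0),
    })
    df.loc[3, "ndvi"] = np.nan
    df.loc[7, "ears"] = np.nan
    return TrialTable(df, provenance="conftest")
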