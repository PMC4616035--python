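import numpy as np
import pandas as pd
import pytest

import fluvialghg as fg
from fluvialghg.simulate import MeasurementSimConfig, StratumConfig

#: Ground-truth pCO2-on-wetland lines used across end-to-end tests,
#: (intercept ppm, slope ppm per unit fraction) per channel class.
TRUE_MODELS = {
    "MS": (1500.0, 20000.0),
    "T>100m": (2000.0, 22000.0),
    "T<100m": (3000.0, 28000.0),
}

#: Six basins with wetland fractions spanning the realistic range.
SIX_BASIN_WETLANDS = {
    "B1": 0.01, "B2": 0.05, "B3": 0.10, "B4": 0.14, "B5": 0.22, "B6": 0.32,
}


def make_six_basin_measurements(seed: int, n_per_stratum: int = 50) -> pd.DataFrame:
    """Measurements for six basins whose stratum medians lie exactly on the
    TRUE_MODELS lines; only sampling noise separates fitted from true."""
    strata = []
    for basin, wf in SIX_BASIN_WETLANDS.items():
        for cls in fg.CHANNEL_CLASSES:
            intercept, slope = TRUE_MODELS[cls]
            strata.append(
                StratumConfig(basin, cls, n_per_stratum, intercept + slope * wf,
                              1.5, 5e-5, 2.5, 0.3)
            )
    return fg.generate_measurements(
        MeasurementSimConfig(strata=tuple(strata), seed=seed)
    )


@pytest.fixture(scope="session")
def study_df() -> pd.DataFrame:
    """Two-basin study-preset measurement table (Amazon n=136, Congo n=280)."""
    return fg.generate_measurements(fg.study_preset(seed=0))


@pytest.fixture(scope="session")
def six_basin_df() -> pd.DataFrame:
    return make_six_basin_measurements(seed=11)


@pytest.fixture(scope="session")
def fitted_models(six_basin_df):
    points = fg.build_basin_points(six_basin_df, SIX_BASIN_WETLANDS)
    return fg.fit_class_models(points)


@pytest.fixture(scope="session")
def true_model_objects():
    return fg.models_from_pairs(TRUE_MODELS)


@pytest.fixture()
def coscat_table():
    table, true_total = fg.generate_coscat(
        fg.CoscatSimConfig(n_cells=40, seed=7, true_models=TRUE_MODELS)
    )
    return table, true_total


def single_cell_table(
    latitude=0.0, wetland=0.10, k_small=2.0, k_large=1.5,
    area_small=100.0, area_large=200.0,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "coscat_id": ["C1"],
            "latitude": [latitude],
            "wetland_fraction": [wetland],
            "k_small_m_d": [k_small],
            "k_large_m_d": [k_large],
            "area_small_km2": [area_small],
            "area_large_km2": [area_large],
        }
    )
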