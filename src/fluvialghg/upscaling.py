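"""Upscaling fitted wetland regressions over a COSCAT table to a tropical
CO2 evasion total.

Each COSCAT cell (a coastal-segmentation catchment unit) carries a
representative latitude, a wetland fraction, and gas transfer velocities and
water surface areas for two channel size classes: streams narrower than
100 m and rivers 100 m or wider. Because surface areas are structured by
stream order, mainstem and large tributaries cannot be separated; their two
regression predictions are therefore averaged and applied to the large size
class, while the small-tributary regression drives the small size class.
Fluxes use a constant 25 degC solubility and 390 ppm atmospheric pCO2, are
scaled to the class areas, and cells with latitude inside the tropical band
(inclusive +/-30 degrees) are summed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .gas import GasConstants, areal_to_integrated, co2_flux
from .measurements import CHANNEL_CLASSES
from .wetlands import WetlandRegression, fit_class_models

logger = logging.getLogger(__name__)

__all__ = [
    "COSCAT_COLUMNS",
    "read_coscat",
    "predict_cell_pco2",
    "cell_flux",
    "upscale_cells",
    "tropical_total",
    "TropicalUpscaler",
]

COSCAT_COLUMNS = (
    "coscat_id",
    "latitude",
    "wetland_fraction",
    "k_small_m_d",
    "k_large_m_d",
    "area_small_km2",
    "area_large_km2",
)


def read_coscat(path: str | Path) -> pd.DataFrame:
    """Read and validate a COSCAT upscaling table CSV."""
    df = pd.read_csv(path)
    missing = [c for c in COSCAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing COSCAT columns: {', '.join(missing)}")
    return validate_coscat(df)


def validate_coscat(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if (df["latitude"].abs() > 90).any():
        raise ValueError("latitudes must lie in [-90, 90]")
    if ((df["wetland_fraction"] < 0) | (df["wetland_fraction"] > 1)).any():
        raise ValueError("wetland fractions must lie in [0, 1]")
    for col in ("k_small_m_d", "k_large_m_d", "area_small_km2", "area_large_km2"):
        if (df[col] < 0).any():
            raise ValueError(f"{col} must be >= 0")
    return df


def predict_cell_pco2(
    models: dict[str, WetlandRegression], wetland_fraction
) -> tuple:
    """Per-cell predicted pCO2 for the two size classes.

    Small streams take the T<100m regression directly; the large class takes
    the arithmetic mean of the MS and T>100m regression predictions, because
    the upscaling table cannot separate mainstem from large tributaries.
    """
    w = np.asarray(wetland_fraction, dtype=float)
    pco2_small = models["T<100m"].predict(w)
    pco2_ms_t = 0.5 * (models["MS"].predict(w) + models["T>100m"].predict(w))
    return pco2_small, pco2_ms_t


def cell_flux(
    cells: pd.DataFrame,
    pco2_small,
    pco2_large,
    constants: GasConstants | None = None,
) -> pd.DataFrame:
    """Areal and area-integrated CO2 fluxes per COSCAT cell.

    Returns one row per cell with the predicted pCO2, the areal fluxes for
    the two size classes (mmol m-2 d-1), and the total integrated flux
    (PgC yr-1), the sum of the two class contributions.
    """
    constants = constants or GasConstants()
    alpha = constants.alpha
    f_small = co2_flux(alpha, cells["k_small_m_d"].to_numpy(),
                       np.asarray(pco2_small), constants.atm_pco2)
    f_large = co2_flux(alpha, cells["k_large_m_d"].to_numpy(),
                       np.asarray(pco2_large), constants.atm_pco2)
    total = areal_to_integrated(f_small, cells["area_small_km2"].to_numpy()) + \
        areal_to_integrated(f_large, cells["area_large_km2"].to_numpy())
    return pd.DataFrame(
        {
            "coscat_id": cells["coscat_id"].to_numpy(),
            "latitude": cells["latitude"].to_numpy(),
            "pco2_small": np.atleast_1d(pco2_small),
            "pco2_msT": np.atleast_1d(pco2_large),
            "F_small": np.atleast_1d(f_small),
            "F_large": np.atleast_1d(f_large),
            "total_pgc_yr": np.atleast_1d(total),
        }
    )


def upscale_cells(
    cells: pd.DataFrame,
    models: dict[str, WetlandRegression],
    constants: GasConstants | None = None,
) -> pd.DataFrame:
    """Predict pCO2 and compute fluxes for every cell of a COSCAT table."""
    pco2_small, pco2_large = predict_cell_pco2(models, cells["wetland_fraction"].to_numpy())
    return cell_flux(cells, pco2_small, pco2_large, constants)


def tropical_total(
    cells: pd.DataFrame,
    models: dict[str, WetlandRegression],
    constants: GasConstants | None = None,
    lat_band: tuple[float, float] = (-30.0, 30.0),
) -> float:
    """Total CO2 evasion (PgC yr-1) summed over cells inside the latitude
    band (bounds inclusive). Cells outside the band are counted in the log;
    an empty selection warns and returns 0."""
    if cells.empty:
        raise ValueError("need at least one COSCAT cell")
    fluxes = upscale_cells(cells, models, constants)
    inside = (fluxes["latitude"] >= lat_band[0]) & (fluxes["latitude"] <= lat_band[1])
    n_out = int((~inside).sum())
    if n_out:
        logger.info("%d cell(s) outside latitude band %s excluded", n_out, lat_band)
    if not inside.any():
        logger.warning("no cells inside latitude band %s; total is 0", lat_band)
        return 0.0
    return float(fluxes.loc[inside, "total_pgc_yr"].sum())


class TropicalUpscaler(BaseEstimator):
    """End-to-end upscaler: fit per-class wetland regressions on basin
    points, then predict per-cell and tropics-total CO2 evasion.

    Parameters
    ----------
    water_temp, atm_pco2 : float
        Conditions for the flux computation (degC, ppm).
    lat_min, lat_max : float
        Inclusive latitude band for the tropical sum.

    After ``fit``, ``models_`` maps each channel class to its fitted
    :class:`~fluvialghg.wetlands.WetlandRegression`.
    """

    def __init__(
        self,
        water_temp: float = 25.0,
        atm_pco2: float = 390.0,
        lat_min: float = -30.0,
        lat_max: float = 30.0,
    ):
        self.water_temp = water_temp
        self.atm_pco2 = atm_pco2
        self.lat_min = lat_min
        self.lat_max = lat_max

    @property
    def _constants(self) -> GasConstants:
        return GasConstants(water_temp=self.water_temp, atm_pco2=self.atm_pco2)

    def fit(self, basin_points: pd.DataFrame, y=None):
        """Fit the three class regressions from a basin-point table
        (columns ``basin, channel_class, median_pco2, wetland_fraction``)."""
        self.models_ = fit_class_models(basin_points)
        return self

    def set_models(self, models: dict[str, WetlandRegression]) -> "TropicalUpscaler":
        """Install externally fitted (e.g. JSON-reloaded) class models."""
        missing = set(CHANNEL_CLASSES) - set(models)
        if missing:
            raise ValueError(f"missing class models: {sorted(missing)}")
        self.models_ = dict(models)
        return self

    def predict(self, cells: pd.DataFrame) -> pd.DataFrame:
        """Per-cell fluxes for a COSCAT table (see :func:`upscale_cells`)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "models_")
        return upscale_cells(validate_coscat(cells), self.models_, self._constants)

    def total(self, cells: pd.DataFrame) -> float:
        """Tropics-total CO2 evasion in PgC yr-1."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "models_")
        return tropical_total(
            validate_coscat(cells),
            self.models_,
            self._constants,
            (self.lat_min, self.lat_max),
        )
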