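"""Synthetic measurement data-sets and COSCAT upscaling tables with known
ground truth.

Every downstream stage — reading, stratified summaries, rank tests,
log-linear CH4 fits, wetland regressions, upscaling, Monte Carlo — can be
exercised end-to-end without any external data. Per-stratum pCO2 is
log-normal (right-skewed, as river-channel gas data are), dissolved CH4 is
coupled to pCO2 through a configurable log-linear relation with Gaussian
noise on the log10 scale, wetland fractions are Beta-distributed (bounded
support), and k and surface areas are log-normal. The COSCAT generator
returns the analytically computed "true" tropical total alongside the
table, so parameter-recovery tests have an exact target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gas import co2_solubility, DAYS_PER_YEAR, MOLAR_MASS_C
from .measurements import CHANNEL_CLASSES
from .wetlands import WetlandRegression

__all__ = [
    "StratumConfig",
    "MeasurementSimConfig",
    "CoscatSimConfig",
    "generate_measurements",
    "generate_coscat",
    "study_preset",
    "models_from_pairs",
]


@dataclass(frozen=True)
class StratumConfig:
    """Generating parameters for one river x channel-class stratum.

    pCO2 ~ log-normal(median, geometric SD); log10(CH4) = ch4_intercept +
    ch4_slope * pCO2 + N(0, ch4_log_noise_sd).
    """

    river: str
    channel_class: str
    n: int
    median_pco2: float        # ppm
    gsd_pco2: float           # geometric SD, > 1
    ch4_slope: float          # log10(nmol L-1) per ppm
    ch4_intercept: float      # log10(nmol L-1)
    ch4_log_noise_sd: float

    def __post_init__(self) -> None:
        if self.channel_class not in CHANNEL_CLASSES:
            raise ValueError(f"unknown channel class {self.channel_class!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.median_pco2 <= 0:
            raise ValueError("median_pco2 must be positive")
        if self.gsd_pco2 <= 1:
            raise ValueError("geometric SD must exceed 1")
        if self.ch4_log_noise_sd < 0:
            raise ValueError("ch4_log_noise_sd must be >= 0")


@dataclass(frozen=True)
class MeasurementSimConfig:
    strata: tuple = ()
    lon_range: tuple = (-61.0, -51.0)
    lat_range: tuple = (-4.0, 0.0)
    date_range: tuple = ("2007-01-30", "2015-05-06")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MeasurementSimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        strata = tuple(StratumConfig(**s) for s in raw.pop("strata"))
        return cls(strata=strata, **{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in raw.items()})


@dataclass(frozen=True)
class CoscatSimConfig:
    """Generating parameters for a synthetic COSCAT upscaling table.

    ``true_models`` maps each channel class to a (intercept ppm, slope ppm
    per unit fraction) pair — the ground-truth pCO2-wetland lines the table
    is consistent with.
    """

    n_cells: int = 60
    lat_range: tuple = (-35.0, 35.0)
    wetland_beta: tuple = (1.5, 8.0)          # Beta(a, b) on [0, 1]
    k_small_lognorm: tuple = (4.0, 0.3)       # (median m d-1, sigma of ln)
    k_large_lognorm: tuple = (2.5, 0.3)
    area_small_lognorm: tuple = (300.0, 1.0)  # (median km2, sigma of ln)
    area_large_lognorm: tuple = (700.0, 1.0)
    true_models: dict = field(
        default_factory=lambda: {
            "MS": (1500.0, 20000.0),
            "T>100m": (2000.0, 22000.0),
            "T<100m": (3000.0, 28000.0),
        }
    )
    water_temp: float = 25.0
    atm_pco2: float = 390.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.wetland_beta) <= 0:
            raise ValueError("Beta parameters must be positive")
        for name in ("k_small_lognorm", "k_large_lognorm",
                     "area_small_lognorm", "area_large_lognorm"):
            med, sig = getattr(self, name)
            if med <= 0 or sig < 0:
                raise ValueError(f"{name}: median must be > 0 and sigma >= 0")
        if set(self.true_models) != set(CHANNEL_CLASSES):
            raise ValueError("true_models must cover MS, T>100m, T<100m")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CoscatSimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**{k: tuple(v) if isinstance(v, list) and k != "true_models" else v
                      for k, v in raw.items()})


def generate_measurements(config: MeasurementSimConfig) -> pd.DataFrame:
    """Draw a measurement table satisfying all record invariants.

    Deterministic per seed; columns match the measurement-reader schema.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    d0 = np.datetime64(config.date_range[0])
    d1 = np.datetime64(config.date_range[1])
    span_days = int((d1 - d0) / np.timedelta64(1, "D"))
    for s in config.strata:
        if s.n == 0:
            continue
        sigma = np.log(s.gsd_pco2)
        pco2 = s.median_pco2 * np.exp(sigma * rng.standard_normal(s.n))
        log_ch4 = (s.ch4_intercept + s.ch4_slope * pco2
                   + s.ch4_log_noise_sd * rng.standard_normal(s.n))
        dates = d0 + rng.integers(0, max(span_days, 1), size=s.n).astype("timedelta64[D]")
        frames.append(
            pd.DataFrame(
                {
                    "river": s.river,
                    "date": np.datetime_as_string(dates, unit="D"),
                    "longitude": rng.uniform(*config.lon_range, size=s.n),
                    "latitude": rng.uniform(*config.lat_range, size=s.n),
                    "channel_class": s.channel_class,
                    "pco2_ppm": pco2,
                    "ch4_nmol_l": 10.0**log_ch4,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["river", "date", "longitude", "latitude",
                     "channel_class", "pco2_ppm", "ch4_nmol_l"]
        )
    return pd.concat(frames, ignore_index=True)


def generate_coscat(config: CoscatSimConfig) -> tuple[pd.DataFrame, float]:
    """Draw a COSCAT table and return it with its exact tropical total.

    The "true" total is computed here with the generator's own arithmetic
    (independent of the upscaling module): per-class pCO2 from the
    ground-truth lines with zero noise, fluxes at the configured constants,
    summed over cells with |latitude| <= 30.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    lat = rng.uniform(*config.lat_range, size=n)
    w = rng.beta(*config.wetland_beta, size=n)

    def logn(params):
        med, sig = params
        return med * np.exp(sig * rng.standard_normal(n))

    df = pd.DataFrame(
        {
            "coscat_id": [f"COSCAT{j:04d}" for j in range(n)],
            "latitude": lat,
            "wetland_fraction": w,
            "k_small_m_d": logn(config.k_small_lognorm),
            "k_large_m_d": logn(config.k_large_lognorm),
            "area_small_km2": logn(config.area_small_lognorm),
            "area_large_km2": logn(config.area_large_lognorm),
        }
    )

    alpha = co2_solubility(config.water_temp)
    b_ms, m_ms = config.true_models["MS"]
    b_lt, m_lt = config.true_models["T>100m"]
    b_st, m_st = config.true_models["T<100m"]
    p_small = np.maximum(b_st + m_st * w, 0.0)
    p_large = np.maximum(
        0.5 * ((b_ms + m_ms * w) + (b_lt + m_lt * w)), 0.0
    )
    conv = 1e-3 * 1e6 * DAYS_PER_YEAR * MOLAR_MASS_C * 1e-15
    per_cell = (
        df["k_small_m_d"] * alpha * (p_small - config.atm_pco2) * df["area_small_km2"]
        + df["k_large_m_d"] * alpha * (p_large - config.atm_pco2) * df["area_large_km2"]
    ) * conv
    inside = np.abs(lat) <= 30.0
    true_total = float(per_cell[inside].sum())
    return df, true_total


def models_from_pairs(
    pairs: dict[str, tuple],
    se_slope: float = 0.0,
    se_intercept: float = 0.0,
) -> dict[str, WetlandRegression]:
    """Build class models directly from (intercept, slope) pairs.

    Useful for driving the upscaler with ground-truth lines; standard errors
    default to zero (exact coefficients).
    """
    models = {}
    for cls, (intercept, slope) in pairs.items():
        models[cls] = WetlandRegression.from_dict(
            {
                "slope": slope,
                "intercept": intercept,
                "se_slope": se_slope,
                "se_intercept": se_intercept,
                "cov": [[se_intercept**2, 0.0], [0.0, se_slope**2]],
                "r2": 1.0,
                "n_basins": 3,
            }
        )
    return models


#: Wetland coverage of the two study basins, fraction of catchment area.
STUDY_WETLAND_FRACTIONS = {"Amazon": 0.14, "Congo": 0.10}


def study_preset(seed: int = 0) -> MeasurementSimConfig:
    """Two-basin configuration shaped like the Amazon/Congo study conditions.

    Encodes the study's structure: paired-sample sizes of 136 (Amazon) and
    280 (Congo); right-skewed pCO2 with medians increasing from mainstem to
    small tributaries in both basins; a higher mainstem pCO2 in the Amazon
    than the Congo; CH4 three to four times higher in the Congo in every
    class; a weak negative CH4-pCO2 coupling in the Amazon mainstem and
    strong positive coupling in small streams. Magnitudes are chosen to be
    realistic for lowland tropical river channels; they are generator
    settings, not measured values.
    """
    strata = (
        StratumConfig("Amazon", "MS", 68, 4500.0, 1.5, -2.0e-5, 2.74, 0.35),
        StratumConfig("Amazon", "T>100m", 40, 5500.0, 1.5, 5.0e-5, 2.60, 0.35),
        StratumConfig("Amazon", "T<100m", 28, 7000.0, 1.6, 1.2e-4, 2.40, 0.30),
        StratumConfig("Congo", "MS", 100, 3200.0, 1.6, 5.0e-5, 3.00, 0.35),
        StratumConfig("Congo", "T>100m", 90, 5000.0, 1.7, 9.0e-5, 3.00, 0.30),
        StratumConfig("Congo", "T<100m", 90, 7500.0, 1.7, 1.0e-4, 3.00, 0.30),
    )
    return MeasurementSimConfig(strata=strata, seed=seed)


def config_to_yaml(config, path: str | Path) -> None:
    """Echo a simulation config to YAML for provenance."""
    d = asdict(config)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
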