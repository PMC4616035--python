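"""Basin-scale characteristics of the two study catchments and the small
derived quantities computed from them.

The table mirrors standard published catchment characteristics for the
Amazon and Congo (catchment area, freshwater discharge, wetland coverage);
it is input data for the pipeline, used for the wetland-fraction lookup and
for simple derived quantities such as the specific discharge.
"""

from __future__ import annotations

import pandas as pd

from .gas import DAYS_PER_YEAR

__all__ = ["BASIN_CHARACTERISTICS", "specific_discharge", "verify_study_dataset"]

#: Catchment area (km2), discharge (km3 yr-1) and wetland coverage
#: (fraction of catchment) for the two study basins.
BASIN_CHARACTERISTICS = pd.DataFrame(
    {
        "basin": ["Amazon", "Congo"],
        "catchment_area_km2": [6_025_735, 3_705_222],
        "discharge_km3_yr": [5444.0, 1270.0],
        "wetland_fraction": [0.14, 0.10],
        "n_paired_samples": [136, 280],
    }
).set_index("basin")


def specific_discharge(discharge_km3_yr: float, catchment_area_km2: float) -> float:
    """Specific discharge in L s-1 km-2 from annual discharge and area.

    km3 yr-1 -> L s-1 (1 km3 = 1e12 L; 1 yr = 365.25 d), divided by the
    catchment area in km2.
    """
    if catchment_area_km2 <= 0:
        raise ValueError("catchment area must be positive")
    litres_per_second = discharge_km3_yr * 1e12 / (DAYS_PER_YEAR * 86400.0)
    return litres_per_second / catchment_area_km2


# Published basin-wide concentration ranges for the study data-set
# (min, max) pooled over all channel classes.
STUDY_RANGES = {
    ("Amazon", "pco2"): (70.0, 16_880.0),
    ("Congo", "pco2"): (1090.0, 22_900.0),
    ("Amazon", "ch4"): (11.0, 189_100.0),
    ("Congo", "ch4"): (22.0, 71_430.0),
}


def verify_study_dataset(df: pd.DataFrame, rtol: float = 0.0) -> dict:
    """Check a measurement table against the published study summaries.

    Intended for the original supplementary data-set of the study: per-basin
    record counts (Amazon 136, Congo 280) and pooled pCO2/CH4 min-max
    ranges. Returns a dict of booleans per check plus the observed values;
    ``rtol`` relaxes the range comparison for rounded published values.
    """
    from .measurements import pooled_range

    out = {}
    for basin, expected_n in (("Amazon", 136), ("Congo", 280)):
        n = int((df["river"] == basin).sum())
        out[f"n_{basin}"] = {"observed": n, "expected": expected_n,
                             "ok": n == expected_n}
    for (basin, gas), (lo, hi) in STUDY_RANGES.items():
        obs_lo, obs_hi = pooled_range(df, basin, gas)
        ok = (abs(obs_lo - lo) <= rtol * lo) and (abs(obs_hi - hi) <= rtol * hi)
        out[f"range_{basin}_{gas}"] = {
            "observed": (obs_lo, obs_hi), "expected": (lo, hi), "ok": ok,
        }
    out["all_ok"] = all(v["ok"] for v in out.values())
    return out
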