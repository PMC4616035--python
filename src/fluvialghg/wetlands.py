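"""Cross-basin regression of median river-channel pCO2 on wetland coverage.

One straight line per channel class: the median pCO2 of a basin's mainstem,
large tributaries or small tributaries is regressed on the fraction of the
catchment covered by wetlands. Each basin contributes one point per class,
unweighted, so small and large data-sets count equally. The fitted slopes,
intercepts, their standard errors and the coefficient covariance feed the
downstream upscaling and its Monte Carlo error propagation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .measurements import CHANNEL_CLASSES, summarize

logger = logging.getLogger(__name__)

__all__ = [
    "WetlandRegression",
    "build_basin_points",
    "fit_wetland_regression",
    "fit_class_models",
    "predict_pco2",
    "export_models",
    "load_models",
]


class WetlandRegression(BaseEstimator, RegressorMixin):
    """Ordinary least squares of median pCO2 (ppm) on wetland fraction.

    scikit-learn style estimator. ``fit`` takes X of shape (n_basins, 1)
    holding wetland fractions in [0, 1] and y holding the per-basin median
    pCO2 in ppm. Predictions are affine, clamped below at ``pco2_floor``
    (default 0 ppm: negative partial pressures are unphysical, while
    sub-atmospheric predictions are legitimate and yield invasion fluxes).

    Attributes (after fit)
    ----------------------
    slope_ : float
        ppm per unit wetland fraction.
    intercept_ : float
        ppm at zero wetland coverage.
    se_slope_, se_intercept_ : float
        OLS standard errors.
    cov_ : ndarray, shape (2, 2)
        Coefficient covariance, order (intercept, slope).
    r2_ : float
        Coefficient of determination.
    n_basins_ : int
    """

    def __init__(self, pco2_floor: float = 0.0):
        self.pco2_floor = pco2_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if X.shape[1] != 1:
            raise ValueError("expected a single wetland-fraction feature")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) < 3:
            raise ValueError(f"need >=3 basins to fit, got {len(X)}")
        x = X[:, 0]
        if np.any((x < 0) | (x > 1)):
            raise ValueError("wetland fractions must lie in [0, 1]")
        if np.ptp(x) == 0:
            raise ValueError("singular fit: zero variance in wetland fraction")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.se_intercept_ = float(res.bse[0])
        self.se_slope_ = float(res.bse[1])
        self.cov_ = np.asarray(res.cov_params())
        self.r2_ = float(res.rsquared)
        self.n_basins_ = int(len(x))
        self.n_clamped_ = 0
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        scalar = X.ndim == 0
        if X.ndim <= 1:
            X = np.atleast_1d(X)[:, None]
        x = X[:, 0]
        if np.any((x < 0) | (x > 1)):
            raise ValueError("wetland fractions must lie in [0, 1]")
        raw = self.intercept_ + self.slope_ * x
        clamped = raw < self.pco2_floor
        if np.any(clamped):
            self.n_clamped_ += int(np.sum(clamped))
            logger.warning(
                "clamped %d predicted pCO2 value(s) below %.1f ppm",
                int(np.sum(clamped)),
                self.pco2_floor,
            )
        out = np.where(clamped, self.pco2_floor, raw)
        return float(out[0]) if scalar else out

    def predict_with_coefficients(self, X, intercept: float, slope: float):
        """Prediction at externally supplied coefficients (Monte Carlo draws),
        with the same floor clamp."""
        x = np.atleast_1d(np.asarray(X, dtype=float))
        raw = intercept + slope * x
        return np.maximum(raw, self.pco2_floor)

    def to_dict(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "se_slope": self.se_slope_,
            "se_intercept": self.se_intercept_,
            "cov": self.cov_.tolist(),
            "r2": self.r2_,
            "n_basins": self.n_basins_,
            "pco2_floor": self.pco2_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WetlandRegression":
        m = cls(pco2_floor=d.get("pco2_floor", 0.0))
        m.slope_ = float(d["slope"])
        m.intercept_ = float(d["intercept"])
        m.se_slope_ = float(d["se_slope"])
        m.se_intercept_ = float(d["se_intercept"])
        m.cov_ = np.asarray(d["cov"], dtype=float)
        m.r2_ = float(d["r2"])
        m.n_basins_ = int(d["n_basins"])
        m.n_clamped_ = 0
        return m


def build_basin_points(
    measurements: pd.DataFrame, wetland_fractions: dict[str, float]
) -> pd.DataFrame:
    """One regression point per basin x channel class.

    Medians are computed from the pooled (all-cruise) measurements of each
    stratum; the wetland fraction comes from the supplied basin table.
    Raises ``KeyError`` naming any basin without a wetland fraction.
    """
    rows = []
    for (river, cls), _ in measurements.groupby(["river", "channel_class"], sort=True):
        if river not in wetland_fractions:
            raise KeyError(f"no wetland fraction for basin {river!r}")
        s = summarize(measurements, river, cls)
        rows.append(
            {
                "basin": river,
                "channel_class": cls,
                "median_pco2": s.pco2_median,
                "wetland_fraction": float(wetland_fractions[river]),
                "n_obs": s.n,
            }
        )
    df = pd.DataFrame(rows, columns=["basin", "channel_class", "median_pco2",
                                     "wetland_fraction", "n_obs"])
    if not df.empty and (df["wetland_fraction"].lt(0).any() or df["wetland_fraction"].gt(1).any()):
        raise ValueError("wetland fractions must lie in [0, 1]")
    return df


def fit_wetland_regression(points: pd.DataFrame) -> WetlandRegression:
    """Fit one class's regression from its basin points (unweighted OLS)."""
    return WetlandRegression().fit(
        points[["wetland_fraction"]].to_numpy(), points["median_pco2"].to_numpy()
    )


def fit_class_models(points: pd.DataFrame) -> dict[str, WetlandRegression]:
    """Fit the three per-class regressions from a basin-point table."""
    models = {}
    for cls in CHANNEL_CLASSES:
        sub = points[points["channel_class"] == cls]
        if sub.empty:
            raise ValueError(f"no basin points for channel class {cls!r}")
        models[cls] = fit_wetland_regression(sub)
    return models


def predict_pco2(model: WetlandRegression, wetland_fraction) -> float:
    """Predicted median pCO2 (ppm) at a wetland fraction in [0, 1]."""
    return model.predict(np.asarray(wetland_fraction))


def export_models(models: dict[str, WetlandRegression], path: str | Path) -> None:
    """Write fitted class models to JSON (bit-exact reload via load_models)."""
    payload = {cls: m.to_dict() for cls, m in models.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path: str | Path) -> dict[str, WetlandRegression]:
    payload = json.loads(Path(path).read_text())
    return {cls: WetlandRegression.from_dict(d) for cls, d in payload.items()}


def read_wetland_table(path: str | Path, percent: bool = False) -> dict[str, float]:
    """Read a ``basin,wetland_fraction`` CSV into a lookup dict.

    With ``percent=True`` values are divided by 100 (tables often report
    wetland coverage as a percentage of catchment area).
    """
    df = pd.read_csv(path)
    if not {"basin", "wetland_fraction"}.issubset(df.columns):
        raise ValueError("wetland table needs columns: basin, wetland_fraction")
    vals = df.set_index("basin")["wetland_fraction"].astype(float)
    if percent:
        vals = vals / 100.0
    return vals.to_dict()
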