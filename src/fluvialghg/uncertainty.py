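"""Monte Carlo error propagation for the tropical CO2 evasion total.

Three uncertainty sources are propagated, matching the structure of the
upscaling: (1) the wetland-regression coefficients (slope and intercept per
channel class, sampled jointly from the fitted coefficient covariance);
(2) the gas transfer velocities k (default +/-10% relative, 1 SD); and
(3) the river/stream surface areas (default +/-31% relative, 1 SD). Each
iteration redraws all three and recomputes the tropics-total flux; the
ensemble mean, SD and percentiles summarize the propagated uncertainty.

Coefficient draws are shared across cells within an iteration (the
regression is one model, not per-cell noise). The k and area perturbations
are multiplicative truncated normals (truncated at zero); by default one
draw per iteration shifts all cells together (``error_correlation='global'``),
reflecting systematic GIS errors such as the choice of hydraulic equation —
the conservative choice. Per-cell independent draws and uniform half-range
perturbations are available as options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .gas import GasConstants, DAYS_PER_YEAR, MOLAR_MASS_C
from .measurements import CHANNEL_CLASSES
from .wetlands import WetlandRegression

logger = logging.getLogger(__name__)

__all__ = ["McConfig", "McResult", "mc_propagate", "summarize_mc"]


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo settings.

    ``rel_sd_k`` and ``rel_sd_area`` are 1-SD relative errors of
    multiplicative perturbations; ``dist='uniform'`` reinterprets them as
    half-ranges of a uniform instead. ``error_correlation='global'`` applies
    one k draw and one area draw per iteration to every cell;
    ``'independent'`` draws per cell.
    """

    n_iterations: int = 1000
    rel_sd_k: float = 0.10
    rel_sd_area: float = 0.31
    sample_coefficients: bool = True
    use_coef_covariance: bool = True
    dist: str = "normal"
    error_correlation: str = "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.rel_sd_k < 0 or self.rel_sd_area < 0:
            raise ValueError("relative SDs must be >= 0")
        if self.dist not in ("normal", "uniform"):
            raise ValueError("dist must be 'normal' or 'uniform'")
        if self.error_correlation not in ("global", "independent"):
            raise ValueError("error_correlation must be 'global' or 'independent'")


@dataclass(frozen=True)
class McResult:
    """Ensemble summary of the Monte Carlo tropical total (PgC yr-1)."""

    mean: float
    sd: float
    p2_5: float
    p50: float
    p97_5: float
    n_iterations: int
    seed: int
    deterministic_total: float
    config: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (self.p2_5 <= self.p50 <= self.p97_5):
            raise ValueError("percentiles must be ordered")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _draw_factors(rng, rel_sd, dist, size):
    """Multiplicative perturbation factors centred on 1, truncated at 0."""
    if rel_sd == 0:
        return np.ones(size)
    if dist == "uniform":
        return rng.uniform(1.0 - rel_sd, 1.0 + rel_sd, size=size)
    a = (0.0 - 1.0) / rel_sd  # standardized lower bound at zero
    return stats.truncnorm.rvs(a, np.inf, loc=1.0, scale=rel_sd,
                               size=size, random_state=rng)


def _draw_coefficients(rng, model: WetlandRegression, n: int, use_cov: bool):
    """(n, 2) array of (intercept, slope) draws for one class model."""
    mean = np.array([model.intercept_, model.slope_])
    if use_cov:
        try:
            return rng.multivariate_normal(
                mean, model.cov_, size=n, check_valid="raise", method="svd"
            )
        except ValueError:
            logger.warning(
                "coefficient covariance not positive semi-definite; "
                "falling back to independent sampling"
            )
    draws = np.empty((n, 2))
    draws[:, 0] = rng.normal(mean[0], model.se_intercept_, size=n)
    draws[:, 1] = rng.normal(mean[1], model.se_slope_, size=n)
    return draws


def mc_propagate(
    cells: pd.DataFrame,
    models: dict[str, WetlandRegression],
    constants: GasConstants | None = None,
    config: McConfig | None = None,
    lat_band: tuple[float, float] = (-30.0, 30.0),
) -> McResult:
    """Propagate regression, k and area uncertainties to the tropical total.

    Fully vectorized over iterations and cells; reproducible from
    ``config.seed``. Returns the ensemble mean, SD, and 2.5/50/97.5
    percentiles alongside the deterministic (no-perturbation) total.
    """
    from .upscaling import tropical_total, validate_coscat

    constants = constants or GasConstants()
    config = config or McConfig()
    cells = validate_coscat(cells)
    det_total = tropical_total(cells, models, constants, lat_band)

    inside = (cells["latitude"] >= lat_band[0]) & (cells["latitude"] <= lat_band[1])
    sub = cells.loc[inside]
    n_iter = config.n_iterations
    if sub.empty:
        zeros = np.zeros(n_iter)
        return _result(zeros, config, det_total)

    rng = np.random.default_rng(config.seed)
    w = sub["wetland_fraction"].to_numpy()  # (n_cells,)
    n_cells = len(sub)

    coef = {}
    for cls in CHANNEL_CLASSES:
        if config.sample_coefficients:
            coef[cls] = _draw_coefficients(
                rng, models[cls], n_iter, config.use_coef_covariance
            )
        else:
            coef[cls] = np.tile(
                [models[cls].intercept_, models[cls].slope_], (n_iter, 1)
            )

    def predicted(cls):
        # (n_iter, n_cells), clamped at the model's pCO2 floor
        raw = coef[cls][:, [0]] + coef[cls][:, [1]] * w[None, :]
        return np.maximum(raw, models[cls].pco2_floor)

    pco2_small = predicted("T<100m")
    pco2_large = 0.5 * (predicted("MS") + predicted("T>100m"))

    shape = (n_iter, 1) if config.error_correlation == "global" else (n_iter, n_cells)
    k_fac = _draw_factors(rng, config.rel_sd_k, config.dist, shape)
    a_fac = _draw_factors(rng, config.rel_sd_area, config.dist, shape)

    alpha = constants.alpha
    k_small = sub["k_small_m_d"].to_numpy()[None, :] * k_fac
    k_large = sub["k_large_m_d"].to_numpy()[None, :] * k_fac
    area_small = sub["area_small_km2"].to_numpy()[None, :] * a_fac
    area_large = sub["area_large_km2"].to_numpy()[None, :] * a_fac

    f_small = k_small * alpha * (pco2_small - constants.atm_pco2)
    f_large = k_large * alpha * (pco2_large - constants.atm_pco2)
    conv = 1e-3 * 1e6 * DAYS_PER_YEAR * MOLAR_MASS_C * 1e-15
    totals = ((f_small * area_small + f_large * area_large) * conv).sum(axis=1)
    return _result(totals, config, det_total)


def _result(totals: np.ndarray, config: McConfig, det_total: float) -> McResult:
    p2_5, p50, p97_5 = np.percentile(totals, [2.5, 50.0, 97.5])
    if len(totals) > 1 and np.ptp(totals) > 0:
        sd = float(np.std(totals, ddof=1))
    else:
        sd = 0.0  # degenerate ensemble: avoid float residue of the mean
    return McResult(
        mean=float(np.mean(totals)),
        sd=sd,
        p2_5=float(p2_5),
        p50=float(p50),
        p97_5=float(p97_5),
        n_iterations=config.n_iterations,
        seed=config.seed,
        deterministic_total=det_total,
        config=asdict(config),
    )


def summarize_mc(result: McResult, rounding: int = 1) -> str:
    """Render a result as 'mean ± sd [p2.5, p97.5] PgC yr-1' with the
    requested number of decimals."""
    f = f"{{:.{rounding}f}}"
    return (
        f"{f.format(result.mean)} ± {f.format(result.sd)} "
        f"[{f.format(result.p2_5)}, {f.format(result.p97_5)}] PgC yr⁻¹"
    )
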