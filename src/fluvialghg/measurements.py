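"""Reading, validation, stratification and statistics for paired pCO2/CH4
river-channel measurements.

Observations are stratified by river and by channel class — mainstem (MS),
large tributaries (T>100m, width above 100 m) and small tributaries
(T<100m) — and summarized with order statistics. Between-class and
between-river differences are tested nonparametrically (Kruskal-Wallis,
Mann-Whitney), and dissolved CH4 is related to pCO2 with per-stratum
log-linear regressions: log10(CH4) on untransformed pCO2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNEL_CLASSES",
    "ClassSummary",
    "LogLinearFit",
    "read_measurements",
    "classify_channel",
    "summarize",
    "summarize_all",
    "pooled_range",
    "kruskal_wallis",
    "mann_whitney",
    "fit_log_ch4_vs_pco2",
]

#: The three channel classes, ordered from mainstem to small tributaries.
CHANNEL_CLASSES = ("MS", "T>100m", "T<100m")

REQUIRED_COLUMNS = (
    "river",
    "date",
    "longitude",
    "latitude",
    "channel_class",
    "pco2_ppm",
    "ch4_nmol_l",
)


@dataclass(frozen=True)
class ClassSummary:
    """Descriptive statistics for one river x channel-class stratum.

    Quartiles and the 5-95 percentile whisker bounds match box-plot
    conventions; percentiles use linear interpolation (type 7).
    """

    river: str
    channel_class: str
    n: int
    pco2_median: float
    pco2_mean: float
    pco2_q25: float
    pco2_q75: float
    pco2_p5: float
    pco2_p95: float
    pco2_min: float
    pco2_max: float
    ch4_median: float
    ch4_mean: float
    ch4_q25: float
    ch4_q75: float
    ch4_p5: float
    ch4_p95: float
    ch4_min: float
    ch4_max: float


@dataclass(frozen=True)
class LogLinearFit:
    """OLS fit of log10(CH4 / nmol L-1) on pCO2 (ppm) for one stratum."""

    river: str
    channel_class: str
    slope: float          # per ppm
    intercept: float      # log10(nmol L-1)
    r2: float
    n: int


def classify_channel(width_m: float | None, is_mainstem: bool = False) -> str:
    """Assign a channel class from width and a mainstem flag.

    The mainstem flag dominates. Tributaries 100 m wide or wider are
    'T>100m', narrower ones 'T<100m' (the 100 m tie goes to the large
    class).
    """
    if is_mainstem:
        return "MS"
    if width_m is None or width_m <= 0:
        raise ValueError("width must be positive for non-mainstem channels")
    return "T>100m" if width_m >= 100.0 else "T<100m"


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement CSV.

    Expected columns: ``river,date,longitude,latitude,channel_class,
    pco2_ppm,ch4_nmol_l`` with optional ``source`` and ``width_m``. Rows
    violating the record invariants (non-positive pCO2 or CH4, unknown
    channel class, unparseable numerics) are dropped with a logged reason;
    the count of rejected rows is stored in ``df.attrs['n_rejected']``.

    Raises
    ------
    ValueError
        If a required column is missing (all missing names are listed).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    return validate_measurements(df)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the record invariants to a measurement frame, dropping and
    counting invalid rows (see :func:`read_measurements`)."""
    df = df.copy()
    n_in = len(df)
    for col in ("pco2_ppm", "ch4_nmol_l", "longitude", "latitude"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_numeric = df[["pco2_ppm", "ch4_nmol_l", "longitude", "latitude"]].isna().any(axis=1)
    bad_positive = (df["pco2_ppm"] <= 0) | (df["ch4_nmol_l"] <= 0)
    bad_class = ~df["channel_class"].isin(CHANNEL_CLASSES)
    bad = bad_numeric | bad_positive.fillna(True) | bad_class
    for reason, mask in (
        ("unparseable numeric", bad_numeric),
        ("non-positive pCO2 or CH4", bad_positive & ~bad_numeric),
        ("unknown channel class", bad_class),
    ):
        for idx in df.index[mask.fillna(False)]:
            logger.warning("rejected row %d: %s", idx, reason)
    out = df.loc[~bad].reset_index(drop=True)
    out.attrs["n_rejected"] = int(n_in - len(out))
    return out


def _stratum(df: pd.DataFrame, river: str, channel_class: str | None) -> pd.DataFrame:
    sel = df["river"] == river
    if channel_class is not None:
        sel &= df["channel_class"] == channel_class
    return df.loc[sel]


def summarize(df: pd.DataFrame, river: str, channel_class: str | None = None) -> ClassSummary:
    """Order-statistic summary of one river x channel-class stratum.

    ``channel_class=None`` pools all classes of the river (used for the
    basin-wide min-max ranges). Raises ``ValueError`` on an empty stratum.
    """
    sub = _stratum(df, river, channel_class)
    if sub.empty:
        raise ValueError(f"empty stratum: river={river!r}, class={channel_class!r}")
    vals = {}
    for gas, col in (("pco2", "pco2_ppm"), ("ch4", "ch4_nmol_l")):
        x = sub[col].to_numpy(dtype=float)
        p5, q25, med, q75, p95 = np.percentile(x, [5, 25, 50, 75, 95])
        vals.update(
            {
                f"{gas}_median": med,
                f"{gas}_mean": float(np.mean(x)),
                f"{gas}_q25": q25,
                f"{gas}_q75": q75,
                f"{gas}_p5": p5,
                f"{gas}_p95": p95,
                f"{gas}_min": float(np.min(x)),
                f"{gas}_max": float(np.max(x)),
            }
        )
    return ClassSummary(
        river=river,
        channel_class=channel_class if channel_class is not None else "all",
        n=len(sub),
        **vals,
    )


def summarize_all(df: pd.DataFrame) -> pd.DataFrame:
    """One :class:`ClassSummary` row per observed river x channel class."""
    rows = []
    for (river, cls), _ in df.groupby(["river", "channel_class"], sort=True):
        rows.append(summarize(df, river, cls).__dict__)
    return pd.DataFrame(rows)


def pooled_range(df: pd.DataFrame, river: str, gas: str = "pco2") -> tuple[float, float]:
    """Basin-wide (all classes pooled) min and max of a gas for one river."""
    s = summarize(df, river, None)
    return (getattr(s, f"{gas}_min"), getattr(s, f"{gas}_max"))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups.

    Returns the tie-corrected H statistic and the chi-square p-value.
    Requires at least two groups, each non-empty.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if np.ptp(np.concatenate(groups)) == 0:
        # every value tied across all groups: no evidence of difference
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both samples are small and
    tie-free, and the tie-corrected normal approximation otherwise.
    Returns (U of the first sample, two-sided p-value).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def class_comparison_report(df: pd.DataFrame) -> pd.DataFrame:
    """All within-river Kruskal-Wallis class effects and all pairwise
    between-river Mann-Whitney comparisons, for both gases.

    One row per test with the statistic, p-value and sample sizes; p-values
    are reported for every pairwise comparison rather than singling one out.
    """
    rows = []
    rivers = sorted(df["river"].unique())
    for river in rivers:
        for gas, col in (("pco2", "pco2_ppm"), ("ch4", "ch4_nmol_l")):
            groups = [
                _stratum(df, river, c)[col].to_numpy()
                for c in CHANNEL_CLASSES
                if not _stratum(df, river, c).empty
            ]
            if len(groups) >= 2:
                h, p = kruskal_wallis(*groups)
                rows.append(
                    {
                        "test": "kruskal-wallis",
                        "gas": gas,
                        "comparison": f"{river}: classes",
                        "statistic": h,
                        "p_value": p,
                        "n": sum(len(g) for g in groups),
                    }
                )
    for i, r1 in enumerate(rivers):
        for r2 in rivers[i + 1:]:
            for cls in CHANNEL_CLASSES:
                for gas, col in (("pco2", "pco2_ppm"), ("ch4", "ch4_nmol_l")):
                    a = _stratum(df, r1, cls)[col].to_numpy()
                    b = _stratum(df, r2, cls)[col].to_numpy()
                    if len(a) == 0 or len(b) == 0:
                        continue
                    u, p = mann_whitney(a, b)
                    rows.append(
                        {
                            "test": "mann-whitney",
                            "gas": gas,
                            "comparison": f"{r1} vs {r2}: {cls}",
                            "statistic": u,
                            "p_value": p,
                            "n": len(a) + len(b),
                        }
                    )
    return pd.DataFrame(rows)


def fit_log_ch4_vs_pco2(df: pd.DataFrame, river: str, channel_class: str) -> LogLinearFit:
    """Per-stratum OLS of log10(CH4) on pCO2 (pCO2 left untransformed).

    Requires at least 3 records and non-degenerate pCO2. All cruises of the
    stratum are pooled.
    """
    sub = _stratum(df, river, channel_class)
    if len(sub) < 3:
        raise ValueError(
            f"need >=3 records to fit, got {len(sub)} for {river}/{channel_class}"
        )
    x = sub["pco2_ppm"].to_numpy(dtype=float)
    y = np.log10(sub["ch4_nmol_l"].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("singular fit: zero variance in pCO2")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LogLinearFit(
        river=river,
        channel_class=channel_class,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        n=len(sub),
    )
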