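"""Dendrometer-band growth metrics and water-potential summaries.

Band dendrometers record stem circumference every 2-3 weeks; diameter is
circumference / pi.  Three metrics summarise each tree's series over the
rainfall year (1 November - 31 October, matching the site's November-
April wet season):

* ADI, annual diameter increment: net diameter change per rainfall year,
  linearly interpolated to the year boundaries (shrinkage can make it
  negative);
* PDGR, peak diameter growth rate: maximum annualised slope of a
  GCV-tuned cubic smoothing spline evaluated on a daily grid, floored
  at zero;
* growing-season length: days between the first and last day the
  smoothed daily rate exceeds a threshold (default 10% of PDGR).

Monthly predawn/midday xylem pressure potentials are summarised per
species-month with t-based 95% CIs; soil water potential is averaged
across the three logger depths.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .constants import DAYS_PER_YEAR
from .stats import PooledEstimate, pool_estimates, t_interval

__all__ = [
    "band_to_diameter", "compute_adi", "compute_pdgr",
    "growing_season_length", "shrink_species_estimates",
    "summarize_water_potentials", "RAIN_YEAR_START_MONTH",
]

#: Rainfall year runs 1 November - 31 October.
RAIN_YEAR_START_MONTH = 11

#: Minimum observed coverage (days) for a rainfall year to count.
MIN_YEAR_COVERAGE_DAYS = 300


def band_to_diameter(circumference_mm) -> np.ndarray:
    """Stem diameter (mm) from band circumference readings."""
    circ = np.asarray(circumference_mm, dtype=float)
    if np.any(circ < 0):
        raise ValueError("circumference readings must be >= 0")
    return circ / np.pi


def _as_days(dates):
    """Dates -> float days since the first reading, plus the origin."""
    idx = pd.DatetimeIndex(dates)
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise ValueError("dates must be strictly increasing")
    t = (idx - idx[0]).total_seconds() / 86400.0
    return np.asarray(t, dtype=float), idx


def compute_adi(dates, diameter_mm) -> tuple[float, dict[int, float]]:
    """Annual diameter increment per rainfall year, mm.

    Returns the mean over complete years and the per-year breakdown
    keyed by the calendar year in which the rainfall year starts.  Years
    covered for fewer than 300 days are excluded with a warning.
    """
    t, idx = _as_days(dates)
    d = np.asarray(diameter_mm, dtype=float)
    start_year = idx[0].year if idx[0].month >= RAIN_YEAR_START_MONTH \
        else idx[0].year - 1
    end_year = idx[-1].year if idx[-1].month >= RAIN_YEAR_START_MONTH \
        else idx[-1].year - 1
    per_year: dict[int, float] = {}
    for year in range(start_year, end_year + 1):
        y0 = pd.Timestamp(year=year, month=RAIN_YEAR_START_MONTH, day=1)
        y1 = pd.Timestamp(year=year + 1, month=RAIN_YEAR_START_MONTH, day=1)
        lo = max(y0, idx[0])
        hi = min(y1, idx[-1])
        coverage = (hi - lo).days
        if coverage < MIN_YEAR_COVERAGE_DAYS:
            warnings.warn(
                f"rainfall year {year}/{year + 1} covered for {coverage} "
                f"days (< {MIN_YEAR_COVERAGE_DAYS}); excluded", stacklevel=2)
            continue
        t_lo = (lo - idx[0]).total_seconds() / 86400.0
        t_hi = (hi - idx[0]).total_seconds() / 86400.0
        d_lo = float(np.interp(t_lo, t, d))
        d_hi = float(np.interp(t_hi, t, d))
        per_year[year] = d_hi - d_lo
    if not per_year:
        raise ValueError("no rainfall year with sufficient coverage")
    return float(np.mean(list(per_year.values()))), per_year


def _daily_rate(dates, diameter_mm):
    """Smoothed daily growth rate (mm day-1) on a daily grid."""
    t, idx = _as_days(dates)
    d = np.asarray(diameter_mm, dtype=float)
    if t.size < 5:
        raise ValueError("need >= 5 readings to smooth")
    spline = make_smoothing_spline(t, d)     # lam chosen by GCV
    grid = np.arange(t[0], t[-1] + 0.5)
    rate = spline.derivative()(grid)
    return grid, rate, idx


def compute_pdgr(dates, diameter_mm) -> float:
    """Peak diameter growth rate, mm year-1 (never negative)."""
    _, rate, _ = _daily_rate(dates, diameter_mm)
    return float(max(rate.max() * DAYS_PER_YEAR, 0.0))


def growing_season_length(dates, diameter_mm,
                          threshold: float | None = None) -> float:
    """Mean days per rainfall year with supra-threshold smoothed growth.

    Within each rainfall year the season spans the first to the last day
    whose smoothed daily rate exceeds ``threshold`` (mm day-1; by
    default 10% of the tree's own peak daily rate).  Returns the mean
    over rainfall years with any coverage, or 0 (with a warning) when
    growth never exceeds the threshold.
    """
    grid, rate, idx = _daily_rate(dates, diameter_mm)
    if threshold is None:
        peak = rate.max()
        if peak <= 1e-9:          # numerically flat series
            warnings.warn("no growth signal: season length 0", stacklevel=2)
            return 0.0
        threshold = 0.1 * peak
    dates_grid = idx[0] + pd.to_timedelta(grid, unit="D")
    rain_year = np.where(dates_grid.month >= RAIN_YEAR_START_MONTH,
                         dates_grid.year, dates_grid.year - 1)
    lengths = []
    for year in np.unique(rain_year):
        m = rain_year == year
        above = np.flatnonzero(rate[m] > threshold)
        if above.size:
            lengths.append(float(grid[m][above[-1]] - grid[m][above[0]]))
    if not lengths:
        warnings.warn("no supra-threshold growth: season length 0",
                      stacklevel=2)
        return 0.0
    return float(np.mean(lengths))


def shrink_species_estimates(values, initial_size=None, year=None,
                             se=None) -> PooledEstimate:
    """Pool per-tree growth metrics into a species estimate.

    Initial stem size is regressed out (OLS, evaluated at the mean
    size) and year enters as an exchangeable additive offset before the
    empirical-Bayes normal-normal pooling.
    """
    y = np.asarray(values, dtype=float)
    if initial_size is not None:
        x = np.asarray(initial_size, dtype=float)
        if x.size != y.size:
            raise ValueError("initial_size must match values")
        if np.ptp(x) > 0 and y.size >= 3:
            beta = np.polyfit(x, y, 1)[0]
            y = y - beta * (x - x.mean())
    if year is not None:
        yr = np.asarray(year)
        if yr.size != y.size:
            raise ValueError("year must match values")
        grand = y.mean()
        adj = y.copy()
        for u in np.unique(yr):
            m = yr == u
            adj[m] = y[m] - (y[m].mean() - grand)
        y = adj
    return pool_estimates(y, se)


def summarize_water_potentials(records: pd.DataFrame) -> pd.DataFrame:
    """Monthly species means +/- 95% CI for predawn, midday and their gap.

    ``records`` needs columns tree_id, species, date, psi_pd, psi_md and
    any soil_psi_* depth columns.  Soil psi is averaged across depths.
    Returns one row per species-month.
    """
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["month"] = df["date"].dt.to_period("M")
    df["delta_psi"] = df["psi_md"] - df["psi_pd"]
    soil_cols = [c for c in df.columns if c.startswith("soil_psi")]
    if soil_cols:
        df["soil_psi_mean"] = df[soil_cols].mean(axis=1)
    rows = []
    for (species, month), grp in df.groupby(["species", "month"]):
        row = {"species": species, "month": str(month),
               "n_trees": grp["tree_id"].nunique()}
        for var in ("psi_pd", "psi_md", "delta_psi"):
            vals = grp[var].dropna().to_numpy()
            row[var] = float(np.mean(vals)) if vals.size else np.nan
            lo, hi = t_interval(vals) if vals.size else (np.nan, np.nan)
            row[f"{var}_ci_lo"], row[f"{var}_ci_hi"] = lo, hi
        if soil_cols:
            row["soil_psi_mean"] = float(grp["soil_psi_mean"].mean())
        rows.append(row)
    return pd.DataFrame(rows)
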