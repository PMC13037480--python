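"""Pneumatic vulnerability curves: air discharge, PAD and the P50 fit.

A Pneumatron draws a partial vacuum on a small reservoir connected to a
cut branch and logs the pressure every 0.5 s for 1.5 min.  Air pulled
from embolized (gas-filled) xylem raises the reservoir pressure; the
amount of air discharged follows the ideal gas law,

    AD = dP * V / (R * T)    [mol],

with dP the pressure rise over the measurement window.  Scaling each
step's AD between the branch's hydrated minimum and desiccated maximum
gives the percentage of air discharged,

    PAD_i = 100 * (AD_i - AD_min) / (AD_max - AD_min),

a pneumatic proxy for percent loss of hydraulic conductivity.  The
vulnerability curve is the symmetric logistic

    PAD(psi) = 100 / (1 + exp(a * (psi - P50))),

whose midpoint is the water potential at 50% conductivity loss (P50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import R_GAS
from .stats import PooledEstimate, t_interval

__all__ = [
    "PneumatronStep", "PneumatronSeries", "PADCurve",
    "compute_ad", "compute_pad", "VulnerabilityCurve",
    "fit_vulnerability", "species_p50",
]

#: Pressure changes beyond this (kPa) approach the device's detection
#: ceiling; such steps are flagged, never altered.
SATURATION_DELTA_KPA = 50.0


@dataclass
class PneumatronStep:
    """One drying step's pressure trace with its equilibrated psi."""

    psi: float                 # MPa, <= 0
    pressure_kpa: np.ndarray   # 0.5-s cadence over the measurement window

    def __post_init__(self):
        if self.psi > 0:
            raise ValueError("psi must be <= 0 MPa")
        self.pressure_kpa = np.asarray(self.pressure_kpa, dtype=float)


@dataclass
class PneumatronSeries:
    """All steps for one branch plus the tubing geometry."""

    branch_id: str
    steps: list[PneumatronStep]
    tubing_volume: float       # m3
    temperature: float         # K

    def __post_init__(self):
        if not 1e-7 <= self.tubing_volume <= 1e-4:
            raise ValueError(
                f"tubing volume {self.tubing_volume} m3 outside [1e-7, 1e-4]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")


@dataclass
class PADCurve:
    """Percent air discharged per step, scaled per branch."""

    branch_id: str
    psi: np.ndarray
    pad: np.ndarray
    ad: np.ndarray
    ad_min: float
    ad_max: float


def compute_ad(trace_kpa, volume: float, temperature: float,
               endpoint_window: int = 5) -> float:
    """Moles of air discharged over one pressure trace (ideal gas law).

    The start and end pressures are the medians of the first and last
    ``endpoint_window`` readings, resisting single-reading noise.
    """
    if volume <= 0:
        raise ValueError("tubing volume must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    p = np.asarray(trace_kpa, dtype=float)
    if p.size < 2 * endpoint_window:
        raise ValueError(
            f"trace of {p.size} readings shorter than the two "
            f"{endpoint_window}-reading endpoint windows")
    dp_kpa = float(np.median(p[-endpoint_window:])
                   - np.median(p[:endpoint_window]))
    if abs(dp_kpa) >= SATURATION_DELTA_KPA:
        warnings.warn(
            f"pressure change {dp_kpa:.1f} kPa at or beyond the "
            f"~{SATURATION_DELTA_KPA:.0f} kPa detection ceiling", stacklevel=2)
    return dp_kpa * 1000.0 * volume / (R_GAS * temperature)


def compute_pad(series: PneumatronSeries,
                endpoint_window: int = 5) -> PADCurve:
    """Percent air discharged per step.

    AD_min is the branch's hydrated minimum and AD_max its desiccated
    maximum, taken as the min/max over all steps.
    """
    if len(series.steps) < 3:
        raise ValueError("need >= 3 steps for a PAD curve")
    psi = np.array([s.psi for s in series.steps], dtype=float)
    ad = np.array([
        compute_ad(s.pressure_kpa, series.tubing_volume,
                   series.temperature, endpoint_window)
        for s in series.steps])
    ad_min, ad_max = float(ad.min()), float(ad.max())
    if ad_max == ad_min:
        raise ValueError("flat AD series: AD_max equals AD_min")
    pad = 100.0 * (ad - ad_min) / (ad_max - ad_min)
    return PADCurve(series.branch_id, psi, pad, ad, ad_min, ad_max)


def _logistic(psi, slope_a, p50):
    return 100.0 / (1.0 + np.exp(slope_a * (psi - p50)))


class VulnerabilityCurve(BaseEstimator, RegressorMixin):
    """Symmetric logistic (Pammenter-type) fit of PAD against psi.

    Attributes
    ----------
    p50_ : float
        Water potential at 50% air discharge, MPa (< 0).
    slope_a_ : float
        Logistic steepness, MPa-1 (> 0); the PAD slope at P50 is
        25 * slope_a_ in % MPa-1.
    p12_, p88_ : float
        Potentials at 12% and 88% air discharge from the same sigmoid
        (air-entry and full-embolism proxies); p12_ > p50_ > p88_.
    rss_ : float
    """

    def __init__(self, min_span: tuple[float, float] = (20.0, 80.0),
                 slope_init: float = 2.0, maxfev: int = 10000):
        self.min_span = min_span
        self.slope_init = slope_init
        self.maxfev = maxfev

    def fit(self, X, y):
        psi = np.asarray(X, dtype=float).reshape(-1)
        pad = np.asarray(y, dtype=float).reshape(-1)
        lo, hi = self.min_span
        if pad.min() >= lo or pad.max() <= hi:
            raise ValueError(
                f"PAD span [{pad.min():.1f}, {pad.max():.1f}]% does not "
                f"extend below {lo:.0f}% and above {hi:.0f}%")
        # Start value: psi at PAD nearest 50 by interpolation along the
        # curve ordered from least to most negative psi.
        order = np.argsort(psi)[::-1]
        p50_0 = float(np.interp(50.0, pad[order], psi[order]))
        if not np.isfinite(p50_0) or p50_0 >= 0:
            p50_0 = float(np.median(psi))
        try:
            popt, _ = curve_fit(
                _logistic, psi, pad, p0=[self.slope_init, p50_0],
                bounds=([1e-6, -np.inf], [np.inf, 0.0]),
                maxfev=self.maxfev)
        except RuntimeError as err:
            raise RuntimeError(
                f"vulnerability fit did not converge from start values "
                f"slope={self.slope_init}, P50={p50_0:.2f}: {err}") from err
        self.slope_a_, self.p50_ = float(popt[0]), float(popt[1])
        self.rss_ = float(np.sum((pad - _logistic(psi, *popt)) ** 2))
        # Closed-form quantiles of the same sigmoid.
        self.p12_ = self.p50_ + np.log(88.0 / 12.0) / self.slope_a_
        self.p88_ = self.p50_ + np.log(12.0 / 88.0) / self.slope_a_
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "p50_")
        psi = np.asarray(X, dtype=float)
        return _logistic(psi, self.slope_a_, self.p50_)


def fit_vulnerability(pad: PADCurve, **kwargs) -> VulnerabilityCurve:
    """Fit the logistic vulnerability curve to one branch's PAD data."""
    return VulnerabilityCurve(**kwargs).fit(pad.psi, pad.pad)


def species_p50(branch_p50s) -> PooledEstimate:
    """Species P50 as mean of branch values with t-based 90/95% CIs."""
    x = np.asarray(branch_p50s, dtype=float)
    m = float(np.mean(x))
    return PooledEstimate(m, t_interval(x, 0.90), t_interval(x, 0.95),
                          x.size, tau2=float(np.var(x, ddof=1)) if x.size > 1 else 0.0,
                          degenerate=x.size == 1)
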