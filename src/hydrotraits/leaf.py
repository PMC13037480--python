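"""Leaf and wood traits: turgor loss point from osmometry, SLA,
minimum (cuticular) conductance from desiccation series, wood density.

The turgor loss point is estimated from full-turgor osmolality via the
van't Hoff relation, pi_o = -c R T, followed by the published osmometer
calibration psi_tlp = 0.832 * pi_o - 0.631.

Minimum conductance comes from a bench desiccation assay: an excised,
sealed leaf loses mass at a near-constant rate once stomata are closed.
The transpiration rate J is the OLS mass-loss slope divided by total
(two-sided) leaf area and the millimolar mass of water; then

    g_min = J * P_amb / VPD    [mmol m-2 s-1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .constants import (MMW_WATER, P_AMBIENT, R_MPA, TLP_INTERCEPT,
                        TLP_SLOPE)

__all__ = [
    "TurgorLossEstimate", "LeafDesiccationSeries", "GminFit",
    "psi_tlp_from_osmolality", "compute_sla", "compute_vpd",
    "saturation_vapour_pressure", "fit_gmin", "compute_wd",
]


@dataclass
class TurgorLossEstimate:
    pi_o: float      # osmotic potential at full turgor, MPa
    psi_tlp: float   # water potential at turgor loss, MPa


def psi_tlp_from_osmolality(osmolality: float, temperature_c: float = 25.0,
                            slope: float = TLP_SLOPE,
                            intercept: float = TLP_INTERCEPT) -> TurgorLossEstimate:
    """Turgor loss point from a full-turgor osmometer reading.

    Parameters
    ----------
    osmolality : float
        mmol kg-1, > 0.
    temperature_c : float
        Temperature assumed for the van't Hoff conversion (default 25).
    slope, intercept : float
        Osmometer calibration mapping pi_o (MPa) to psi_tlp.
    """
    if osmolality <= 0:
        raise ValueError("osmolality must be positive")
    rt = R_MPA * (273.15 + temperature_c)          # MPa kg mol-1
    pi_o = -osmolality / 1000.0 * rt
    return TurgorLossEstimate(pi_o, slope * pi_o + intercept)


def compute_sla(area_cm2, dry_mass_g) -> float:
    """Specific leaf area, cm2 g-1; arrays give the mean per-leaf ratio."""
    area = np.atleast_1d(np.asarray(area_cm2, dtype=float))
    mass = np.atleast_1d(np.asarray(dry_mass_g, dtype=float))
    if np.any(area <= 0) or np.any(mass <= 0):
        raise ValueError("areas and dry masses must be positive")
    return float(np.mean(area / mass))


def saturation_vapour_pressure(t_c: float) -> float:
    """Tetens saturation vapour pressure over water, kPa."""
    return 0.61078 * np.exp(17.27 * t_c / (t_c + 237.3))


def compute_vpd(t_c: float, rh: float) -> float:
    """Vapour pressure deficit, kPa, from temperature (degC) and RH (%)."""
    if not 0 < rh < 100:
        raise ValueError("RH must lie strictly between 0 and 100%")
    return saturation_vapour_pressure(t_c) * (1.0 - rh / 100.0)


@dataclass
class LeafDesiccationSeries:
    """Timed mass readings of a detached leaf drying on the bench."""

    leaf_id: str
    time_s: np.ndarray
    mass_g: np.ndarray
    area_projected_m2: float
    t_c: float
    rh: float
    p_amb_kpa: float = P_AMBIENT
    dm_g: float | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.mass_g = np.asarray(self.mass_g, dtype=float)
        if self.time_s.size != self.mass_g.size:
            raise ValueError("time and mass series differ in length")
        if self.area_projected_m2 <= 0:
            raise ValueError("projected area must be positive")
        if self.rh >= 100:
            raise ValueError("RH >= 100%: no vapour pressure deficit")

    @property
    def area_total_m2(self) -> float:
        """Total evaporating surface: projected area times two."""
        return 2.0 * self.area_projected_m2


@dataclass
class GminFit:
    slope_g_per_s: float
    J: float        # transpiration rate, mmol m-2 s-1
    gmin: float     # mmol m-2 s-1
    window: tuple[float, float]
    n_points: int
    r_squared: float


def fit_gmin(series: LeafDesiccationSeries,
             skip_initial_s: float = 1800.0) -> GminFit:
    """Minimum conductance from the linear tail of a desiccation series.

    The first ``skip_initial_s`` seconds (default 30 min) are dropped as
    the stomatal-closure transient; the remaining window must hold at
    least 4 readings and show non-increasing mass.
    """
    t0 = series.time_s.min() + skip_initial_s
    sel = series.time_s >= t0
    t, m = series.time_s[sel], series.mass_g[sel]
    if t.size < 4:
        raise ValueError(
            f"only {t.size} readings after the {skip_initial_s / 60:.0f}-min "
            "transient window (need >= 4)")
    res = linregress(t, m)
    if res.slope > 0:
        raise ValueError("mass increases over the fit window")
    vpd = compute_vpd(series.t_c, series.rh)
    if vpd <= 0:
        raise ValueError("zero vapour pressure deficit")
    j = -res.slope / (series.area_total_m2 * MMW_WATER)
    gmin = j * series.p_amb_kpa / vpd
    return GminFit(float(res.slope), float(j), float(gmin),
                   (float(t[0]), float(t[-1])), int(t.size),
                   float(res.rvalue ** 2))


def compute_wd(dry_mass_g: float, fresh_volume_cm3: float) -> float:
    """Wood density: oven-dry mass over water-saturated fresh volume."""
    if fresh_volume_cm3 <= 0:
        raise ValueError("fresh volume must be positive")
    wd = dry_mass_g / fresh_volume_cm3
    if not 0 < wd < 1.5:
        warnings.warn(f"wood density {wd:.2f} g cm-3 outside (0, 1.5)",
                      stacklevel=2)
    return wd
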