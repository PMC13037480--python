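"""Gas-exchange response curves: cleaning, light-response and A-Ci fits.

Light response follows the non-rectangular hyperbola

    A(I) = [phi*I + Asat - sqrt((phi*I + Asat)^2 - 4*theta*phi*I*Asat)]
           / (2*theta) - Rd,

with quantum yield phi, curvature theta, light-saturated gross rate
Asat and dark respiration Rd; the reported A_max is the fitted net rate
at the protocol maximum I = 2000 umol m-2 s-1.

CO2 response follows the FvCB model as the minimum of the Rubisco- and
electron-transport-limited rates,

    Ac = Vcmax (Ci - G*) / (Ci + Kc (1 + O/Ko)),
    Aj = J (Ci - G*) / (4 Ci + 8 G*),     A = min(Ac, Aj) - Rd,

fitted at the chamber irradiance of 2000 umol m-2 s-1, so the fitted J
is the electron transport rate at 2000 (the operational J_max); the
underlying NRH capacity parameter is also reported, inverted through
the light-curve phi and theta.

The 50 -> 400 ppm protocol transition can leave anomalous readings in
the three 400-ppm recovery points; cleaning flags recovery points whose
A deviates from the median of the stable 400-ppm readings by more than
a configurable relative threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import GAMMA_STAR_25, KC_25, KO_25, O2_MMOL
from .stats import PooledEstimate, pool_estimates

__all__ = [
    "ResponseCurve", "LIGHT_SEQUENCE", "CO2_SEQUENCE",
    "clean_response_curve", "LightResponseCurve", "ACiCurve",
    "fit_light_response", "fit_aci", "pool_species",
    "nrh_capacity_from_rate",
]

#: Printed chamber protocols.
LIGHT_SEQUENCE = (2000, 1500, 1000, 500, 250, 120, 60, 30, 15, 0)
CO2_SEQUENCE = (400, 300, 200, 100, 50, 400, 400, 400, 600, 800, 1000, 1200)

#: Protocol irradiance at which CO2 curves are measured and at which the
#: operational J_max and A_max are reported, umol m-2 s-1.
I_REFERENCE = 2000.0


@dataclass
class ResponseCurve:
    """One light or CO2 response curve in protocol order."""

    curve_id: str
    kind: str                      # "light" | "co2"
    driver: np.ndarray             # PAR or chamber CO2, protocol order
    a_net: np.ndarray              # umol m-2 s-1
    ci: np.ndarray | None = None   # ppm, CO2 curves
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.kind not in ("light", "co2"):
            raise ValueError("kind must be 'light' or 'co2'")
        self.driver = np.asarray(self.driver, dtype=float)
        self.a_net = np.asarray(self.a_net, dtype=float)
        if self.ci is not None:
            self.ci = np.asarray(self.ci, dtype=float)

    def unflagged(self):
        keep = np.array([i not in self.flags for i in range(self.driver.size)])
        return keep


def clean_response_curve(curve: ResponseCurve, threshold: float = 0.15,
                         manual_exclude=()) -> ResponseCurve:
    """Flag anomalous 400-ppm recovery points after the 50-ppm step.

    Recovery points are the (up to three) 400-ppm observations that
    follow the 50-ppm step; the reference is the median A of the stable
    400-ppm readings (those not in the recovery block).  A recovery
    point deviating from the reference by more than ``threshold`` in
    relative terms is flagged.  Light curves pass through untouched
    apart from the manual list.
    """
    curve.flags.update(manual_exclude)
    if curve.kind != "co2":
        return curve
    drv = curve.driver
    low = np.flatnonzero(drv == 50)
    if low.size == 0:
        return curve
    after = np.flatnonzero((np.arange(drv.size) > low[-1]) & (drv == 400))
    recovery = set(after[:3].tolist())
    stable = [i for i in np.flatnonzero(drv == 400) if i not in recovery]
    if not stable:
        return curve
    ref = float(np.median(curve.a_net[stable]))
    scale = abs(ref) if ref != 0 else 1.0
    for i in recovery:
        if abs(curve.a_net[i] - ref) > threshold * scale:
            curve.flags.add(int(i))
    return curve


def _nrh(i, phi, theta, asat):
    s = phi * i + asat
    return (s - np.sqrt(np.maximum(s * s - 4.0 * theta * phi * i * asat, 0.0))) \
        / (2.0 * theta)


def nrh_capacity_from_rate(rate: float, phi: float, theta: float,
                           i0: float = I_REFERENCE) -> float:
    """Invert the non-rectangular hyperbola at irradiance ``i0``.

    Given the realised rate y = NRH(i0; phi, theta, cap), solve for the
    capacity: cap = y (phi*i0 - theta*y) / (phi*i0 - y).
    """
    denom = phi * i0 - rate
    if denom <= 0:
        raise ValueError(
            f"rate {rate:.2f} not reachable below phi*I = {phi * i0:.2f}")
    return rate * (phi * i0 - theta * rate) / denom


class LightResponseCurve(BaseEstimator, RegressorMixin):
    """Non-rectangular hyperbola fit of net assimilation against PAR.

    Attributes
    ----------
    phi_ : float
        Apparent quantum yield, mol CO2 mol-1 photons.
    theta_ : float
        Curvature, in (0, 1).
    asat_ : float
        Light-saturated gross assimilation, umol m-2 s-1.
    rd_ : float
        Dark respiration, umol m-2 s-1 (A(0) = -rd_).
    amax_ : float
        Fitted net assimilation at I = 2000.
    """

    def __init__(self, maxfev: int = 20000):
        self.maxfev = maxfev

    def fit(self, X, y):
        par = np.asarray(X, dtype=float).reshape(-1)
        a = np.asarray(y, dtype=float).reshape(-1)
        if par.size < 6:
            raise ValueError("need >= 6 unflagged light points")
        if par.min() > 0:
            raise ValueError("light curve must include a dark (I=0) point")
        rd0 = max(-a[np.argmin(par)], 0.1)
        asat0 = max(a.max() + rd0, 1.0)

        def model(i, phi, theta, asat, rd):
            return _nrh(i, phi, theta, asat) - rd

        try:
            popt, _ = curve_fit(
                model, par, a, p0=[0.05, 0.7, asat0, rd0],
                bounds=([1e-4, 1e-3, 1e-3, 0.0],
                        [1.0, 1.0 - 1e-6, np.inf, np.inf]),
                maxfev=self.maxfev)
        except RuntimeError as err:
            raise RuntimeError(
                "light-response fit did not converge from start values "
                f"phi=0.05, theta=0.7, Asat={asat0:.1f}, Rd={rd0:.2f}: {err}"
            ) from err
        self.phi_, self.theta_, self.asat_, self.rd_ = map(float, popt)
        self.rss_ = float(np.sum((a - model(par, *popt)) ** 2))
        self.amax_ = float(model(I_REFERENCE, *popt))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "phi_")
        par = np.asarray(X, dtype=float)
        return _nrh(par, self.phi_, self.theta_, self.asat_) - self.rd_


class ACiCurve(BaseEstimator, RegressorMixin):
    """FvCB fit of net assimilation against intercellular CO2.

    Kinetic constants default to 25 degC values and are estimator
    parameters (Ci-basis, no mesophyll conductance; TPU limitation
    omitted as the protocol tops out at 1200 ppm).

    Attributes
    ----------
    vcmax_ : float
        Maximum Rubisco carboxylation rate, umol m-2 s-1.
    j_ : float
        Electron transport rate at the measurement irradiance
        (2000 umol m-2 s-1), i.e. the operational J_max.
    rd_ : float
        Day respiration, umol m-2 s-1.
    j_identifiable_ : bool
        False when no retained point is electron-transport-limited.
    """

    def __init__(self, gamma_star: float = GAMMA_STAR_25,
                 kc: float = KC_25, ko: float = KO_25,
                 o2: float = O2_MMOL, maxfev: int = 20000):
        self.gamma_star = gamma_star
        self.kc = kc
        self.ko = ko
        self.o2 = o2
        self.maxfev = maxfev

    @property
    def _km(self):
        return self.kc * (1.0 + self.o2 / self.ko)

    def _model(self, ci, vcmax, j, rd):
        ac = vcmax * (ci - self.gamma_star) / (ci + self._km)
        aj = j * (ci - self.gamma_star) / (4.0 * ci + 8.0 * self.gamma_star)
        return np.minimum(ac, aj) - rd

    def fit(self, X, y):
        ci = np.asarray(X, dtype=float).reshape(-1)
        a = np.asarray(y, dtype=float).reshape(-1)
        if ci.size < 7:
            raise ValueError("need >= 7 unflagged A-Ci points")
        vc0 = max(4.0 * a.max(), 10.0)
        j0 = max(6.0 * a.max(), 10.0)
        try:
            popt, _ = curve_fit(
                self._model, ci, a, p0=[vc0, j0, 1.0],
                bounds=([1e-3, 1e-3, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=self.maxfev)
        except RuntimeError as err:
            raise RuntimeError(
                f"A-Ci fit did not converge from start values Vcmax={vc0:.0f},"
                f" J={j0:.0f}, Rd=1: {err}") from err
        self.vcmax_, self.j_, self.rd_ = map(float, popt)
        self.rss_ = float(np.sum((a - self._model(ci, *popt)) ** 2))
        ac = self.vcmax_ * (ci - self.gamma_star) / (ci + self._km)
        aj = self.j_ * (ci - self.gamma_star) / (4.0 * ci + 8.0 * self.gamma_star)
        self.n_rubisco_limited_ = int(np.sum(ac <= aj))
        self.n_j_limited_ = int(np.sum(aj < ac))
        # A limitation is identifiable only if dropping it makes the fit
        # worse: compare against single-limitation refits.
        rss_ac = self._single_branch_rss(ci, a, "ac")
        rss_aj = self._single_branch_rss(ci, a, "aj")
        best = min(self.rss_, rss_ac, rss_aj)
        floor = 1.05 * best + 1e-8 * max(float(np.sum(a * a)), 1.0)
        self.j_identifiable_ = rss_ac > floor
        self.vcmax_identifiable_ = rss_aj > floor
        if not self.j_identifiable_:
            warnings.warn(
                f"Rubisco-only model fits equally well over Ci span "
                f"[{ci.min():.0f}, {ci.max():.0f}] ppm: J unidentifiable",
                stacklevel=2)
        if not self.vcmax_identifiable_:
            warnings.warn(
                f"electron-transport-only model fits equally well over Ci "
                f"span [{ci.min():.0f}, {ci.max():.0f}] ppm: Vcmax "
                "unidentifiable", stacklevel=2)
        self.n_features_in_ = 1
        return self

    def _single_branch_rss(self, ci, a, branch):
        """Best RSS achievable with one limitation only."""
        if branch == "ac":
            def model(ci_, v, rd):
                return v * (ci_ - self.gamma_star) / (ci_ + self._km) - rd
        else:
            def model(ci_, j, rd):
                return j * (ci_ - self.gamma_star) \
                    / (4.0 * ci_ + 8.0 * self.gamma_star) - rd
        try:
            popt, _ = curve_fit(model, ci, a, p0=[100.0, 1.0],
                                bounds=([1e-3, 0.0], [np.inf, np.inf]),
                                maxfev=self.maxfev)
        except RuntimeError:
            return np.inf
        return float(np.sum((a - model(ci, *popt)) ** 2))

    def predict(self, X):
        check_is_fitted(self, "vcmax_")
        ci = np.asarray(X, dtype=float)
        return self._model(ci, self.vcmax_, self.j_, self.rd_)

    def jmax_capacity(self, phi: float, theta: float) -> float:
        """NRH capacity implied by the fitted J at I = 2000.

        ``phi`` and ``theta`` come from the companion light curve; the
        assimilation-basis quantum yield is scaled by 4 electrons per
        CO2.
        """
        check_is_fitted(self, "j_")
        return nrh_capacity_from_rate(self.j_, 4.0 * phi, theta)


def fit_light_response(curve: ResponseCurve, **kwargs) -> LightResponseCurve:
    """Fit the non-rectangular hyperbola to a cleaned light curve."""
    keep = curve.unflagged()
    return LightResponseCurve(**kwargs).fit(curve.driver[keep],
                                            curve.a_net[keep])


def fit_aci(curve: ResponseCurve, **kwargs) -> ACiCurve:
    """Fit the FvCB model to a cleaned CO2 curve (on Ci where given)."""
    keep = curve.unflagged()
    x = curve.ci if curve.ci is not None else curve.driver
    return ACiCurve(**kwargs).fit(x[keep], curve.a_net[keep])


def pool_species(tree_values, tree_se=None) -> PooledEstimate:
    """Species-level pooling of per-tree parameter estimates.

    Closed-form empirical-Bayes shrinkage toward the species mean with
    90/95% intervals; a single tree passes through with a degenerate
    interval (warned).
    """
    return pool_estimates(tree_values, tree_se)
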