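"""Shoot drying curves: RWC bookkeeping, saturated water content,
the exponential RWC-water-potential decay and standardized capacitance.

A bench drying experiment repeatedly weighs a detached shoot while its
xylem water potential falls.  Leaves are excised at some steps (for
pressure-chamber readings), so the running product of fresh-mass ratios
in the relative water content (RWC) must use the post-excision mass of
the previous step as each ratio's denominator:

    RWC_i = (SM * prod_{k<=i} FM_before_k / FM_after_{k-1} - DM) / (SM - DM)

with RWC_1 = 1 by definition, SM the saturated (initial) mass and DM the
oven dry mass.  Saturated water content is SWC = (SM - DM)/DM.

The RWC-psi relation is summarised by an exponential decay anchored at
RWC(0) = 1, and hydraulic capacitance by the slope of the linear
post-stomatal-closure segment, standardized per unit dry mass:

    C_std = dRWC/dPsi * (SM - DM)[g] / DM[kg] / Mw   (mol kg-1 MPa-1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import MW_WATER

__all__ = [
    "DryingStep", "ShootDryingExperiment", "RWCCurve",
    "compute_rwc_series", "compute_swc", "rwc_at_psi",
    "ExpDecayCurve", "CapacitanceRegression", "compute_c_std",
    "fit_rwc_psi", "fit_capacitance",
]

#: Relative tolerance above which a fresh-mass ratio > 1 (mass gain
#: between weighings, an evaporation/condensation artifact) is flagged.
MASS_GAIN_RTOL = 1e-6

#: Leaf-psi pairs further apart than this (MPa) flag poor equilibration.
PSI_PAIR_MAX_SPREAD = 0.5


@dataclass
class DryingStep:
    """One weighing step of a shoot drying experiment."""

    fm_before_cut: float            # fresh mass before leaf excision, g
    excised_leaf_mass: float = 0.0  # g
    psi_leaf: tuple[float, float] = (np.nan, np.nan)  # two leaves, MPa
    timestamp: float | None = None  # seconds since start, optional

    @property
    def fm_after_cut(self) -> float:
        return self.fm_before_cut - self.excised_leaf_mass

    def __post_init__(self):
        if self.excised_leaf_mass < 0:
            raise ValueError("excised leaf mass must be >= 0")
        psis = [p for p in self.psi_leaf if np.isfinite(p)]
        if any(p > 0 for p in psis):
            raise ValueError("leaf water potentials must be <= 0 MPa")


@dataclass
class ShootDryingExperiment:
    """A branch's full drying protocol with terminal dry mass."""

    branch_id: str
    sm: float                      # saturated (initial) mass, g
    dm: float                      # oven dry mass, g
    steps: list[DryingStep] = field(default_factory=list)

    def __post_init__(self):
        if not (self.sm > self.dm > 0):
            raise ValueError(
                f"need SM > DM > 0, got SM={self.sm}, DM={self.dm}")


@dataclass
class RWCCurve:
    """Per-step relative water content paired with mean leaf psi."""

    branch_id: str
    rwc: np.ndarray
    psi: np.ndarray
    mass_gain_flags: np.ndarray      # bool per step
    psi_spread_flags: np.ndarray     # bool per step


def compute_rwc_series(exp: ShootDryingExperiment) -> RWCCurve:
    """Relative water content per drying step (RWC_1 = 1 by definition).

    Each ratio divides the current step's pre-excision fresh mass by the
    previous step's post-excision mass, so excised leaf mass does not
    count as evaporative loss.  Mass-gain steps are retained but flagged.
    """
    if not exp.steps:
        raise ValueError("experiment has no drying steps")
    n = len(exp.steps)
    rwc = np.empty(n)
    psi = np.empty(n)
    gain = np.zeros(n, dtype=bool)
    spread = np.zeros(n, dtype=bool)

    prod = 1.0
    for i, step in enumerate(exp.steps):
        if i == 0:
            rwc[i] = 1.0
        else:
            prev = exp.steps[i - 1]
            if prev.fm_after_cut <= 0:
                raise ValueError(f"non-positive post-excision mass at step {i}")
            ratio = step.fm_before_cut / prev.fm_after_cut
            if ratio > 1.0 + MASS_GAIN_RTOL:
                gain[i] = True
                warnings.warn(
                    f"branch {exp.branch_id}: mass gain at step {i + 1} "
                    f"(ratio {ratio:.6f}); step retained", stacklevel=2)
            prod *= ratio
            rwc[i] = (exp.sm * prod - exp.dm) / (exp.sm - exp.dm)
        pair = np.asarray(step.psi_leaf, dtype=float)
        finite = pair[np.isfinite(pair)]
        psi[i] = np.mean(finite) if finite.size else np.nan
        if finite.size == 2 and abs(finite[0] - finite[1]) > PSI_PAIR_MAX_SPREAD:
            spread[i] = True
    return RWCCurve(exp.branch_id, rwc, psi, gain, spread)


def compute_swc(exp: ShootDryingExperiment) -> float:
    """Whole-shoot saturated water content (SM - DM)/DM, g g-1."""
    if exp.dm <= 0:
        raise ValueError("dry mass must be positive")
    return (exp.sm - exp.dm) / exp.dm


def _decay(psi, residual, rate):
    return residual + (1.0 - residual) * np.exp(rate * psi)


class ExpDecayCurve(BaseEstimator, RegressorMixin):
    """Exponential decay of RWC with water potential, anchored at RWC(0)=1.

        RWC(psi) = residual + (1 - residual) * exp(rate * psi),  psi <= 0

    Two free parameters: the asymptotic residual water fraction and the
    decay rate (MPa-1).  After fitting, the model is compared on RSS
    against a straight line; ``beats_linear_`` records whether the decay
    describes the data better, the acceptance condition used for this
    family.

    Attributes
    ----------
    residual_ : float
        Asymptotic RWC as psi -> -inf, in [0, 1).
    rate_ : float
        Decay rate, MPa-1, > 0.
    rss_ : float
        Residual sum of squares of the decay fit.
    linear_rss_ : float
        RSS of the competing straight-line fit.
    beats_linear_ : bool
    """

    def __init__(self, maxfev: int = 10000):
        self.maxfev = maxfev

    def fit(self, X, y):
        psi = np.asarray(X, dtype=float).reshape(-1)
        rwc = np.asarray(y, dtype=float).reshape(-1)
        ok = np.isfinite(psi) & np.isfinite(rwc)
        psi, rwc = psi[ok], rwc[ok]
        if psi.size < 5:
            raise ValueError("need >= 5 (RWC, psi) points")
        if psi.max() - psi.min() < 2.0:
            raise ValueError(
                f"psi span {psi.max() - psi.min():.2f} MPa < 2 MPa")
        if np.any(psi > 0):
            raise ValueError("water potentials must be <= 0")
        r0 = max(min(rwc.min(), 0.9), 0.0)
        try:
            popt, _ = curve_fit(
                _decay, psi, rwc, p0=[r0, 0.5],
                bounds=([0.0, 1e-8], [1.0 - 1e-9, np.inf]),
                maxfev=self.maxfev)
        except RuntimeError as err:
            raise RuntimeError(
                f"exponential decay fit did not converge: {err}") from err
        self.residual_, self.rate_ = float(popt[0]), float(popt[1])
        self.rss_ = float(np.sum((rwc - _decay(psi, *popt)) ** 2))
        lin = linregress(psi, rwc)
        self.linear_rss_ = float(np.sum(
            (rwc - (lin.intercept + lin.slope * psi)) ** 2))
        self.beats_linear_ = bool(self.rss_ <= self.linear_rss_)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "rate_")
        psi = np.asarray(X, dtype=float)
        if np.any(psi > 0):
            raise ValueError("water potentials must be <= 0")
        return _decay(psi, self.residual_, self.rate_)


def rwc_at_psi(fit: ExpDecayCurve, psi: float) -> float:
    """Evaluate a fitted decay at one water potential (psi <= 0).

    With psi = psi_tlp this yields RWC_tlp; with psi = P50, RWC_50.
    """
    return float(fit.predict(np.atleast_1d(psi))[0])


class CapacitanceRegression(BaseEstimator, RegressorMixin):
    """Post-stomatal-closure linear RWC-psi slope and standardized capacitance.

    Stomatal closure splits the drying curve into a steep early segment
    and a shallow linear tail.  With ``closure_psi='auto'`` the breakpoint
    is chosen by grid search over interior points, minimizing the summed
    RSS of the two one-segment regressions; a numeric ``closure_psi``
    (e.g. the turgor loss point) overrides the search.

    Attributes
    ----------
    slope_ : float
        dRWC/dPsi over the post-closure segment, g g-1 MPa-1 (> 0 for a
        drying shoot: RWC falls as psi falls).
    breakpoint_psi_ : float
    n_post_ : int
        Points in the post-closure segment.
    """

    def __init__(self, closure_psi="auto", min_segment: int = 3):
        self.closure_psi = closure_psi
        self.min_segment = min_segment

    def fit(self, X, y):
        psi = np.asarray(X, dtype=float).reshape(-1)
        rwc = np.asarray(y, dtype=float).reshape(-1)
        ok = np.isfinite(psi) & np.isfinite(rwc)
        psi, rwc = psi[ok], rwc[ok]
        order = np.argsort(psi)[::-1]          # least to most negative
        psi, rwc = psi[order], rwc[order]
        n = psi.size
        if self.closure_psi == "auto":
            if n < 2 * self.min_segment:
                raise ValueError(
                    f"{n} points cannot hold two segments of "
                    f">= {self.min_segment}")
            best = (np.inf, None)
            for cut in range(self.min_segment, n - self.min_segment + 1):
                rss = (_seg_rss(psi[:cut], rwc[:cut])
                       + _seg_rss(psi[cut:], rwc[cut:]))
                if rss < best[0]:
                    best = (rss, cut)
            cut = best[1]
            self.breakpoint_psi_ = float(psi[cut - 1])
        else:
            self.breakpoint_psi_ = float(self.closure_psi)
            cut = int(np.searchsorted(-psi, -self.breakpoint_psi_))
        post_psi, post_rwc = psi[cut:], rwc[cut:]
        if post_psi.size < self.min_segment:
            raise ValueError(
                f"only {post_psi.size} points beyond closure at "
                f"{self.breakpoint_psi_} MPa (need >= {self.min_segment})")
        res = linregress(post_psi, post_rwc)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.rss_ = float(np.sum(
            (post_rwc - (res.intercept + res.slope * post_psi)) ** 2))
        self.n_post_ = int(post_psi.size)
        if self.slope_ <= 0:
            warnings.warn(
                "non-positive post-closure slope: RWC does not decline "
                "with psi over the selected segment", stacklevel=2)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        psi = np.asarray(X, dtype=float)
        return self.intercept_ + self.slope_ * psi

    def c_std(self, sm: float, dm: float) -> float:
        """Standardized capacitance, mol kg-1 MPa-1 (sm, dm in g)."""
        check_is_fitted(self, "slope_")
        return compute_c_std(self.slope_, sm, dm)


def _seg_rss(x, y):
    if np.ptp(x) == 0:
        return float(np.sum((y - np.mean(y)) ** 2))
    res = linregress(x, y)
    return float(np.sum((y - (res.intercept + res.slope * x)) ** 2))


def compute_c_std(slope: float, sm: float, dm: float) -> float:
    """Standardize a RWC-psi slope by stored water and dry mass.

    C_std = slope[g g-1 MPa-1] * (SM - DM)[g] / DM[kg] / Mw[g mol-1],
    giving mol kg-1 MPa-1.  SM and DM are both in grams.
    """
    if not (sm > dm > 0):
        raise ValueError("need SM > DM > 0")
    return slope * (sm - dm) / (dm / 1000.0) / MW_WATER


def fit_rwc_psi(curve: RWCCurve) -> ExpDecayCurve:
    """Fit the exponential decay to one branch's RWC curve."""
    return ExpDecayCurve().fit(curve.psi, curve.rwc)


def fit_capacitance(curve: RWCCurve, closure_psi="auto") -> CapacitanceRegression:
    """Fit the post-closure linear segment of one branch's RWC curve."""
    return CapacitanceRegression(closure_psi=closure_psi).fit(curve.psi, curve.rwc)
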