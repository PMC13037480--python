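"""Instrument-realistic synthetic data with recorded ground truth.

Every downstream stage has a forward model here that emulates the field
protocol it was designed for: shoot drying steps with leaf excisions,
Pneumatron pressure traces, leaf desiccation mass series, light/CO2
response tables, dendrometer band readings and monthly water-potential
campaigns.  Generators take a :class:`SpeciesTruth` (the parameters an
estimator should recover) and a :class:`GeneratorConfig` (protocol sizes
and per-instrument Gaussian noise levels) and return the instrument data
together with a ground-truth record, kept separate so estimators can
never read it by accident.

A fixed config seed makes every generator bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import DAYS_PER_YEAR, MMW_WATER, R_GAS
from .drying import DryingStep, ShootDryingExperiment
from .gas_exchange import (CO2_SEQUENCE, LIGHT_SEQUENCE, I_REFERENCE,
                           ResponseCurve, nrh_capacity_from_rate, _nrh)
from .leaf import LeafDesiccationSeries, compute_vpd
from .pneumatics import PneumatronSeries, PneumatronStep

__all__ = [
    "SpeciesTruth", "GeneratorConfig", "default_truth", "species_panel",
    "generate_drying_experiment", "generate_pneumatron_series",
    "generate_leaf_desiccation", "generate_response_curves",
    "generate_dendro_series", "generate_water_potentials",
    "rwc_composite", "psi_schedule",
]


@dataclass
class SpeciesTruth:
    """True parameter values a synthetic species is generated from."""

    species_id: str = "SYN"
    p50: float = -2.0                 # MPa
    vuln_slope: float = 9.0           # logistic steepness a, MPa-1
    swc: float = 1.2                  # g g-1
    capacitance_slope: float = 0.05   # post-closure dRWC/dPsi, g g-1 MPa-1
    rwc_residual: float = 0.2         # decay asymptote
    rwc_rate: float = 0.5             # decay rate, MPa-1
    closure_psi: float = -1.5         # stomatal closure breakpoint, MPa
    psi_tlp: float = -1.8             # MPa
    gmin: float = 5.0                 # mmol m-2 s-1
    sla: float = 80.0                 # cm2 g-1
    wd: float = 0.75                  # g cm-3
    vcmax: float = 120.0              # umol m-2 s-1
    jmax: float = 130.0               # J at I = 2000, umol m-2 s-1
    amax: float = 14.0                # umol m-2 s-1
    rd: float = 1.5                   # dark respiration, umol m-2 s-1
    phi: float = 0.06                 # quantum yield (CO2 basis)
    theta: float = 0.7                # NRH curvature
    adi: float = 7.0                  # nominal seasonal amplitude, mm
    pdgr: float = 30.0                # nominal peak rate, mm year-1

    def __post_init__(self):
        if self.p50 >= 0:
            raise ValueError("P50 must be negative")
        if self.psi_tlp >= 0:
            raise ValueError("psi_tlp must be negative")
        for name in ("vuln_slope", "swc", "capacitance_slope", "gmin",
                     "sla", "wd", "vcmax", "jmax", "amax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.wd < 1.5:
            raise ValueError("wood density must lie in (0, 1.5)")


@dataclass
class GeneratorConfig:
    """Protocol sizes and per-instrument noise levels.

    Defaults mirror the field protocols: 10 mg balance precision, four
    branches per species, about a dozen drying steps with increasing
    intervals, 0.5-s Pneumatron cadence over 1.5 min, 1.7-3 mL tubing,
    two rainfall years of band readings every 17 days.
    """

    n_species: int = 6
    n_branches: int = 4
    n_drying_steps: int = 12
    noise_mass_g: float = 0.01        # shoot balance, 10 mg
    noise_leaf_mass_g: float = 0.0005  # leaf balance, 0.5 mg
    noise_psi_mpa: float = 0.05
    noise_pressure_kpa: float = 0.5
    noise_a_rel: float = 0.03          # gas exchange, fraction of A_max
    noise_circ_mm: float = 0.2
    tubing_volume: float = 2.6e-6      # m3
    temperature: float = 293.15        # K
    dm_g: float = 10.0                 # shoot oven dry mass
    leaf_mass_fraction: float = 0.3    # of initial shoot mass
    excision_fraction: float = 0.1     # of current leaf mass, every 2nd step
    seed: int = 0

    def __post_init__(self):
        for name in ("n_species", "n_branches", "n_drying_steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("noise_mass_g", "noise_leaf_mass_g", "noise_psi_mpa",
                     "noise_pressure_kpa", "noise_a_rel", "noise_circ_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tubing_volume <= 0:
            raise ValueError("tubing volume must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_truth(**overrides) -> SpeciesTruth:
    """A representative synthetic species."""
    return SpeciesTruth(**overrides)


def species_panel(n: int = 6) -> list[SpeciesTruth]:
    """A panel of species spanning realistic savanna trait ranges."""
    grid = np.linspace(0.0, 1.0, n)
    panel = []
    for k, u in enumerate(grid):
        panel.append(SpeciesTruth(
            species_id=f"SP{k + 1}",
            p50=-6.5 + 5.0 * u,
            vuln_slope=5.5 + 2.5 * u,
            swc=0.95 + 0.7 * u,
            capacitance_slope=0.02 + 0.08 * u,
            psi_tlp=-3.0 + 1.6 * u,
            gmin=9.5 - 5.0 * u,
            sla=55.0 + 40.0 * u,
            wd=0.85 - 0.20 * u,
            vcmax=110.0 + 40.0 * u,
            jmax=115.0 + 20.0 * u,
            amax=11.0 + 4.0 * u,
            adi=5.0 + 5.0 * u,
            pdgr=22.0 + 12.0 * u,
        ))
    return panel


def psi_schedule(n_steps: int, start: float = -0.1,
                 stop: float = -10.0) -> np.ndarray:
    """Geometric drying schedule mirroring increasing drying intervals."""
    return -np.geomspace(-start, -stop, n_steps)


def rwc_composite(psi, truth: SpeciesTruth, anchor_psi: float = 0.0):
    """Forward RWC model: exponential decay with a linear post-closure tail.

    The exponential is anchored at ``anchor_psi`` (RWC = 1 there), and
    below ``truth.closure_psi`` the curve continues linearly with slope
    ``truth.capacitance_slope`` so the capacitance estimator has an
    exactly linear segment to recover.
    """
    psi = np.asarray(psi, dtype=float)
    res, rate = truth.rwc_residual, truth.rwc_rate
    decay = res + (1.0 - res) * np.exp(rate * (psi - anchor_psi))
    closure = truth.closure_psi
    r_closure = res + (1.0 - res) * np.exp(rate * (closure - anchor_psi))
    linear = r_closure + truth.capacitance_slope * (psi - closure)
    out = np.where(psi >= closure, decay, linear)
    return np.maximum(out, 1e-3)


def generate_drying_experiment(
        truth: SpeciesTruth, cfg: GeneratorConfig,
        schedule=None, rng=None, branch_id: str | None = None,
) -> tuple[ShootDryingExperiment, dict]:
    """One branch's drying protocol generated from known truth.

    The target RWC series is the composite curve evaluated on the psi
    schedule (anchored so RWC = 1 at the first step); step masses are
    obtained by inverting the RWC bookkeeping, leaf excisions of a fixed
    fraction happen at every second step, and Gaussian mass/psi noise is
    added to the recorded values.
    """
    rng = cfg.rng() if rng is None else rng
    psi = psi_schedule(cfg.n_drying_steps) if schedule is None \
        else np.asarray(schedule, dtype=float)
    if np.any(np.diff(psi) >= 0):
        raise ValueError("psi schedule must be strictly decreasing")
    rwc_true = rwc_composite(psi, truth, anchor_psi=psi[0])

    dm = cfg.dm_g
    sm = dm * (1.0 + truth.swc)
    # Invert the running-product bookkeeping: S_i = RWC_i*(SM-DM) + DM,
    # FM_before_i = FM_after_(i-1) * S_i / S_(i-1).
    s = rwc_true * (sm - dm) + dm
    leaf_mass = cfg.leaf_mass_fraction * sm
    steps = []
    fm_after_prev = None
    noisy_first = None
    for i, p in enumerate(psi):
        if i == 0:
            fm_before = sm
        else:
            fm_before = fm_after_prev * s[i] / s[i - 1]
        excised = 0.0
        if i > 0 and i % 2 == 1:          # every second step
            excised = cfg.excision_fraction * leaf_mass
            leaf_mass -= excised
        fm_after_prev = fm_before - excised
        fm_rec = fm_before + rng.normal(0.0, cfg.noise_mass_g)
        exc_rec = max(excised + rng.normal(0.0, cfg.noise_mass_g), 0.0) \
            if excised > 0 else 0.0
        psi_pair = tuple(np.minimum(
            p + rng.normal(0.0, cfg.noise_psi_mpa, 2), 0.0))
        if i == 0:
            noisy_first = fm_rec
        steps.append(DryingStep(fm_before_cut=fm_rec,
                                excised_leaf_mass=exc_rec,
                                psi_leaf=psi_pair))
    dm_rec = dm + rng.normal(0.0, cfg.noise_mass_g)
    exp = ShootDryingExperiment(
        branch_id=branch_id or f"{truth.species_id}-b1",
        sm=noisy_first, dm=dm_rec, steps=steps)
    ground_truth = {"swc": truth.swc,
                    "capacitance_slope": truth.capacitance_slope,
                    "closure_psi": truth.closure_psi,
                    "rwc_true": rwc_true, "psi_true": psi,
                    "sm": sm, "dm": dm}
    return exp, ground_truth


def generate_pneumatron_series(
        truth: SpeciesTruth, schedule, cfg: GeneratorConfig,
        rng=None, branch_id: str | None = None,
        dp_min_kpa: float = 2.0, dp_max_kpa: float = 45.0,
        trace_seconds: float = 90.0, cadence_s: float = 0.5,
        rise_tau_s: float = 20.0,
) -> tuple[PneumatronSeries, dict]:
    """Pneumatron pressure traces whose endpoints encode true PAD.

    Per step the true air discharge interpolates between the hydrated
    minimum and desiccated maximum along the logistic vulnerability
    curve; the trace is a saturating-exponential pressure rise sampled
    at 0.5 s with Gaussian pressure noise.
    """
    rng = cfg.rng() if rng is None else rng
    psi = np.asarray(schedule, dtype=float)
    if np.any(np.diff(psi) >= 0):
        raise ValueError("psi schedule must be strictly decreasing")
    if cfg.tubing_volume <= 0:
        raise ValueError("tubing volume must be positive")
    pad_true = 100.0 / (1.0 + np.exp(
        truth.vuln_slope * (psi - truth.p50)))
    dp = dp_min_kpa + (dp_max_kpa - dp_min_kpa) * pad_true / 100.0
    t = np.arange(0.0, trace_seconds, cadence_s)
    rise = (1.0 - np.exp(-t / rise_tau_s)) / (1.0 - np.exp(
        -t[-1] / rise_tau_s))
    p_base = 40.0                      # partial-vacuum baseline, kPa
    steps = []
    for p_xylem, delta in zip(psi, dp):
        trace = p_base + delta * rise \
            + rng.normal(0.0, cfg.noise_pressure_kpa, t.size)
        steps.append(PneumatronStep(psi=float(p_xylem), pressure_kpa=trace))
    series = PneumatronSeries(
        branch_id=branch_id or f"{truth.species_id}-p1",
        steps=steps, tubing_volume=cfg.tubing_volume,
        temperature=cfg.temperature)
    ad_true = dp * 1000.0 * cfg.tubing_volume / (R_GAS * cfg.temperature)
    ground_truth = {"p50": truth.p50, "vuln_slope": truth.vuln_slope,
                    "pad_true": pad_true, "ad_true": ad_true}
    return series, ground_truth


def generate_leaf_desiccation(
        truth: SpeciesTruth, cfg: GeneratorConfig, rng=None,
        leaf_id: str | None = None, t_c: float = 25.0, rh: float = 50.0,
        p_amb_kpa: float = 101.3, area_projected_m2: float = 2.5e-3,
        duration_s: float = 5.5 * 3600, interval_s: float = 35 * 60,
        initial_mass_g: float = 1.5,
) -> tuple[LeafDesiccationSeries, dict]:
    """Constant-conductance evaporation of a detached leaf.

    Mass declines linearly at the rate implied by the true minimum
    conductance under the configured chamber conditions.
    """
    if rh >= 100:
        raise ValueError("RH >= 100%: no vapour pressure deficit to drive "
                         "evaporation")
    rng = cfg.rng() if rng is None else rng
    vpd = compute_vpd(t_c, rh)
    j = truth.gmin * vpd / p_amb_kpa           # mmol m-2 s-1
    slope = j * (2.0 * area_projected_m2) * MMW_WATER   # g s-1
    t = np.arange(0.0, duration_s + 1.0, interval_s)
    mass = initial_mass_g - slope * t \
        + rng.normal(0.0, cfg.noise_leaf_mass_g, t.size)
    series = LeafDesiccationSeries(
        leaf_id=leaf_id or f"{truth.species_id}-l1",
        time_s=t, mass_g=mass, area_projected_m2=area_projected_m2,
        t_c=t_c, rh=rh, p_amb_kpa=p_amb_kpa)
    return series, {"gmin": truth.gmin, "J": j, "slope_g_per_s": -slope}


def generate_response_curves(
        truth: SpeciesTruth, cfg: GeneratorConfig, rng=None,
        curve_id: str | None = None, ci_ratio: float = 0.7,
        inject_anomalies: bool = False, anomaly_factor: float = 0.75,
        anomaly_count: int = 2,
) -> tuple[dict[str, ResponseCurve], dict]:
    """Light and CO2 response curves from the NRH/FvCB forward model.

    The light-saturated gross rate is solved so the fitted curve's net
    rate at I = 2000 equals ``truth.amax``.  With ``inject_anomalies``
    the first ``anomaly_count`` 400-ppm recovery points after the 50-ppm
    step are perturbed by ``anomaly_factor`` (relative), exercising the
    cleaning rule.
    """
    rng = cfg.rng() if rng is None else rng
    cid = curve_id or f"{truth.species_id}-g1"
    noise_sd = cfg.noise_a_rel * truth.amax

    asat = nrh_capacity_from_rate(truth.amax + truth.rd, truth.phi,
                                  truth.theta, I_REFERENCE)
    par = np.array(LIGHT_SEQUENCE, dtype=float)
    a_light = _nrh(par, truth.phi, truth.theta, asat) - truth.rd
    a_light = a_light + rng.normal(0.0, noise_sd, par.size)
    light = ResponseCurve(f"{cid}-light", "light", par, a_light)

    ca = np.array(CO2_SEQUENCE, dtype=float)
    ci = ci_ratio * ca
    km = 404.9 * (1.0 + 210.0 / 278.4)
    ac = truth.vcmax * (ci - 42.75) / (ci + km)
    aj = truth.jmax * (ci - 42.75) / (4.0 * ci + 8.0 * 42.75)
    a_co2 = np.minimum(ac, aj) - truth.rd
    anomalous = []
    if inject_anomalies:
        low = np.flatnonzero(ca == 50)[-1]
        rec = np.flatnonzero((np.arange(ca.size) > low) & (ca == 400))
        anomalous = rec[:anomaly_count].tolist()
        a_co2[anomalous] *= (1.0 + anomaly_factor)
    a_co2 = a_co2 + rng.normal(0.0, noise_sd, ca.size)
    co2 = ResponseCurve(f"{cid}-co2", "co2", ca, a_co2, ci=ci)

    ground_truth = {"vcmax": truth.vcmax, "jmax": truth.jmax,
                    "amax": truth.amax, "rd": truth.rd, "phi": truth.phi,
                    "theta": truth.theta, "asat": asat,
                    "anomalous_indices": anomalous}
    return {"light": light, "co2": co2}, ground_truth


def _season_logistic(t_days, mid, amplitude, k):
    return amplitude / (1.0 + np.exp(-k * (t_days - mid)))


def generate_dendro_series(
        truth: SpeciesTruth, cfg: GeneratorConfig, rng=None,
        tree_id: str | None = None, start: str = "2021-11-15",
        n_years: int = 2, interval_days: int = 17,
        initial_diameter_mm: float = 50.0, shrinkage: bool = False,
        shrink_depth_mm: float = 0.5, shrink_width_days: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Band-circumference readings from a seasonal logistic growth curve.

    Each rainfall year contributes a logistic diameter ramp centred
    mid-wet-season whose amplitude is ``truth.adi`` and whose maximum
    annualised slope is ``truth.pdgr``; an optional Gaussian shrinkage
    episode mimics a growing-season dry spell.  Recorded truth is the
    generating curve's own net annual change and peak annualised slope,
    measured on a daily grid.
    """
    rng = cfg.rng() if rng is None else rng
    start_ts = pd.Timestamp(start)
    end_ts = start_ts + pd.Timedelta(days=int(365 * n_years) - 47)
    dates = pd.date_range(start_ts, end_ts, freq=f"{interval_days}D")
    t = (dates - start_ts).days.to_numpy(dtype=float)

    k = 4.0 * truth.pdgr / (truth.adi * DAYS_PER_YEAR)      # day-1
    season_mids = []
    for year in range(n_years):
        # Mid wet season: 1 February, the November-April midpoint.
        mid = (pd.Timestamp(year=start_ts.year + year + 1, month=2, day=1)
               - start_ts).days
        season_mids.append(float(mid))

    def diameter(tt):
        d = np.full_like(np.asarray(tt, dtype=float), initial_diameter_mm)
        for mid in season_mids:
            d = d + _season_logistic(np.asarray(tt, dtype=float),
                                     mid, truth.adi, k)
        if shrinkage:
            for mid in season_mids:
                d = d - shrink_depth_mm * np.exp(
                    -0.5 * ((np.asarray(tt, dtype=float) - (mid + 30.0))
                            / shrink_width_days) ** 2)
        return d

    circ = np.pi * diameter(t) + rng.normal(0.0, cfg.noise_circ_mm, t.size)
    df = pd.DataFrame({
        "tree_id": tree_id or f"{truth.species_id}-t1",
        "species": truth.species_id,
        "date": dates,
        "circumference_mm": circ,
    })

    grid = np.arange(t[0], t[-1] + 0.5)
    d_grid = diameter(grid)
    rate = np.gradient(d_grid, grid)
    # Net change per rainfall year of the generating curve itself.
    adi_years, season_years = [], []
    thr = 0.1 * rate.max()
    for year in range(n_years):
        y0 = (pd.Timestamp(year=start_ts.year + year, month=11, day=1)
              - start_ts).days
        y1 = (pd.Timestamp(year=start_ts.year + year + 1, month=11, day=1)
              - start_ts).days
        lo, hi = max(y0, grid[0]), min(y1, grid[-1])
        adi_years.append(float(diameter(hi) - diameter(lo)))
        m = (grid >= lo) & (grid < hi)
        above = np.flatnonzero(rate[m] > thr)
        if above.size:
            season_years.append(float(grid[m][above[-1]]
                                      - grid[m][above[0]]))
    ground_truth = {"adi": float(np.mean(adi_years)),
                    "adi_per_year": adi_years,
                    "pdgr": float(rate.max() * DAYS_PER_YEAR),
                    "season_length": float(np.mean(season_years))
                    if season_years else 0.0}
    return df, ground_truth


def generate_water_potentials(
        truth: SpeciesTruth, cfg: GeneratorConfig, rng=None,
        n_trees: int = 9, months=("2022-01", "2022-02", "2022-03"),
        psi_pd_base: float = -0.6, daily_drop: float = -1.0,
) -> pd.DataFrame:
    """Monthly predawn/midday campaign records with three soil depths."""
    rng = cfg.rng() if rng is None else rng
    rows = []
    for m, month in enumerate(months):
        date = pd.Period(month).to_timestamp() + pd.Timedelta(days=14)
        soil = psi_pd_base - 0.1 * m + np.array([0.0, -0.05, -0.1])
        for tree in range(n_trees):
            pd_psi = min(psi_pd_base - 0.1 * m
                         + rng.normal(0.0, cfg.noise_psi_mpa), 0.0)
            md_psi = pd_psi + daily_drop + rng.normal(0.0, cfg.noise_psi_mpa)
            rows.append({
                "tree_id": f"{truth.species_id}-t{tree + 1}",
                "species": truth.species_id, "date": date,
                "psi_pd": pd_psi, "psi_md": min(md_psi, pd_psi),
                "soil_psi_15cm": soil[0], "soil_psi_30cm": soil[1],
                "soil_psi_45cm": soil[2],
            })
    return pd.DataFrame(rows)


def truth_sidecar(truths: list[SpeciesTruth]) -> dict:
    """Ground-truth bundle for a species panel (sidecar, never embedded)."""
    return {t.species_id: {k: (float(v) if isinstance(v, (int, float,
                                                          np.floating)) else v)
                           for k, v in asdict(t).items()}
            for t in truths}
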