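"""End-to-end orchestration: simulate -> estimate -> integrate.

The pipeline reads whichever instrument CSVs the configuration names,
runs each estimation stage, writes per-branch/per-species outputs with
provenance headers (input hashes, config hash, package version) and
finishes with the trait matrix, its correlation structure and PCA.  A
stage failure halts the run with the stage named; outputs written by
earlier stages are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, drying, gas_exchange, growth, io, leaf, pneumatics
from .integrate import TraitPCA, build_trait_matrix, correlation_matrix
from .stats import t_interval
from .synth import (GeneratorConfig, generate_dendro_series,
                    generate_drying_experiment, generate_leaf_desiccation,
                    generate_pneumatron_series, generate_response_curves,
                    generate_water_potentials, psi_schedule, species_panel,
                    truth_sidecar)

log = logging.getLogger("hydrotraits.pipeline")

_KNOWN_KEYS = {"inputs", "out_dir", "seed", "params"}
_KNOWN_PARAMS = {"closure_psi", "clean_threshold", "gmin_skip_initial_s",
                 "tubing_volume", "temperature", "tlp_temperature_c",
                 "pca_standardize"}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    inputs: dict = field(default_factory=dict)
    out_dir: str = "outputs"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.inputs) - set(io.SCHEMAS)
        if unknown - {"trait_matrix"}:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        bad = set(self.params) - _KNOWN_PARAMS
        if bad:
            raise ValueError(f"unknown parameter keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {"inputs": self.inputs, "seed": self.seed, "params": self.params},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_inputs(out_dir, cfg: GeneratorConfig) -> dict:
    """Generate the full synthetic instrument panel plus truth sidecar.

    Returns the input-path mapping usable as ``PipelineConfig.inputs``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()
    panel = species_panel(cfg.n_species)

    drying_rows, step_rows, trace_rows = [], [], []
    des_rows, osm_rows, morph_rows, wood_rows = [], [], [], []
    gas_rows, dendro_frames, wp_frames = [], [], []
    for truth in panel:
        for b in range(cfg.n_branches):
            bid = f"{truth.species_id}-b{b + 1}"
            exp, _ = generate_drying_experiment(truth, cfg, rng=rng,
                                                branch_id=bid)
            for k, st in enumerate(exp.steps):
                drying_rows.append({
                    "branch_id": bid, "species": truth.species_id,
                    "step": k + 1, "sm_g": exp.sm, "dm_g": exp.dm,
                    "fm_before_cut_g": st.fm_before_cut,
                    "excised_leaf_mass_g": st.excised_leaf_mass,
                    "psi_leaf1_mpa": st.psi_leaf[0],
                    "psi_leaf2_mpa": st.psi_leaf[1]})
            series, _ = generate_pneumatron_series(
                truth, psi_schedule(cfg.n_drying_steps), cfg, rng=rng,
                branch_id=bid)
            for k, st in enumerate(series.steps):
                step_rows.append({"branch_id": bid,
                                  "species": truth.species_id,
                                  "step": k + 1, "psi_mpa": st.psi})
                tt = np.arange(st.pressure_kpa.size) * 0.5
                trace_rows.append(pd.DataFrame({
                    "branch_id": bid, "step": k + 1, "time_s": tt,
                    "pressure_kpa": st.pressure_kpa}))
        for tree in range(4):
            tid = f"{truth.species_id}-t{tree + 1}"
            ser, _ = generate_leaf_desiccation(truth, cfg, rng=rng,
                                               leaf_id=f"{tid}-l1")
            des_rows.append(pd.DataFrame({
                "leaf_id": ser.leaf_id, "species": truth.species_id,
                "time_s": ser.time_s, "mass_g": ser.mass_g,
                "area_projected_m2": ser.area_projected_m2,
                "t_c": ser.t_c, "rh": ser.rh, "p_amb_kpa": ser.p_amb_kpa}))
            rt = 8.3145e-3 * 298.15
            osmolality = -(truth.psi_tlp + 0.631) / 0.832 / rt * 1000.0
            osm_rows.append({"tree_id": tid, "species": truth.species_id,
                             "osmolality_mmol_kg": osmolality})
            for lf in range(3):
                area = float(rng.uniform(20.0, 40.0))
                morph_rows.append({
                    "tree_id": tid, "species": truth.species_id,
                    "leaf_id": f"{tid}-m{lf + 1}", "area_cm2": area,
                    "dry_mass_g": area / truth.sla})
            wood_rows.append({"branch_id": f"{tid}-w", "species":
                              truth.species_id, "dry_mass_g": truth.wd * 2.0,
                              "fresh_volume_cm3": 2.0})
            curves, _ = generate_response_curves(truth, cfg, rng=rng,
                                                 curve_id=tid)
            for kind, cv in curves.items():
                gas_rows.append(pd.DataFrame({
                    "curve_id": cv.curve_id, "species": truth.species_id,
                    "kind": kind, "driver": cv.driver,
                    "a_umol_m2_s": cv.a_net,
                    "ci_ppm": cv.ci if cv.ci is not None else cv.driver}))
        for tree in range(4):
            df, _ = generate_dendro_series(
                truth, cfg, rng=rng, tree_id=f"{truth.species_id}-t{tree + 1}")
            dendro_frames.append(df)
        wp_frames.append(generate_water_potentials(truth, cfg, rng=rng,
                                                   n_trees=4))

    paths = {}

    def _dump(name, df, schema):
        p = out / f"{name}.csv"
        io.write_csv(df, p, schema=schema, provenance={"seed": cfg.seed})
        paths[schema] = str(p)

    _dump("drying", pd.DataFrame(drying_rows), "drying")
    _dump("pneumatron_steps", pd.DataFrame(step_rows), "pneumatron_steps")
    _dump("pneumatron_trace", pd.concat(trace_rows, ignore_index=True),
          "pneumatron_trace")
    _dump("desiccation", pd.concat(des_rows, ignore_index=True),
          "desiccation")
    _dump("osmometry", pd.DataFrame(osm_rows), "osmometry")
    _dump("morphology", pd.DataFrame(morph_rows), "morphology")
    _dump("wood", pd.DataFrame(wood_rows), "wood")
    _dump("gas", pd.concat(gas_rows, ignore_index=True), "gas")
    _dump("dendro", pd.concat(dendro_frames, ignore_index=True), "dendro")
    _dump("water_potential", pd.concat(wp_frames, ignore_index=True),
          "water_potential")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_sidecar(panel), fh, sort_keys=True)
    return paths


def _species_rows(trait, species_values):
    return pd.DataFrame([{"species": sp, "trait": trait, "value": v}
                         for sp, v in species_values.items()])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns a result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config": config.digest(), "seed": config.seed}
    for key, path in config.inputs.items():
        prov[f"input_{key}"] = io.file_sha256(path)
    summaries: list[pd.DataFrame] = []
    results: dict = {"outputs": [], "warnings": 0}
    decay_fits: dict[str, tuple[float, float]] = {}
    species_p50: dict[str, float] = {}
    species_tlp: dict[str, float] = {}
    params = config.params

    def _write(name, df):
        p = out / f"{name}.csv"
        io.write_csv(df, p, provenance=prov)
        results["outputs"].append(str(p))

    def _stage(name):
        log.info("stage %s", name)

    # ---- drying --------------------------------------------------------
    if "drying" in config.inputs:
        _stage("drying")
        try:
            df = io.read_csv(config.inputs["drying"], "drying")
            rows = []
            by_species_curves: dict[str, list] = {}
            for bid, sub in df.groupby("branch_id", sort=True):
                sub = sub.sort_values("step")
                steps = [drying.DryingStep(
                    fm_before_cut=r.fm_before_cut_g,
                    excised_leaf_mass=r.excised_leaf_mass_g,
                    psi_leaf=(r.psi_leaf1_mpa, r.psi_leaf2_mpa))
                    for r in sub.itertuples()]
                exp = drying.ShootDryingExperiment(
                    branch_id=str(bid), sm=float(sub.sm_g.iloc[0]),
                    dm=float(sub.dm_g.iloc[0]), steps=steps)
                curve = drying.compute_rwc_series(exp)
                cap = drying.fit_capacitance(
                    curve, closure_psi=params.get("closure_psi", "auto"))
                dec = drying.fit_rwc_psi(curve)
                sp = str(sub.species.iloc[0])
                by_species_curves.setdefault(sp, []).append(
                    (dec.residual_, dec.rate_))
                rows.append({
                    "branch_id": bid, "species": sp,
                    "swc": drying.compute_swc(exp),
                    "cap_slope": cap.slope_,
                    "breakpoint_psi": cap.breakpoint_psi_,
                    "c_std": cap.c_std(exp.sm, exp.dm),
                    "decay_residual": dec.residual_,
                    "decay_rate": dec.rate_, "decay_rss": dec.rss_,
                    "beats_linear": dec.beats_linear_})
            branches = pd.DataFrame(rows)
            _write("drying_branches", branches)
            for sp, fits in by_species_curves.items():
                arr = np.array(fits)
                decay_fits[sp] = (float(arr[:, 0].mean()),
                                  float(arr[:, 1].mean()))
            sp_mean = branches.groupby("species").agg(
                swc=("swc", "mean"), c_std=("c_std", "mean"))
            _write("drying_species", sp_mean.reset_index())
            summaries.append(_species_rows("SWC_br", sp_mean["swc"].to_dict()))
            summaries.append(_species_rows("C_std", sp_mean["c_std"].to_dict()))
        except Exception as err:
            raise StageError(f"stage 'drying' failed: {err}") from err

    # ---- pneumatics ----------------------------------------------------
    if "pneumatron_trace" in config.inputs and \
            "pneumatron_steps" in config.inputs:
        _stage("pneumatic")
        try:
            traces = io.read_csv(config.inputs["pneumatron_trace"],
                                 "pneumatron_trace")
            steps = io.read_csv(config.inputs["pneumatron_steps"],
                                "pneumatron_steps")
            vol = params.get("tubing_volume", 2.6e-6)
            temp = params.get("temperature", 293.15)
            rows = []
            for bid, sub in steps.groupby("branch_id", sort=True):
                br_tr = traces[traces.branch_id == bid]
                plist = []
                for r in sub.sort_values("step").itertuples():
                    tr = br_tr[br_tr.step == r.step].sort_values("time_s")
                    plist.append(pneumatics.PneumatronStep(
                        psi=float(r.psi_mpa),
                        pressure_kpa=tr.pressure_kpa.to_numpy()))
                series = pneumatics.PneumatronSeries(
                    branch_id=str(bid), steps=plist,
                    tubing_volume=vol, temperature=temp)
                pad = pneumatics.compute_pad(series)
                fit = pneumatics.fit_vulnerability(pad)
                rows.append({"branch_id": bid,
                             "species": str(sub.species.iloc[0]),
                             "p50": fit.p50_, "slope_a": fit.slope_a_,
                             "p12": fit.p12_, "p88": fit.p88_,
                             "rss": fit.rss_})
            branches = pd.DataFrame(rows)
            _write("vulnerability_branches", branches)
            sp = branches.groupby("species")["p50"].agg(["mean", list])
            out_rows = []
            for name, row in sp.iterrows():
                lo, hi = t_interval(row["list"], 0.95)
                out_rows.append({"species": name, "p50": row["mean"],
                                 "p50_ci_lo": lo, "p50_ci_hi": hi})
                species_p50[name] = float(row["mean"])
            _write("vulnerability_species", pd.DataFrame(out_rows))
            summaries.append(_species_rows("P50", species_p50))
        except StageError:
            raise
        except Exception as err:
            raise StageError(f"stage 'pneumatic' failed: {err}") from err

    # ---- leaf + wood ---------------------------------------------------
    _stage("leaf")
    try:
        leaf_summaries = {}
        if "osmometry" in config.inputs:
            osm = io.read_csv(config.inputs["osmometry"], "osmometry")
            t_c = params.get("tlp_temperature_c", 25.0)
            osm["psi_tlp"] = [
                leaf.psi_tlp_from_osmolality(v, t_c).psi_tlp
                for v in osm.osmolality_mmol_kg]
            sp = osm.groupby("species")["psi_tlp"].mean()
            species_tlp.update(sp.to_dict())
            leaf_summaries["psi_tlp"] = sp.to_dict()
        if "morphology" in config.inputs:
            mor = io.read_csv(config.inputs["morphology"], "morphology")
            tree_sla = mor.groupby(["species", "tree_id"]).apply(
                lambda g: leaf.compute_sla(g.area_cm2, g.dry_mass_g),
                include_groups=False)
            leaf_summaries["SLA"] = tree_sla.groupby(level=0).mean().to_dict()
        if "desiccation" in config.inputs:
            des = io.read_csv(config.inputs["desiccation"], "desiccation")
            skip = params.get("gmin_skip_initial_s", 1800.0)
            rows = []
            for lid, sub in des.groupby("leaf_id", sort=True):
                sub = sub.sort_values("time_s")
                ser = leaf.LeafDesiccationSeries(
                    leaf_id=str(lid), time_s=sub.time_s.to_numpy(),
                    mass_g=sub.mass_g.to_numpy(),
                    area_projected_m2=float(sub.area_projected_m2.iloc[0]),
                    t_c=float(sub.t_c.iloc[0]), rh=float(sub.rh.iloc[0]),
                    p_amb_kpa=float(sub.p_amb_kpa.iloc[0]))
                rows.append({"species": str(sub.species.iloc[0]),
                             "gmin": leaf.fit_gmin(ser, skip).gmin})
            gdf = pd.DataFrame(rows)
            leaf_summaries["g_min"] = gdf.groupby("species")["gmin"] \
                .mean().to_dict()
        if "wood" in config.inputs:
            wood = io.read_csv(config.inputs["wood"], "wood")
            wood["wd"] = [leaf.compute_wd(m, v) for m, v in
                          zip(wood.dry_mass_g, wood.fresh_volume_cm3)]
            leaf_summaries["WD"] = wood.groupby("species")["wd"] \
                .mean().to_dict()
        if leaf_summaries:
            _write("leaf_species", pd.concat(
                [_species_rows(k, v) for k, v in leaf_summaries.items()],
                ignore_index=True))
            for k, v in leaf_summaries.items():
                summaries.append(_species_rows(k, v))
    except Exception as err:
        raise StageError(f"stage 'leaf' failed: {err}") from err

    # ---- gas exchange --------------------------------------------------
    if "gas" in config.inputs:
        _stage("gas")
        try:
            gas = io.read_csv(config.inputs["gas"], "gas")
            thr = params.get("clean_threshold", 0.15)
            fits = []
            for cid, sub in gas.groupby("curve_id", sort=True):
                kind = str(sub.kind.iloc[0])
                cv = gas_exchange.ResponseCurve(
                    str(cid), kind, sub.driver.to_numpy(),
                    sub.a_umol_m2_s.to_numpy(),
                    ci=sub.ci_ppm.to_numpy() if kind == "co2" else None)
                gas_exchange.clean_response_curve(cv, threshold=thr)
                sp_name = str(sub.species.iloc[0])
                if kind == "light":
                    f = gas_exchange.fit_light_response(cv)
                    fits.append({"curve_id": cid, "species": sp_name,
                                 "kind": kind, "amax": f.amax_,
                                 "phi": f.phi_, "theta": f.theta_,
                                 "rd": f.rd_})
                else:
                    f = gas_exchange.fit_aci(cv)
                    fits.append({"curve_id": cid, "species": sp_name,
                                 "kind": kind, "vcmax": f.vcmax_,
                                 "j2000": f.j_, "rd": f.rd_})
            fdf = pd.DataFrame(fits)
            _write("gas_curves", fdf)
            gas_sp = {}
            for trait, col, kind in (("A_max", "amax", "light"),
                                     ("Vc_max", "vcmax", "co2"),
                                     ("J_max", "j2000", "co2")):
                sub = fdf[fdf.kind == kind]
                pooled = {sp_name: gas_exchange.pool_species(
                    g[col].to_numpy()).mean
                    for sp_name, g in sub.groupby("species")}
                gas_sp[trait] = pooled
                summaries.append(_species_rows(trait, pooled))
            _write("gas_species", pd.concat(
                [_species_rows(k, v) for k, v in gas_sp.items()],
                ignore_index=True))
        except Exception as err:
            raise StageError(f"stage 'gas' failed: {err}") from err

    # ---- growth --------------------------------------------------------
    if "dendro" in config.inputs:
        _stage("growth")
        try:
            den = io.read_csv(config.inputs["dendro"], "dendro")
            rows = []
            for tid, sub in den.groupby("tree_id", sort=True):
                sub = sub.sort_values("date")
                diam = growth.band_to_diameter(
                    sub.circumference_mm.to_numpy())
                adi, _ = growth.compute_adi(sub.date, diam)
                rows.append({
                    "tree_id": tid, "species": str(sub.species.iloc[0]),
                    "adi": adi,
                    "pdgr": growth.compute_pdgr(sub.date, diam),
                    "season_days": growth.growing_season_length(
                        sub.date, diam),
                    "initial_diameter": float(diam[0])})
            tdf = pd.DataFrame(rows)
            _write("growth_trees", tdf)
            gr = {}
            for trait, col in (("ADI", "adi"), ("PDGR", "pdgr")):
                pooled = {sp_name: growth.shrink_species_estimates(
                    g[col].to_numpy(),
                    initial_size=g["initial_diameter"].to_numpy()).mean
                    for sp_name, g in tdf.groupby("species")}
                gr[trait] = pooled
                summaries.append(_species_rows(trait, pooled))
            _write("growth_species", pd.concat(
                [_species_rows(k, v) for k, v in gr.items()],
                ignore_index=True))
        except Exception as err:
            raise StageError(f"stage 'growth' failed: {err}") from err

    if "water_potential" in config.inputs:
        _stage("water_potentials")
        try:
            wp = io.read_csv(config.inputs["water_potential"],
                             "water_potential")
            _write("water_potentials_monthly",
                   growth.summarize_water_potentials(wp))
        except Exception as err:
            raise StageError(
                f"stage 'water_potentials' failed: {err}") from err

    # ---- derived RWC thresholds ---------------------------------------
    if decay_fits and species_tlp:
        rows = []
        for sp_name, (res, rate) in decay_fits.items():
            tlp = species_tlp.get(sp_name)
            if tlp is None:
                continue
            rwc_tlp = res + (1 - res) * np.exp(rate * tlp)
            row = {"species": sp_name, "RWC_tlp": rwc_tlp}
            if sp_name in species_p50:
                row["RWC_50"] = res + (1 - res) * np.exp(
                    rate * species_p50[sp_name])
            rows.append(row)
        if rows:
            rwc_df = pd.DataFrame(rows)
            _write("rwc_thresholds", rwc_df)
            summaries.append(_species_rows(
                "RWC_tlp", dict(zip(rwc_df.species, rwc_df.RWC_tlp))))

    # ---- integration ---------------------------------------------------
    _stage("integrate")
    try:
        if "trait_matrix" in config.inputs:
            matrix = pd.read_csv(config.inputs["trait_matrix"], comment="#",
                                 index_col="species")
        elif summaries:
            matrix, missing = build_trait_matrix(summaries)
            if missing:
                log.warning("missing trait cells: %s", missing)
        else:
            raise ValueError("no trait matrix input and no stage summaries")
        _write("trait_matrix", matrix.reset_index())
        usable = matrix.dropna(axis=1)
        corr = correlation_matrix(usable)
        _write("correlations_r", corr.r.reset_index(names="trait"))
        _write("correlations_p", corr.p.reset_index(names="trait"))
        _write("correlations_flags",
               corr.flags.reset_index(names="trait"))
        pca = TraitPCA(standardize=params.get("pca_standardize", True))
        pca.fit(usable)
        _write("pca_variance", pd.DataFrame({
            "component": [f"PC{k + 1}" for k in
                          range(pca.variance_explained_.size)],
            "variance_pct": pca.variance_explained_}))
        _write("pca_loadings", pca.loadings_.reset_index(names="trait"))
        _write("pca_scores", pca.scores_.reset_index(names="species"))
        results["trait_matrix"] = matrix
        results["correlations"] = corr
        results["pca"] = pca
    except Exception as err:
        raise StageError(f"stage 'integrate' failed: {err}") from err

    return results
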