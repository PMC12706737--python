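"""End-to-end orchestration: simulate -> flux -> disperse -> sample -> stats.

The pipeline runs the full source-attribution analysis with one config and
one seed: synthetic (or user-supplied) water and meteorology feed the
two-film flux stage; the flux drives a Gaussian-plume area source to give
predicted receptor concentrations; "measured" air is the plume's water
contribution plus an urban non-water component, pushed through the PUF-PAS
forward model and inverted back; profile and spatial statistics then
compare predicted with measured, ending in a predicted/measured
attribution summary.

Every run can write a manifest (config, seed, package version) sufficient
to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, flux as flux_mod, plume, profiles, pufpas, spatial, synth
from . import properties as props_mod

log = logging.getLogger("harborair")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str | None = None
    # optional real inputs (CSV); None -> synthesize
    water_csv: str | None = None
    met_csv: str | None = None
    properties_csv: str | None = None
    # stage parameters
    synthetic: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    coefficient_preset: str = "calibrated"
    area_m2: float = 1.5e7
    k_highest: int = 3
    worst_case_total: float | None = None  # rescale worst-case ΣPCB (pg L-1)
    n_iter_mc: int = 10_000
    cell_size: float = 250.0
    urban: bool = True
    fallback_rs: float = 4.9  # m3 d-1, model sampling rate when DCs invalid
    near_m: float = 200.0
    far_m: float = 2200.0
    n_perm: int = 999

    def validate(self) -> "RunConfig":
        for name in ("water_csv", "met_csv", "properties_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if self.coefficient_preset not in flux_mod.COEFFICIENT_PRESETS:
            raise ValueError(f"unknown coefficient preset {self.coefficient_preset!r}")
        self.synthetic.validate()
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = synth.SyntheticConfig(**raw.pop("synthetic", {}))
        cfg = cls(synthetic=syn, **raw)
        if "seed" in raw:
            cfg.synthetic.seed = cfg.seed
        return cfg.validate()


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in dependency order; returns a results dict."""
    cfg.validate()
    cfg.synthetic.seed = cfg.seed
    t_start = time.time()
    qc: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.time()
        return name

    def done(name):
        timings[name] = round(time.time() - timings[name], 2)

    # -- properties ---------------------------------------------------------
    stage("properties")
    table = (props_mod.load_congener_table(cfg.properties_csv)
             if cfg.properties_csv else props_mod.default_table())
    done("properties")

    # -- simulate -----------------------------------------------------------
    stage("simulate")
    water = (pd.read_csv(cfg.water_csv) if cfg.water_csv
             else synth.generate_water_samples(cfg.synthetic, table))
    met = (pd.read_csv(cfg.met_csv, parse_dates=["timestamp"]) if cfg.met_csv
           else synth.generate_met(cfg.synthetic))
    sites = synth.generate_puf_sites(cfg.synthetic)
    done("simulate")

    # -- flux ---------------------------------------------------------------
    stage("flux")
    coeffs = flux_mod.COEFFICIENT_PRESETS[cfg.coefficient_preset]
    worst = flux_mod.select_worst_case(water, cfg.k_highest)
    if cfg.worst_case_total is not None:
        worst = worst / worst.sum() * cfg.worst_case_total
    flux_df = flux_mod.compute_fluxes(worst, met, table, coeffs, cfg.area_m2)
    mc = flux_mod.monte_carlo_flux(worst, met, table, n_iter=cfg.n_iter_mc,
                                   seed=cfg.seed + 10, coeffs=coeffs)
    flux_df = flux_df.join(mc["per_peak"])
    done("flux")

    # -- disperse -----------------------------------------------------------
    stage("disperse")
    src = plume.AreaSource(plume.default_source_polygon(area_m2=cfg.area_m2),
                           flux_df["flux"])
    disp = plume.period_average(src, sites, met, urban=cfg.urban,
                                cell_size=cfg.cell_size)
    predicted = disp["concentrations"]  # pg m-3
    if disp["n_calm"]:
        qc.append(f"{disp['n_calm']} calm hour(s) excluded from plume average")
    done("disperse")

    # -- sample (forward PUF model on measured truth, then inversion) -------
    stage("sample")
    rng = np.random.default_rng(cfg.seed + 20)
    urban_air = synth.generate_true_air(cfg.synthetic, table, sites)
    true_air = urban_air.add(predicted, fill_value=0.0)
    rs_true = pd.Series(
        rng.uniform(*cfg.synthetic.rs_range, size=len(sites)),
        index=sites["site_id"], name="rs_true")
    puf = synth.generate_puf_dataset(cfg.synthetic, true_air, rs_true, table,
                                     sites=sites)
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        loq = pufpas.loq_from_blanks(puf["blanks"])
        qc.extend(str(w.message) for w in wlist)

    recs = {pid: r for pid, r in zip(
        table["peak_id"], props_mod.records_from_table(table))}
    t_avg_k = cfg.synthetic.mean_daily_temp + 273.15
    t_days = cfg.synthetic.deployment_days
    dc28 = puf["dc"][puf["dc"]["compound"] == "13C-PCB28"].set_index("site_id")
    rs_rows, measured_rows = [], []
    n_below = 0
    for sid in sites["site_id"]:
        est = pufpas.dc_sampling_rate(
            dc28.loc[sid, "initial_pg"], dc28.loc[sid, "final_pg"], t_days,
            recs[dc28.loc[sid, "surrogate_peak"]], site_id=sid,
            v_puf=cfg.synthetic.v_puf, t_avg_k=t_avg_k)
        rs = est.rs if est.valid else cfg.fallback_rs
        rs_rows.append({"site_id": sid, "rs": rs, "method": est.method if est.valid
                        else "model", "dc_valid": est.valid,
                        "dc_loss_fraction": est.dc_loss_fraction})
        masses = pufpas.recovery_correction(
            puf["masses"].loc[sid], puf["recoveries"].loc[sid])
        inv = pufpas.airborne_concentration(
            pd.Series(masses, index=puf["masses"].columns), rs, recs, loq,
            t_days, cfg.synthetic.v_puf, t_avg_k)
        n_below += int(inv["below_loq"].sum())
        measured_rows.append(inv["conc_pg_m3"].rename(sid))
    rs_table = pd.DataFrame(rs_rows).set_index("site_id")
    measured = pd.DataFrame(measured_rows)
    measured.index.name = "site_id"
    n_invalid = int((~rs_table["dc_valid"]).sum())
    if n_invalid:
        qc.append(f"DC sampling rate invalid (outside 20-80% loss) at "
                  f"{n_invalid} site(s); model fallback rs={cfg.fallback_rs} used")
    if n_below:
        qc.append(f"{n_below} peak measurement(s) below LOQ set to 0")
    done("sample")

    # -- stats --------------------------------------------------------------
    stage("stats")
    meas_sigma = measured.sum(axis=1)
    pred_sigma = predicted.sum(axis=1)
    air_profiles = {sid: profiles.normalize_profile(measured.loc[sid])
                    for sid in measured.index if measured.loc[sid].sum() > 0}
    refs = {name: props_mod.subset_profile(
        props_mod.load_aroclor_profile(name), measured.columns)
        for name in ("Aroclor1016", "Aroclor1242")}
    sim_report = profiles.profile_similarity_report(air_profiles, refs)
    water_profile = profiles.normalize_profile(
        water[flux_mod.peak_columns(water)].mean(axis=0))
    air_vs_water = profiles.cosine_similarity(
        profiles.mean_profile(air_profiles), water_profile)
    flux_profile = profiles.normalize_profile(flux_df["flux"])
    air_vs_flux = profiles.cosine_similarity(
        profiles.mean_profile(air_profiles), flux_profile)

    # collapse co-located replicate samplers to location means
    obs = sites.set_index("site_id").loc[meas_sigma.index].reset_index()
    obs["value"] = meas_sigma.to_numpy()
    obs = (obs.groupby("location")
           .agg({"x": "mean", "y": "mean", "distance_to_water": "mean",
                 "value": "mean"})
           .reset_index().rename(columns={"location": "site_id"}))
    loc_sigma = obs.set_index("site_id")["value"]
    reg = spatial.distance_regression(obs)
    moran = spatial.morans_i(obs, n_perm=cfg.n_perm, seed=cfg.seed + 30)
    krig = spatial.ordinary_kriging(obs)
    dists = obs.set_index("site_id")["distance_to_water"]
    near = loc_sigma[dists < cfg.near_m]
    far = loc_sigma[dists > cfg.far_m]
    ranksum = (spatial.ranksum_test(near, far)
               if len(near) >= 2 and len(far) >= 2 else None)
    done("stats")

    # -- attribution summary ------------------------------------------------
    ratio = (pred_sigma / meas_sigma).replace([np.inf, -np.inf], np.nan)
    summary = {
        "sigma_flux_ng_m2_d": float(flux_df["flux"].sum()),
        "flux_mc_mean": mc["total_mean"],
        "flux_mc_sd": mc["total_sd"],
        "sigma_emission_g_s": float(flux_df["emission"].sum()),
        "worst_case_total_pg_L": float(worst.sum()),
        "predicted_min_pg_m3": float(pred_sigma.min()),
        "predicted_median_pg_m3": float(pred_sigma.median()),
        "predicted_max_pg_m3": float(pred_sigma.max()),
        "measured_geomean_pg_m3": float(np.exp(np.log(meas_sigma[meas_sigma > 0]).mean())),
        "measured_median_pg_m3": float(meas_sigma.median()),
        "near_median_pg_m3": float(near.median()) if len(near) else np.nan,
        "far_median_pg_m3": float(far.median()) if len(far) else np.nan,
        "mean_pred_over_meas_ratio": float(ratio.mean()),
        "within_air_cos_mean": sim_report["pairwise_mean"],
        "within_air_cos_sd": sim_report["pairwise_sd"],
        "air_vs_water_cos": air_vs_water,
        "air_vs_flux_cos": air_vs_flux,
        "aroclor_cos_mean": sim_report["reference_mean"],
        "distance_regression": reg,
        "morans_i": moran,
        "kriging_loo_r2": krig["loo_r2"],
        "kriging_loo_rmse": krig["loo_rmse"],
        "ranksum_near_far": ranksum,
        "qc": qc,
    }

    results = {
        "table": table, "water": water, "met": met, "sites": sites,
        "worst_case": worst, "flux": flux_df, "predicted": predicted,
        "measured": measured, "rs_table": rs_table, "loq": loq,
        "similarity": sim_report, "summary": summary, "timings": timings,
    }

    if cfg.out_dir:
        _write_outputs(cfg, results)
    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return results


def _write_outputs(cfg: RunConfig, results: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["water"].to_csv(out / "water.csv", index=False)
    results["met"].to_csv(out / "met.csv", index=False)
    results["flux"].to_csv(out / "flux.csv")
    results["predicted"].to_csv(out / "predicted.csv")
    results["measured"].to_csv(out / "measured.csv")
    results["rs_table"].to_csv(out / "sampling_rates.csv")
    results["loq"].to_csv(out / "loq.csv")
    results["similarity"]["matrix"].to_csv(out / "cosine_matrix.csv")
    (out / "summary.json").write_text(
        json.dumps(results["summary"], indent=2, default=str))
    manifest = {
        "package": "harborair",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "config": dataclasses.asdict(cfg),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
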