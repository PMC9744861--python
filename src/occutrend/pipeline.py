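"""End-to-end orchestration: simulate -> prep -> occupancy -> trends ->
drivers -> regression -> scenarios.

Every stage reads and writes plain CSV/JSON under the configured output
directory, so runs are diffable and resumable; a YAML manifest records the
seed and a hash of the configuration.  All randomness flows from the
configured seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import prep, synthetic as syn
from .occupancy import OccupancyDesign, OccupancyModel, check_convergence
from .regression import TrendRegression, build_design, sensitivity_filter
from .scenarios import run_scenarios
from .trends import fit_window_trend, intervals_for, summarize_trends, trend_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]


@dataclass
class PipelineConfig:
    """Reproducible configuration of a full pipeline run."""

    outdir: str = "runs/demo"
    seed: int = 0
    interval_length: int = 5
    model_version: int = 1
    sensitivity: str | None = None
    min_year_fraction: float = 0.25
    sim: dict = field(default_factory=dict)            # SimulationConfig overrides
    occ_mcmc: dict = field(default_factory=lambda: dict(
        chains=2, n_iter=400, warmup=400, thin=2))
    reg_mcmc: dict = field(default_factory=lambda: dict(
        chains=2, n_iter=400, warmup=300, thin=1))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def sim_config(self) -> syn.SimulationConfig:
        kw = dict(self.sim)
        kw.setdefault("rng_seed", self.seed)
        kw.setdefault("interval_length", self.interval_length)
        return syn.SimulationConfig(**kw)


def _write_manifest(outdir: Path, config: PipelineConfig, extra: dict | None = None):
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "config": config.to_dict(), **(extra or {})}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the pipeline; returns in-memory results keyed by stage.

    ``stages`` restricts execution (later stages recompute their inputs in
    memory if caches are absent).  Artifacts are written per stage; failures
    propagate with the stage name.
    """
    all_stages = ["simulate", "prep", "occupancy", "trends", "drivers",
                  "regress", "scenarios"]
    stages = stages or all_stages
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res: dict = {}
    cfg = config.sim_config()
    try:
        _stage_simulate(res, cfg, outdir, "simulate" in stages)
        _stage_prep(res, cfg, config, outdir, "prep" in stages)
        if "occupancy" in stages or "trends" in stages:
            _stage_occupancy(res, cfg, config, outdir)
            _stage_trends(res, cfg, config, outdir)
        if {"drivers", "regress", "scenarios"} & set(stages):
            _stage_drivers(res, cfg, outdir)
        if "regress" in stages or "scenarios" in stages:
            _stage_regress(res, cfg, config, outdir)
        if "scenarios" in stages:
            _stage_scenarios(res, config, outdir)
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed ({e.__class__.__name__}): {e}") from e
    res["manifest"] = _write_manifest(outdir, config, {
        "stages": stages, "n_records": int(len(res["records"])) if "records" in res else None})
    return res


def _stage_simulate(res, cfg, outdir, write):
    frame = syn.generate_landscape(cfg)
    raw = syn.generate_driver_trajectories(cfg)
    species = syn.generate_species(cfg)
    driver_table, scaling = syn.derive_driver_table(raw, cfg)
    truth = syn.simulate_occupancy_dynamics(frame, driver_table, species, cfg)
    obs = syn.simulate_visits_and_records(truth, frame, cfg)
    res.update(frame=frame, raw_drivers=raw, species=species,
               driver_table=driver_table, driver_scaling=scaling, truth=truth,
               records=obs["records"], projects=obs["projects"])
    if write:
        frame.to_csv(outdir / "squares.csv", index=False)
        species.drop(columns=["habitats"]).to_csv(outdir / "species.csv", index=False)
        obs["records"].to_csv(outdir / "records.csv", index=False)
        obs["projects"].to_csv(outdir / "projects.csv", index=False)
        raw["climate_monthly"].to_csv(outdir / "climate_monthly.csv", index=False)
        raw["landuse"].to_csv(outdir / "landuse_raw.csv", index=False)
        truth.true_trends_zone.to_csv(outdir / "true_trends_zone.csv", index=False)
        truth.true_trends_country.to_csv(outdir / "true_trends_country.csv", index=False)
    logger.info("simulate: %d squares, %d records", len(frame), len(res["records"]))


def _stage_prep(res, cfg, config, outdir, write):
    years = cfg.years
    rec = prep.filter_records(res["records"], int(years[0]), int(years[-1]))
    visits = prep.build_visits(rec)
    selected = prep.select_species(rec, years, config.min_year_fraction)
    hist = prep.build_detection_histories(selected, visits, rec, res["frame"],
                                          res["projects"])
    res.update(records_filtered=rec, visits=visits, selected_species=selected,
               histories={sp: h for sp, h in hist.items() if len(h)})
    counts = (rec.merge(res["frame"][["square_id", "zone"]], on="square_id")
              .groupby(["species_id", "zone"]).size().rename("n_records").reset_index())
    res["record_counts"] = counts
    if write:
        visits.drop(columns=["species_list"]).to_csv(outdir / "visits.csv", index=False)
        counts.to_csv(outdir / "record_counts.csv", index=False)
    logger.info("prep: %d visits, %d species selected", len(visits), len(selected))


def _stage_occupancy(res, cfg, config, outdir):
    posteriors = {}
    for i, sp in enumerate(sorted(res["histories"])):
        hist = res["histories"][sp]
        design = OccupancyDesign(sp, res["frame"][[
            "square_id", "elevation_scaled", "region", "zone"]], hist, cfg.years)
        model = OccupancyModel(seed=config.seed + 1000 + i, **config.occ_mcmc)
        try:
            model.fit(design)
        except ValueError as e:
            logger.warning("occupancy fit skipped for %s: %s", sp, e)
            continue
        posteriors[sp] = model.posterior_
    if not posteriors:
        raise ValueError("no species could be fitted")
    res["posteriors"] = posteriors
    rhat = pd.DataFrame([
        {"species_id": sp,
         "fraction_rhat_ok": (m["fraction_below_threshold"] if m.get("available") else np.nan),
         "max_rhat": (m["max_rhat"] if m.get("available") else np.nan)}
        for sp, post in posteriors.items()
        for m in [check_convergence(post)]])
    rhat.to_csv(outdir / "occupancy_rhat.csv", index=False)
    res["occupancy_rhat"] = rhat
    logger.info("occupancy: fitted %d species", len(posteriors))


def _stage_trends(res, cfg, config, outdir):
    years = cfg.years
    intervals = intervals_for(int(years[0]), int(years[-1]), config.interval_length)
    country_trend_draws = {}
    zone_rows = []
    for sp, post in res["posteriors"].items():
        cty = post.country_occ_flat()
        country_trend_draws[sp] = fit_window_trend(
            cty, post.analysis_years, (int(years[0]), int(years[-1])))
        zocc = post.zone_occ_flat()
        for zi, zone in enumerate(post.zones):
            if not post.zone_has_record[zi]:
                continue
            for (lo, hi) in intervals:
                d = fit_window_trend(zocc[:, zi, :], post.analysis_years, (lo, hi))
                zone_rows.append({"species_id": sp, "zone": zone,
                                  "interval": f"{lo}-{hi}",
                                  "trend": float(d.mean()),
                                  "trend_sd": float(d.std())})
    species_ids = sorted(country_trend_draws)
    tmat = np.column_stack([country_trend_draws[sp] for sp in species_ids])
    occ_mean = np.column_stack([res["posteriors"][sp].country_occ_flat().mean(axis=1)
                                for sp in species_ids])
    summary = summarize_trends(tmat, occ_mean, species_ids,
                               rng=np.random.default_rng(config.seed + 77))
    res.update(country_trends=tmat, country_trend_species=species_ids,
               zone_trends=pd.DataFrame(zone_rows), trend_summary=summary)
    trend_table(tmat, species_ids, "country-40yr").to_csv(
        outdir / "trends_country.csv", index=False)
    res["zone_trends"].to_csv(outdir / "trends_zone.csv", index=False)
    with open(outdir / "trend_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)


def _stage_drivers(res, cfg, outdir):
    res["driver_table"].to_csv(outdir / "driver_changes.csv", index=False)
    res["driver_scaling"].to_csv(outdir / "driver_scaling.csv")


def _stage_regress(res, cfg, config, outdir):
    traits = res["species"].rename(columns={})
    trends = res["zone_trends"][["species_id", "zone", "interval", "trend"]]
    design = build_design(trends, res["driver_table"], traits,
                          version=config.model_version)
    if config.sensitivity:
        design = sensitivity_filter(design, config.sensitivity,
                                    record_counts=res["record_counts"],
                                    traits=traits)
    reg = TrendRegression(seed=config.seed + 500, **config.reg_mcmc).fit(design)
    res.update(regression_design=design, regression=reg)
    reg.summary_.to_csv(outdir / "regression_summary.csv")
    pd.DataFrame(design.X, columns=design.x_cols).to_csv(
        outdir / "regression_modelmatrix.csv", index=False)
    with open(outdir / "regression_fit.json", "w") as fh:
        json.dump({"converged": bool(reg.converged_),
                   "residual_diagnostics": reg.residual_diagnostics(),
                   "version": design.version}, fh, indent=1, default=float)


def _stage_scenarios(res, config, outdir):
    # scenario predictions use an agri-species-only fit (model version 2)
    traits = res["species"]
    trends = res["zone_trends"][["species_id", "zone", "interval", "trend"]]
    if res["regression_design"].version == 2:
        design2, reg2 = res["regression_design"], res["regression"]
    else:
        design2 = build_design(trends, res["driver_table"], traits, version=2)
        reg2 = TrendRegression(seed=config.seed + 600, **config.reg_mcmc).fit(design2)
    n_sq = res["frame"].groupby("zone").size()
    table = run_scenarios(reg2, design2, res["driver_scaling"], n_sq)
    res["scenario_table"] = table
    table.to_csv(outdir / "scenario_r2.csv", index=False)


# ---------------------------------------------------------------------------
# deterministic micro-fixtures for the test-suite and documentation
# ---------------------------------------------------------------------------

def make_fixtures(kind: str):
    """Small deterministic datasets: 'tiny-occupancy', 'toy-trend', 'driver-grid'."""
    if kind == "tiny-occupancy":
        sites = pd.DataFrame({
            "square_id": ["a", "b", "c"],
            "elevation_scaled": [-1.0, 0.0, 1.0],
            "region": ["r1", "r1", "r2"],
            "zone": ["z1", "z1", "z2"],
        })
        visits = pd.DataFrame({
            "square_id": ["a", "a", "b", "c", "c"],
            "year": [2000, 2001, 2000, 2001, 2001],
            "y": [1, 0, 0, 1, 1],
            "yday_scaled": [0.0, 0.5, -0.5, 0.2, -0.2],
            "shortlist": [1, 0, 0, 0, 1],
            "longlist": [0, 0, 1, 0, 0],
            "expert": [0, 1, 0, 0, 0],
            "project": [0, 0, 0, 1, 0],
            "targeted_project": [0, 0, 0, 0, 0],
            "redlist": [0, 0, 0, 0, 1],
        })
        return OccupancyDesign("tiny", sites, visits, np.array([2000, 2001]))
    if kind == "toy-trend":
        years = np.arange(1980, 2021)
        slopes = np.array([-0.004, -0.003, -0.001, -0.0005, 0.0005, 0.001, 0.002, 0.003])
        series = 0.2 + slopes[:, None] * (years - years[0])[None, :]
        return {"years": years, "slopes": slopes,
                "series": np.repeat(series[None, :, :], 50, axis=0)}  # draws x sp x yr
    if kind == "driver-grid":
        rows = []
        for z in ["z1_low", "z2_high"]:
            for k in range(8):
                lo = 1980 + 5 * k
                rows.append({"zone": z, "interval": f"{lo}-{lo + 5}",
                             "temp_mean_change": 0.1 * k - (0.2 if z == "z2_high" else 0.0),
                             "temp_seasonality_change": 0.05 * ((-1) ** k),
                             "summer_precip_change": -2.0 + 0.5 * k,
                             "agri_area_change": -0.01 * k,
                             "grassland_intensity_change": 0.02 * k - 0.05,
                             "crop_intensity_change": 0.5 - 0.1 * k})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown fixture kind {kind!r}")
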