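"""Virtual study system with known ground truth.

Generates a landscape of 1x1 km squares stratified into bioclimatic zones
(biogeographic region x elevation class), zone-wise climate and land-use
driver trajectories, three insect species groups with temperature-niche and
habitat-specialisation traits, latent occupancy dynamics whose zone-year
effects respond to driver changes, and an opportunistic observation process
(visits by heterogeneous observers and project sources, detections with
imperfect, covariate-dependent probability).

Driver effects enter through the zone-year effect of the occupancy process,
not through per-square covariates: the occupancy-detection model estimates
zone-year effects freely, so ground-truth driver signal must live exactly
there for the downstream attribution to be recoverable.

Visit days are drawn uniformly over a group-specific season window; observer
activity follows a discrete power law so that a small expert tail exists.
All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drivers as drv
from .trends import ols_slope, intervals_for

__all__ = [
    "SimulationConfig",
    "TrueState",
    "generate_landscape",
    "generate_driver_trajectories",
    "generate_species",
    "simulate_occupancy_dynamics",
    "simulate_visits_and_records",
    "elevation_class",
    "GROUPS",
]

GROUPS = ["butterflies", "grasshoppers", "dragonflies"]

#: group-specific flight/activity season (day-of-year window for visits)
SEASON = {"butterflies": (120, 240), "grasshoppers": (150, 270), "dragonflies": (130, 250)}

#: per-group habitat universes (counts mirror group habitat breadth)
HABITAT_UNIVERSE = {
    "butterflies": [f"hab_b{i}" for i in range(18)],
    "grasshoppers": [f"hab_g{i}" for i in range(12)],
    "dragonflies": [f"hab_d{i}" for i in range(10)],
}

ZONE_LAYOUT_9 = [
    ("jura", "low"), ("jura", "high"), ("plateau", "low"),
    ("north_alps", "low"), ("north_alps", "high"),
    ("central_alps", "low"), ("central_alps", "high"),
    ("south_alps", "low"), ("south_alps", "high"),
]

CROP_TYPES = ["cereal", "maize", "rapeseed", "orchard", "vineyard"]

#: mean insecticide application rates per crop type (kg/km2/yr), config table
DEFAULT_CROP_RATES = {"cereal": 20.0, "maize": 40.0, "rapeseed": 60.0,
                      "orchard": 150.0, "vineyard": 120.0}


def elevation_class(mean_elevation_m: float) -> str:
    """Elevation class of a square: below 1000 m asl is 'low', else 'high'."""
    return "low" if mean_elevation_m < 1000.0 else "high"


@dataclass
class SimulationConfig:
    """Knobs of the virtual study system.

    Defaults reproduce the structure of the real study: 9 bioclimatic zones,
    41 years labelled 1980-2020, three species groups.  Effect sizes are on
    the logit-occupancy trend scale (change per standard deviation of a
    standardized driver change, per 5-year interval).
    """

    n_squares_per_zone: int = 50
    n_zones: int = 9
    n_years: int = 41
    start_year: int = 1980
    n_species_per_group: tuple = (20, 10, 7)
    interval_length: int = 5

    # occupancy process
    occ_intercept: float = -1.0
    occ_elev: float = -0.4
    occ_elev2: float = -0.3
    sd_region: float = 0.4
    sd_square: float = 1.0
    species_intercept_sd: float = 0.8
    year_walk_sd: float = 0.03

    # ground-truth driver effects on the zone-year trend (per interval)
    driver_effect_sizes: dict = field(default_factory=lambda: {
        "temp_mean_change": -0.15,
        "temp_seasonality_change": -0.08,
        "summer_precip_change": -0.06,
        "agri_area_change": 0.08,
        "grassland_intensity_change": -0.10,
        "crop_intensity_change": -0.06,
    })
    # trait modulation: climate effects vary with temperature niche,
    # land-use effects with habitat specialisation (standardized traits)
    trait_interactions: dict = field(default_factory=lambda: {
        "temp_mean_change": 0.12,          # x standardized niche
        "temp_seasonality_change": 0.0,
        "summer_precip_change": 0.0,
        "agri_area_change": 0.0,
        "grassland_intensity_change": -0.06,  # x standardized specialisation
        "crop_intensity_change": -0.04,
    })
    landuse_agri_only: bool = True  # land-use effects act only on agri-associated species

    # detection process
    det_intercept: float = -0.2
    det_yday: float = 0.0
    det_yday2: float = -0.6
    det_effort_sd: float = 1.0
    det_skill_sd: float = 0.4
    det_expert_bonus: float = 1.0
    det_source_effects: dict = field(default_factory=lambda: {
        "naturalist": 0.0, "project": 0.4, "targeted_project": 1.5, "redlist": 0.8})
    det_year_sd: float = 0.3

    # observation design
    visit_intensity: float = 2.0          # expected visits per square-year per group
    n_observers: int = 250
    observer_powerlaw: float = 1.6        # Zipf exponent of activity weights
    source_probs: dict = field(default_factory=lambda: {
        "private": 0.70, "project": 0.15, "targeted_project": 0.05, "redlist": 0.10})
    n_projects: int = 12
    larval_fraction: float = 0.04         # emitted records flagged non-adult

    # climate trajectories (per-zone trends drawn within these ranges)
    temp_trend_range: tuple = (0.02, 0.07)      # degC / yr
    seasonality_trend_range: tuple = (-0.01, 0.02)
    precip_trend_range: tuple = (-2.0, 1.0)     # mm (monthly) / yr in summer
    climate_noise_sd: float = 0.4
    precip_noise_sd: float = 12.0
    landuse_gap_fraction: float = 0.5           # missing years before the census era

    rng_seed: int = 0

    def __post_init__(self):
        counts = [self.n_squares_per_zone, self.n_zones, self.n_years,
                  *self.n_species_per_group]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        sds = [self.sd_region, self.sd_square, self.species_intercept_sd,
               self.year_walk_sd, self.det_effort_sd, self.det_year_sd]
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be >= 0")

    @property
    def years(self):
        return np.arange(self.start_year, self.start_year + self.n_years)

    @property
    def intervals(self):
        return intervals_for(self.start_year, self.start_year + self.n_years - 1,
                             self.interval_length)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream per stage."""
        h = int(np.frombuffer(str(stream).encode(), dtype=np.uint8).sum())
        return np.random.default_rng(np.random.SeedSequence([self.rng_seed, h]))


@dataclass
class TrueState:
    """Ground truth of the simulated occupancy dynamics."""

    psi: np.ndarray           # (n_species_total, S, T)
    z: np.ndarray             # bool, same shape
    species: pd.DataFrame     # traits table aligned with axis 0
    true_trends_zone: pd.DataFrame     # species, zone, interval, true 5-yr change
    true_trends_country: pd.DataFrame  # species, true 40-yr change


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def generate_landscape(config: SimulationConfig) -> pd.DataFrame:
    """StudyFrame: one row per square with zone, region, fine region, elevation."""
    rng = config.rng("landscape")
    if config.n_zones == 9:
        layout = ZONE_LAYOUT_9
    else:
        layout = [(f"region{k // 2 + 1}", "low" if k % 2 == 0 else "high")
                  for k in range(config.n_zones)]
    rows = []
    sq = 0
    for region, elev_cls in layout:
        zone = f"{region}_{elev_cls}"
        n_fine = 2 if region != "plateau" else 3
        for _ in range(config.n_squares_per_zone):
            if elev_cls == "low":
                elev = float(rng.uniform(250, 999))
            else:
                elev = float(rng.uniform(1000, 2600))
            rows.append({
                "square_id": f"sq{sq:05d}",
                "zone": zone,
                "region": region,
                "fine_region": f"{region}_f{rng.integers(n_fine) + 1}",
                "elevation_m": elev,
                "elevation_class": elevation_class(elev),
            })
            sq += 1
    frame = pd.DataFrame(rows)
    if frame.groupby("zone").size().min() < 1:
        raise ValueError("config leaves a zone without squares")
    e = frame["elevation_m"]
    frame["elevation_scaled"] = (e - e.mean()) / e.std(ddof=0)
    return frame


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def generate_driver_trajectories(config: SimulationConfig) -> dict:
    """Raw zone-level driver series.

    Returns a dict with:

    ``climate_monthly`` : DataFrame (zone, year, month, temp_c, precip_mm),
        covering a 5-year lead-in before the first study year so interval
        climate regressions have their full 10-year windows.
    ``landuse`` : DataFrame (zone, year, agri_area_km2, grassland_area_km2,
        lsu, crop_*_km2) with NaN gaps in the pre-census era.
    ``zone_area_km2`` : Series per zone.
    ``crop_rates`` : the application-rate table used downstream.
    """
    rng = config.rng("drivers")
    zones = sorted({f"{r}_{e}" for r, e in (
        ZONE_LAYOUT_9 if config.n_zones == 9 else
        [(f"region{k // 2 + 1}", "low" if k % 2 == 0 else "high")
         for k in range(config.n_zones)])})
    years_ext = np.arange(config.start_year - config.interval_length,
                          config.start_year + config.n_years)
    months = np.arange(1, 13)
    clim_rows = []
    lu_frames = []
    zone_area = {}
    for z in zones:
        high = z.endswith("high")
        base_t = rng.uniform(7.5, 10.5) - (4.5 if high else 0.0)
        amp = rng.uniform(8.0, 10.0)
        t_trend = rng.uniform(*config.temp_trend_range)
        s_trend = rng.uniform(*config.seasonality_trend_range)
        p_base = rng.uniform(70.0, 120.0)
        p_trend = rng.uniform(*config.precip_trend_range)
        for yr in years_ext:
            dy = yr - config.start_year
            seas_amp = amp + s_trend * dy
            mu_t = base_t + t_trend * dy
            temp = (mu_t + seas_amp * np.cos(2 * np.pi * (months - 7) / 12.0)
                    + rng.normal(0, config.climate_noise_sd, 12))
            summer = np.exp(-0.5 * ((months - 7) / 2.0) ** 2)
            precip = np.clip(
                p_base + p_trend * dy * summer
                + rng.normal(0, config.precip_noise_sd, 12), 1.0, None)
            for m, t_c, p_mm in zip(months, temp, precip):
                clim_rows.append({"zone": z, "year": int(yr), "month": int(m),
                                  "temp_c": float(t_c), "precip_mm": float(p_mm)})
        # land use: smooth multi-decadal change
        area = config.n_squares_per_zone * 1.0  # km2, one square = 1 km2
        zone_area[z] = area
        yrs = np.arange(config.start_year, config.start_year + config.n_years)
        u = (yrs - yrs[0]) / max(1, (yrs[-1] - yrs[0]))
        agri0 = area * rng.uniform(0.35, 0.55) * (0.6 if high else 1.0)
        agri = agri0 * (1.0 - rng.uniform(0.05, 0.25) * u ** rng.uniform(0.8, 1.5))
        grass_frac = rng.uniform(0.5, 0.8) + rng.uniform(-0.1, 0.1) * u
        grass = agri * np.clip(grass_frac, 0.2, 0.95)
        lsu = grass * rng.uniform(0.8, 1.6) * (1.0 + rng.uniform(-0.2, 0.5) * u)
        lu = pd.DataFrame({"zone": z, "year": yrs, "agri_area_km2": agri,
                           "grassland_area_km2": grass, "lsu": lsu})
        crop_total = agri - grass
        shares = rng.dirichlet(np.ones(len(CROP_TYPES)) * 2.0)
        drift = rng.normal(0, 0.3, len(CROP_TYPES))
        for k, crop in enumerate(CROP_TYPES):
            share = np.clip(shares[k] * (1.0 + drift[k] * u), 0.0, 1.0)
            lu[f"crop_{crop}_km2"] = crop_total * share
        # observation gaps: sparse census years before 1996-equivalent era
        census_start = config.start_year + int(0.4 * config.n_years)
        # endpoints always observed so interval changes are anchored
        early = (yrs < census_start) & ~np.isin(yrs, [yrs[0], yrs[-1]])
        gap = early & (rng.uniform(size=len(yrs)) < config.landuse_gap_fraction)
        lu.loc[gap, lu.columns.difference(["zone", "year"])] = np.nan
        lu_frames.append(lu)
    climate = pd.DataFrame(clim_rows)
    landuse = pd.concat(lu_frames, ignore_index=True)
    return {"climate_monthly": climate, "landuse": landuse,
            "zone_area_km2": pd.Series(zone_area),
            "crop_rates": dict(DEFAULT_CROP_RATES)}


def derive_driver_table(raw: dict, config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized zone x interval driver-change table from raw series.

    Applies the bioclim derivation, 10-year-window climate regressions,
    spline gap-filling of land-use series and endpoint interval differences,
    then centres/scales each change variable over its zone x interval
    replicates.  Returns (driver_table, scaling).
    """
    climate = raw["climate_monthly"]
    landuse = raw["landuse"]
    zones = sorted(climate["zone"].unique())
    years = config.years
    intervals = config.intervals
    bio_rows = []
    for (z, yr), g in climate.groupby(["zone", "year"]):
        g = g.sort_values("month")
        bio1, bio4, bio18 = drv.compute_bioclim(g["temp_c"].to_numpy(),
                                                g["precip_mm"].to_numpy())
        bio_rows.append({"zone": z, "year": int(yr), "bio1": bio1, "bio4": bio4,
                         "bio18": bio18})
    bio = pd.DataFrame(bio_rows)
    rows = []
    for z in zones:
        bz = bio[bio["zone"] == z].set_index("year")
        lz = landuse[landuse["zone"] == z].set_index("year")
        filled = {}
        for col in ["agri_area_km2", "grassland_area_km2", "lsu"] + [
                f"crop_{c}_km2" for c in CROP_TYPES]:
            filled[col] = drv.gapfill_landuse(lz.index.to_numpy(),
                                              lz[col].to_numpy(), years)
        filled = pd.DataFrame(filled, index=years)
        intens = drv.landuse_variables(filled, raw["crop_rates"],
                                       float(raw["zone_area_km2"][z]))
        for (lo, hi) in intervals:
            rows.append({
                "zone": z, "interval": f"{lo}-{hi}",
                "temp_mean_change": drv.climate_change(bz["bio1"], (lo, hi)),
                "temp_seasonality_change": drv.climate_change(bz["bio4"], (lo, hi)),
                "summer_precip_change": drv.climate_change(bz["bio18"], (lo, hi)),
                "agri_area_change": drv.landuse_change(intens["agri_area_prop"], (lo, hi)),
                "grassland_intensity_change": drv.landuse_change(
                    intens["grassland_intensity"], (lo, hi)),
                "crop_intensity_change": drv.landuse_change(intens["crop_intensity"], (lo, hi)),
            })
    table = pd.DataFrame(rows)
    std, scaling = drv.standardize_changes(table)
    return std, scaling


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------

def generate_species(config: SimulationConfig) -> pd.DataFrame:
    """SpeciesTraits table for the three groups.

    Temperature niches are drawn around group-specific means (dragonflies
    and grasshoppers warmer-adapted on average than butterflies);
    specialisation comes from simulated habitat-preference lists through the
    within-group rescaled index; agri-association mirrors the real pattern
    (most butterflies and grasshoppers, no dragonflies).
    """
    rng = config.rng("species")
    niche_mean = {"butterflies": 8.5, "grasshoppers": 10.0, "dragonflies": 11.0}
    agri_prob = {"butterflies": 0.85, "grasshoppers": 0.90, "dragonflies": 0.0}
    rows, habitat_lists, group_of = [], {}, {}
    for g, n_sp in zip(GROUPS, config.n_species_per_group):
        uni = HABITAT_UNIVERSE[g]
        for k in range(n_sp):
            sp = f"{g[:3]}_{k:03d}"
            n_hab = int(rng.integers(1, len(uni) + 1))
            habitat_lists[sp] = list(rng.choice(uni, size=n_hab, replace=False))
            group_of[sp] = g
            rows.append({
                "species_id": sp, "group": g,
                "temperature_niche": float(rng.normal(niche_mean[g], 1.8)),
                "agri_associated": bool(rng.uniform() < agri_prob[g]),
                "flag_excluded": bool(rng.uniform() < 0.05),
            })
    traits = pd.DataFrame(rows).set_index("species_id")
    spec = drv.habitat_specialisation(habitat_lists, group_of, HABITAT_UNIVERSE)
    traits["habitat_specialisation"] = spec
    traits["habitats"] = pd.Series(habitat_lists)
    return traits.reset_index()


# ---------------------------------------------------------------------------
# occupancy dynamics
# ---------------------------------------------------------------------------

def simulate_occupancy_dynamics(frame: pd.DataFrame, driver_table: pd.DataFrame,
                                species: pd.DataFrame, config: SimulationConfig) -> TrueState:
    """Latent occupancy probabilities and states for every species.

    logit(psi) = species intercept + elevation + elevation^2 + square and
    region random effects + zone-year effect; the zone-year effect drifts by
    a linear combination of standardized driver changes modulated by species
    traits, plus random-walk noise.
    """
    rng = config.rng("occupancy")
    S = len(frame)
    T = config.n_years
    years = config.years
    zones = sorted(frame["zone"].unique())
    zmap = {z: k for k, z in enumerate(zones)}
    zone_idx = frame["zone"].map(zmap).to_numpy()
    regions = sorted(frame["region"].unique())
    rmap = {r: k for k, r in enumerate(regions)}
    region_idx = frame["region"].map(rmap).to_numpy()
    elev = frame["elevation_scaled"].to_numpy()
    n_sp = len(species)
    intervals = config.intervals
    L = config.interval_length

    # standardized traits over the whole species pool (recording level)
    niche = species["temperature_niche"].to_numpy(dtype=float)
    niche_s = (niche - niche.mean()) / niche.std(ddof=0)
    spec = species["habitat_specialisation"].to_numpy(dtype=float)
    spec_sd = spec.std(ddof=0)
    spec_s = (spec - spec.mean()) / spec_sd if spec_sd > 0 else np.zeros_like(spec)
    agri = species["agri_associated"].to_numpy(dtype=bool)

    # driver change lookup: (zone, interval) -> standardized changes
    dt = driver_table.set_index(["zone", "interval"])
    interval_of_year = np.zeros(T, dtype=int)
    for k, (lo, hi) in enumerate(intervals):
        interval_of_year[(years >= lo) & (years < hi)] = k
    interval_of_year[years >= intervals[-1][1]] = len(intervals) - 1

    region_eff = rng.normal(0, config.sd_region, size=len(regions))
    square_eff = rng.normal(0, config.sd_square, size=S)
    base_site = (config.occ_intercept + config.occ_elev * elev
                 + config.occ_elev2 * elev ** 2
                 + region_eff[region_idx] + square_eff)

    psi = np.empty((n_sp, S, T))
    z = np.empty((n_sp, S, T), dtype=bool)
    eff = config.driver_effect_sizes
    trait_eff = config.trait_interactions
    for s_i, row in enumerate(species.itertuples(index=False)):
        sp_int = rng.normal(0, config.species_intercept_sd)
        gamma = np.zeros((len(zones), T))
        for zi, zname in enumerate(zones):
            g = 0.0
            for t in range(1, T):
                k = interval_of_year[t]
                ch = dt.loc[(zname, f"{intervals[k][0]}-{intervals[k][1]}")]
                drift = 0.0
                for d in drv.CLIMATE_VARS:
                    drift += (eff.get(d, 0.0) + trait_eff.get(d, 0.0) * niche_s[s_i]) * ch[d]
                lu_mult = 1.0 if (agri[s_i] or not config.landuse_agri_only) else 0.0
                for d in drv.LANDUSE_VARS:
                    drift += lu_mult * (eff.get(d, 0.0)
                                        + trait_eff.get(d, 0.0) * spec_s[s_i]) * ch[d]
                g = g + drift / L + rng.normal(0, config.year_walk_sd)
                gamma[zi, t] = g
        lin = (base_site[:, None] + sp_int + gamma[zone_idx, :])
        if not np.all(np.isfinite(lin)):
            raise FloatingPointError("non-finite occupancy linear predictor")
        psi[s_i] = 1.0 / (1.0 + np.exp(-lin))
        z[s_i] = rng.uniform(size=(S, T)) < psi[s_i]

    # ground-truth trends from the mean-of-psi series
    zone_rows, cty_rows = [], []
    n_per_zone = np.bincount(zone_idx, minlength=len(zones))
    for s_i, sp in enumerate(species["species_id"]):
        mean_zone = np.stack([psi[s_i][zone_idx == zi].mean(axis=0)
                              for zi in range(len(zones))])
        mean_cty = psi[s_i].mean(axis=0)
        for zi, zname in enumerate(zones):
            for (lo, hi) in intervals:
                m = (years >= lo) & (years <= hi)
                slope = float(ols_slope(mean_zone[zi, m], years[m].astype(float)))
                zone_rows.append({"species_id": sp, "zone": zname,
                                  "interval": f"{lo}-{hi}",
                                  "true_trend": slope * L})
        slope = float(ols_slope(mean_cty, years.astype(float)))
        cty_rows.append({"species_id": sp, "true_trend": slope * (T - 1)})
    return TrueState(psi=psi, z=z, species=species.copy(),
                     true_trends_zone=pd.DataFrame(zone_rows),
                     true_trends_country=pd.DataFrame(cty_rows))


# ---------------------------------------------------------------------------
# observation process
# ---------------------------------------------------------------------------

def simulate_visits_and_records(true_state: TrueState, frame: pd.DataFrame,
                                config: SimulationConfig) -> dict:
    """Visits and emitted records for all three group datasets.

    Returns ``{"records": RecordTable, "projects": project coverage table}``.
    Records carry species, square, date, observer or project key, a source
    hint and a life-stage flag; detections are Bernoulli(z * p) per
    visit x species and only detections are emitted.
    """
    rng = config.rng("records")
    species = true_state.species
    years = config.years
    S = len(frame)
    sq_ids = frame["square_id"].to_numpy()

    # observer pool with power-law activity
    obs_w = (np.arange(1, config.n_observers + 1) ** -config.observer_powerlaw)
    obs_w = obs_w / obs_w.sum()
    n_expert = max(1, int(np.ceil(0.025 * config.n_observers)))
    skills = rng.normal(0, config.det_skill_sd, config.n_observers)
    skills[:n_expert] += config.det_expert_bonus  # most active observers are better

    # projects: generic (whole-group), red-list (whole-group), targeted (one species)
    proj_rows = []
    proj_group, proj_target, proj_kind = {}, {}, {}
    for k in range(config.n_projects):
        pid = f"proj{k:02d}"
        kind = ["project", "redlist", "targeted_project"][k % 3]
        g = GROUPS[k % len(GROUPS)]
        target = None
        if kind == "targeted_project":
            pool = species.loc[species["group"] == g, "species_id"]
            target = str(pool.iloc[int(rng.integers(len(pool)))])
        proj_group[pid], proj_target[pid], proj_kind[pid] = g, target, kind
        proj_rows.append({"project_id": pid, "kind": kind, "group": g,
                          "target_species": target})
    projects = pd.DataFrame(proj_rows)
    kinds = list(config.source_probs.keys())
    kind_p = np.array([config.source_probs[k] for k in kinds])
    kind_p = kind_p / kind_p.sum()

    rec_frames = []
    for g in GROUPS:
        gsp = species[species["group"] == g]
        if gsp.empty:
            continue
        sp_idx = gsp.index.to_numpy()
        sp_ids = gsp["species_id"].to_numpy()
        d0, d1 = SEASON[g]
        mid, half = (d0 + d1) / 2.0, (d1 - d0) / 2.0
        gp = projects[projects["group"] == g]
        n_visits = rng.poisson(config.visit_intensity, size=(S, len(years)))
        vs, vy = np.nonzero(n_visits)
        counts = n_visits[vs, vy]
        v_site = np.repeat(vs, counts)
        v_year_i = np.repeat(vy, counts)
        nv = v_site.size
        v_day = rng.integers(d0, d1 + 1, size=nv)
        v_kind = np.array(kinds)[rng.choice(len(kinds), size=nv, p=kind_p)]
        v_obs = rng.choice(config.n_observers, size=nv, p=obs_w)
        v_proj = np.full(nv, None, dtype=object)
        for kind in ["project", "redlist", "targeted_project"]:
            mask = v_kind == kind
            pool = gp.loc[gp["kind"] == kind, "project_id"].to_numpy()
            if pool.size == 0:
                v_kind[mask] = "private"
                continue
            v_proj[mask] = pool[rng.integers(pool.size, size=int(mask.sum()))]
        yday_s = (v_day - mid) / (half / 1.5)
        effort = rng.normal(0, config.det_effort_sd, nv)
        year_eff = rng.normal(0, config.det_year_sd, len(years))
        src_eff = np.array([config.det_source_effects.get(
            {"private": "naturalist"}.get(k, k), 0.0) for k in v_kind])
        lp_visit = (config.det_intercept + config.det_yday * yday_s
                    + config.det_yday2 * yday_s ** 2 + effort
                    + year_eff[v_year_i] + src_eff
                    + np.where(v_kind == "private", skills[v_obs], 0.0))
        p_visit = 1.0 / (1.0 + np.exp(-lp_visit))
        # detection trials per visit x species of the group
        zg = true_state.z[sp_idx][:, v_site, v_year_i]  # (n_sp_g, nv)
        det = (rng.uniform(size=zg.shape) < p_visit[None, :]) & zg
        # targeted projects only record their focal species
        tmask = v_kind == "targeted_project"
        if tmask.any():
            targets = np.array([proj_target.get(p, None) for p in v_proj], dtype=object)
            for si, sp in enumerate(sp_ids):
                det[si, tmask & (targets != sp)] = False
        si_arr, vi_arr = np.nonzero(det)
        if si_arr.size == 0:
            continue
        dates = pd.to_datetime({"year": years[v_year_i[vi_arr]],
                                "month": 1, "day": 1}) + pd.to_timedelta(
            v_day[vi_arr] - 1, unit="D")
        rec = pd.DataFrame({
            "species_id": sp_ids[si_arr],
            "group": g,
            "square_id": sq_ids[v_site[vi_arr]],
            "date": dates,
            "observer_id": np.where(v_kind[vi_arr] == "private",
                                    [f"obs{o:04d}" for o in v_obs[vi_arr]], None),
            "project_id": v_proj[vi_arr],
            "source_hint": v_kind[vi_arr],
            "life_stage": np.where(rng.uniform(size=si_arr.size) < config.larval_fraction,
                                   "larva", "adult"),
        })
        rec_frames.append(rec)
    records = (pd.concat(rec_frames, ignore_index=True) if rec_frames
               else pd.DataFrame(columns=["species_id", "group", "square_id", "date",
                                          "observer_id", "project_id", "source_hint",
                                          "life_stage"]))
    return {"records": records, "projects": projects,
            "expert_observers": [f"obs{o:04d}" for o in range(n_expert)]}
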