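"""Shared simulation helpers for the test-suite: tiny random occupancy
instances with a brute-force likelihood oracle, constant-probability
detection datasets, and regression-model simulators."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from occutrend.drivers import DRIVER_VARS
from occutrend.occupancy import OccupancyDesign, OccupancyParams
from occutrend.regression import build_design
from occutrend.trends import signed_square

VISIT_COLS = ["square_id", "year", "y", "yday_scaled", "shortlist", "longlist",
              "expert", "project", "targeted_project", "redlist"]


def random_tiny_instance(rng):
    """A random occupancy instance small enough for exact enumeration."""
    S = int(rng.integers(1, 4))
    T = int(rng.integers(1, 4))
    sites = pd.DataFrame({
        "square_id": [f"s{i}" for i in range(S)],
        "elevation_scaled": rng.normal(size=S),
        "region": rng.choice(["r1", "r2"], S),
        "zone": rng.choice(["z1", "z2"], S),
    })
    rows = []
    for i in range(S):
        for t in range(T):
            for _ in range(int(rng.integers(0, 4))):
                rows.append({
                    "square_id": f"s{i}", "year": 2000 + t,
                    "y": int(rng.uniform() < 0.5),
                    "yday_scaled": float(rng.normal()),
                    "shortlist": int(rng.uniform() < 0.5), "longlist": 0,
                    "expert": int(rng.uniform() < 0.3), "project": 0,
                    "targeted_project": 0, "redlist": 0,
                })
    if not rows:
        rows = [{"square_id": "s0", "year": 2000, "y": 0, "yday_scaled": 0.0,
                 "shortlist": 0, "longlist": 0, "expert": 0, "project": 0,
                 "targeted_project": 0, "redlist": 0}]
    visits = pd.DataFrame(rows, columns=VISIT_COLS)
    design = OccupancyDesign("tiny", sites, visits, np.arange(2000, 2000 + T))
    p = OccupancyParams.zeros(len(design.regions), S, len(design.zones), T)
    p.mu_o = float(rng.normal())
    p.beta_o1 = float(rng.normal() * 0.5)
    p.beta_o2 = float(rng.normal() * 0.3)
    p.alpha_o1 = rng.normal(size=len(design.regions)) * 0.5
    p.alpha_o2 = rng.normal(size=S) * 0.5
    p.gamma = rng.normal(size=(len(design.zones), T))
    p.mu_d = float(rng.normal())
    p.beta_d = rng.normal(size=8) * 0.4
    p.alpha_d1 = rng.normal(size=T) * 0.5
    return design, p


def enumeration_loglik(design, params):
    """Exact likelihood by summing over every latent occupancy configuration."""
    pk = design.packed()
    occ = (params.mu_o + params.beta_o1 * design.elev
           + params.beta_o2 * design.elev ** 2
           + params.alpha_o1[design.region_idx] + params.alpha_o2)
    lin = occ[pk["sy_site"]] + params.gamma[design.zone_idx[pk["sy_site"]], pk["sy_year"]]
    psi = 1.0 / (1.0 + np.exp(-lin))
    pv = 1.0 / (1.0 + np.exp(-(params.mu_d + pk["Xd"] @ params.beta_d
                               + params.alpha_d1[pk["v_year"]])))
    lik = 0.0
    for zcfg in itertools.product([0, 1], repeat=pk["n_sy"]):
        z = np.asarray(zcfg)
        pr_z = np.prod(np.where(z == 1, psi, 1 - psi))
        pdet = z[pk["v_sy"]] * pv
        pr_y = np.prod(np.where(pk["v_y"] > 0, pdet, 1 - pdet))
        lik += pr_z * pr_y
    return float(np.log(lik))


def constant_prob_dataset(rng, n_squares=100, n_years=10, n_visits=3,
                          psi=0.7, p=0.8):
    """Detection data with constant occupancy and detection probabilities."""
    z = rng.uniform(size=(n_squares, n_years)) < psi
    det = (rng.uniform(size=(n_squares, n_years, n_visits)) < p) & z[:, :, None]
    i, t, j = np.meshgrid(np.arange(n_squares), np.arange(n_years),
                          np.arange(n_visits), indexing="ij")
    visits = pd.DataFrame({
        "square_id": [f"s{k}" for k in i.ravel()],
        "year": 2000 + t.ravel(),
        "y": det.ravel().astype(int),
        "yday_scaled": 0.0, "shortlist": 0, "longlist": 0, "expert": 0,
        "project": 0, "targeted_project": 0, "redlist": 0,
    })
    sites = pd.DataFrame({
        "square_id": [f"s{k}" for k in range(n_squares)],
        "elevation_scaled": 0.0,
        "region": "r1",
        "zone": ["z1"] * (n_squares // 2) + ["z2"] * (n_squares - n_squares // 2),
    })
    design = OccupancyDesign("const", sites, visits, np.arange(2000, 2000 + n_years))
    naive = float(visits.groupby(["square_id", "year"])["y"].max().mean())
    return design, z, naive


def simulated_regression_problem(rng, n_species=200, n_zones=9, n_intervals=8,
                                 coef=None, resid_sd=0.1, zone_subsets=False,
                                 slope_sd=0.0, version=3,
                                 temp_signal=(0.15, 0.12, 0.06)):
    """Trend-regression data simulated from the model with known coefficients.

    ``coef`` maps fixed-effect column names to true values (others zero).
    With ``zone_subsets`` species occupy random zone subsets, mirroring the
    per-species zone filter of the real pipeline.
    """
    zones = [f"z{i}_{'low' if i % 2 else 'high'}" for i in range(n_zones)]
    intervals = [f"{1980 + 5 * k}-{1985 + 5 * k}" for k in range(n_intervals)]
    base, zspread, noise = temp_signal
    drows = []
    for z in zones:
        zt = rng.normal()
        for iv in intervals:
            row = {"zone": z, "interval": iv,
                   "temp_mean_change_raw": base + zspread * zt + noise * rng.normal()}
            for d in DRIVER_VARS:
                if d != "temp_mean_change":
                    row[f"{d}_raw"] = rng.normal(scale=0.1)
            drows.append(row)
    drivers = pd.DataFrame(drows)
    scale_rows = []
    for d in DRIVER_VARS:
        v = drivers[f"{d}_raw"]
        m, s = float(v.mean()), float(v.std(ddof=0))
        drivers[d] = (v - m) / s
        scale_rows.append({"variable": d, "mean": m, "sd": s})
    scaling = pd.DataFrame(scale_rows).set_index("variable")
    traits = pd.DataFrame({
        "species_id": [f"sp{i:03d}" for i in range(n_species)],
        "group": rng.choice(["butterflies", "grasshoppers", "dragonflies"],
                            n_species, p=[0.55, 0.26, 0.19]),
        "temperature_niche": rng.normal(9, 2, n_species),
        "habitat_specialisation": rng.uniform(0, 1, n_species),
        "agri_associated": True,
    })
    rows = []
    for sp in traits["species_id"]:
        if zone_subsets:
            zs = rng.choice(n_zones, size=int(rng.integers(4, min(8, n_zones + 1))),
                            replace=False)
        else:
            zs = np.arange(n_zones)
        rows.extend({"species_id": sp, "zone": zones[zi], "interval": iv, "trend": 0.0}
                    for zi in zs for iv in intervals)
    trends = pd.DataFrame(rows)
    design0 = build_design(trends, drivers, traits, version=version)
    beta = np.zeros(len(design0.x_cols))
    for name, val in (coef or {}).items():
        beta[design0.x_cols.index(name)] = val
    b = np.zeros((len(design0.species), len(design0.w_cols)))
    if slope_sd > 0:
        b[:, design0.w_cols.index("temp_mean_change")] = rng.normal(
            0, slope_sd, len(design0.species))
    y = (design0.X @ beta
         + np.einsum("nq,nq->n", design0.W, b[design0.sp_idx])
         + rng.normal(0, resid_sd, design0.n))
    trends = design0.frame[["species_id", "zone", "interval"]].copy()
    trends["trend"] = signed_square(y)
    design = build_design(trends, drivers, traits, version=version)
    return {"design": design, "drivers": drivers, "traits": traits,
            "scaling": scaling, "beta_true": beta, "x_cols": design0.x_cols,
            "zones": zones, "trends": trends}
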