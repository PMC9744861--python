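"""Hierarchical regression of short-term trends on climate and land-use change.

The response is the sign-preserving square root of the 5-year change in a
species' zonal mean occupancy, one row per (species, zone, interval).  Fixed
effects comprise three climate-change and three land-use-change variables
(standardized over their zone x interval replicates), two species traits
(standardized over species), elevation class, group and interval factors
(sum-to-zero coded), and the interaction structure: elevation x each driver
except crop-use intensity (crop fields are too scarce at high elevation),
elevation x traits, all nine climate x land-use products, temperature niche x
climate and habitat specialisation x land use.  Bioclimatic zone gets a
random intercept; species get a random intercept plus independent random
slopes for the six drivers and the nine climate x land-use interactions.

Three model versions control how species not associated with agriculturally
influenced habitats inform the agricultural-area and grassland-intensity
parameters: version 1 zeroes those covariate columns for non-agri species
(the parameters learn only from agri species, everything else from all
species), version 2 drops non-agri species entirely, version 3 uses all rows
and columns.

Inference is blocked Gibbs sampling: coefficients and random effects have
conjugate Gaussian full conditionals; standard deviations (half-Normal
priors) are updated by slice sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drivers import CLIMATE_VARS, LANDUSE_VARS, DRIVER_VARS
from .trends import signed_sqrt

try:  # pragma: no cover
    from sklearn.base import BaseEstimator
except Exception:  # pragma: no cover
    class BaseEstimator:
        def get_params(self, deep=True):
            return dict(self.__dict__)

        def set_params(self, **p):
            self.__dict__.update(p)
            return self

__all__ = [
    "RegressionDesign",
    "TrendRegression",
    "build_design",
    "fit_trend_regression",
    "sensitivity_filter",
    "fixed_effect_columns",
    "random_slope_columns",
    "AGRI_VARS",
]

AGRI_VARS = ["agri_area_change", "grassland_intensity_change"]
TRAIT_VARS = ["temperature_niche", "habitat_specialisation"]


def fixed_effect_columns(groups: list[str], intervals: list[str]) -> list[str]:
    """Deterministic fixed-effect column order (test-pinned)."""
    cols = ["intercept"]
    cols += [f"group_s{i + 1}" for i in range(len(groups) - 1)]
    cols += [f"interval_s{i + 1}" for i in range(len(intervals) - 1)]
    cols += ["elev_high"]
    cols += DRIVER_VARS
    cols += TRAIT_VARS
    cols += [f"elev_high:{d}" for d in DRIVER_VARS if d != "crop_intensity_change"]
    cols += [f"elev_high:{t}" for t in TRAIT_VARS]
    cols += [f"{c}:{l}" for c in CLIMATE_VARS for l in LANDUSE_VARS]
    cols += [f"temperature_niche:{c}" for c in CLIMATE_VARS]
    cols += [f"habitat_specialisation:{l}" for l in LANDUSE_VARS]
    return cols


def random_slope_columns() -> list[str]:
    return ["intercept"] + DRIVER_VARS + [f"{c}:{l}" for c in CLIMATE_VARS
                                          for l in LANDUSE_VARS]


def _sum_to_zero(levels: list, values: pd.Series) -> np.ndarray:
    """contr.sum coding: last level is minus the sum of the others."""
    k = len(levels)
    out = np.zeros((len(values), k - 1))
    for i, lev in enumerate(levels[:-1]):
        out[:, i] = (values == lev).to_numpy(dtype=float)
    out[(values == levels[-1]).to_numpy(), :] = -1.0
    return out


@dataclass
class RegressionDesign:
    """Model matrices and bookkeeping for the trend regression."""

    frame: pd.DataFrame                 # tidy rows incl. standardized covariates
    X: np.ndarray                       # fixed-effect matrix
    W: np.ndarray                       # random-slope matrix (species level)
    y: np.ndarray                       # signed-sqrt response
    x_cols: list
    w_cols: list
    species: list
    zones: list
    groups: list
    intervals: list
    sp_idx: np.ndarray
    zone_idx: np.ndarray
    version: int
    trait_scaling: pd.DataFrame
    agri_of_species: pd.Series

    @property
    def n(self):
        return len(self.y)


def _build_matrices(frame: pd.DataFrame, groups, intervals, version, agri_of_species):
    x_cols = fixed_effect_columns(groups, intervals)
    w_cols = random_slope_columns()
    n = len(frame)
    cols = {"intercept": np.ones(n)}
    gs = _sum_to_zero(groups, frame["group"])
    for i in range(len(groups) - 1):
        cols[f"group_s{i + 1}"] = gs[:, i]
    ks = _sum_to_zero(intervals, frame["interval"])
    for i in range(len(intervals) - 1):
        cols[f"interval_s{i + 1}"] = ks[:, i]
    elev = np.where(frame["elevation_class"].to_numpy() == "high", 0.5, -0.5)
    cols["elev_high"] = elev
    for d in DRIVER_VARS:
        cols[d] = frame[d].to_numpy(dtype=float)
    for t in TRAIT_VARS:
        cols[t] = frame[f"{t}_scaled"].to_numpy(dtype=float)
    for d in DRIVER_VARS:
        if d != "crop_intensity_change":
            cols[f"elev_high:{d}"] = elev * cols[d]
    for t in TRAIT_VARS:
        cols[f"elev_high:{t}"] = elev * cols[t]
    for c in CLIMATE_VARS:
        for l in LANDUSE_VARS:
            cols[f"{c}:{l}"] = cols[c] * cols[l]
    for c in CLIMATE_VARS:
        cols[f"temperature_niche:{c}"] = cols["temperature_niche"] * cols[c]
    for l in LANDUSE_VARS:
        cols[f"habitat_specialisation:{l}"] = cols["habitat_specialisation"] * cols[l]

    agri_row = frame["species_id"].map(agri_of_species).to_numpy(dtype=bool)
    if version == 1:
        # agricultural-area / grassland parameters learn only from agri species
        for name in list(cols):
            if any(v in name.split(":") for v in AGRI_VARS):
                cols[name] = np.where(agri_row, cols[name], 0.0)
    X = np.column_stack([cols[c] for c in x_cols])
    W = np.column_stack([cols[c] for c in w_cols])
    return X, W, x_cols, w_cols


def build_design(trends: pd.DataFrame, drivers: pd.DataFrame, traits: pd.DataFrame,
                 version: int = 1, squares: pd.DataFrame | None = None) -> RegressionDesign:
    """Assemble the regression design from aligned trend/driver/trait tables.

    ``trends``: columns species_id, zone, interval, trend (5-year occupancy
    change, untransformed).  ``drivers``: standardized changes per
    (zone, interval).  ``traits``: species_id, group, temperature_niche,
    habitat_specialisation, agri_associated.  Rows failing to align raise
    with the orphan keys listed.
    """
    if version not in (1, 2, 3):
        raise ValueError("version must be 1, 2 or 3")
    df = trends.merge(drivers, on=["zone", "interval"], how="left", validate="m:1")
    miss = df[DRIVER_VARS[0]].isna()
    if miss.any():
        orphans = df.loc[miss, ["zone", "interval"]].drop_duplicates()
        raise ValueError(f"trend rows without driver data: {orphans.to_dict('records')[:5]}")
    tcols = ["species_id", "group", "temperature_niche", "habitat_specialisation",
             "agri_associated"]
    df = df.merge(traits[tcols], on="species_id", how="left", validate="m:1")
    if df["group"].isna().any():
        orphans = sorted(df.loc[df["group"].isna(), "species_id"].unique())[:5]
        raise ValueError(f"trend rows without traits, e.g. {orphans}")
    if "elevation_class" not in df:
        df["elevation_class"] = np.where(df["zone"].str.endswith("high"), "high", "low")

    agri_of_species = traits.set_index("species_id")["agri_associated"].astype(bool)
    if version == 2:
        df = df[df["species_id"].map(agri_of_species)].reset_index(drop=True)
        if df.empty:
            raise ValueError("version 2 design empty: no agri-associated species")

    # traits standardized at the species level (each species counted once)
    sp_tr = df.drop_duplicates("species_id")
    scale_rows = []
    for t in TRAIT_VARS:
        m, s = float(sp_tr[t].mean()), float(sp_tr[t].std(ddof=0))
        s = s if s > 0 else 1.0
        df[f"{t}_scaled"] = (df[t] - m) / s
        scale_rows.append({"variable": t, "mean": m, "sd": s})
    trait_scaling = pd.DataFrame(scale_rows).set_index("variable")

    groups = sorted(df["group"].unique())
    intervals = sorted(df["interval"].unique())
    species = sorted(df["species_id"].unique())
    zones = sorted(df["zone"].unique())
    df = df.sort_values(["species_id", "zone", "interval"]).reset_index(drop=True)
    X, W, x_cols, w_cols = _build_matrices(df, groups, intervals, version, agri_of_species)
    sp_map = {s: i for i, s in enumerate(species)}
    z_map = {z: i for i, z in enumerate(zones)}
    return RegressionDesign(
        frame=df, X=X, W=W, y=signed_sqrt(df["trend"].to_numpy(dtype=float)),
        x_cols=x_cols, w_cols=w_cols, species=species, zones=zones,
        groups=groups, intervals=intervals,
        sp_idx=df["species_id"].map(sp_map).to_numpy(dtype=int),
        zone_idx=df["zone"].map(z_map).to_numpy(dtype=int),
        version=version, trait_scaling=trait_scaling,
        agri_of_species=agri_of_species,
    )


def sensitivity_filter(design: RegressionDesign, mode: str,
                       record_counts: pd.DataFrame | None = None,
                       traits: pd.DataFrame | None = None,
                       min_zone_records: int = 41,
                       lowest_fraction: float = 0.20) -> RegressionDesign:
    """Refit designs for the sensitivity analyses.

    ``mode='species'`` drops flagged species (migratory / introduced /
    taxonomically difficult) and the lowest 20% of species per group by
    total record count; ``mode='sparse_zones'`` drops species-zone
    combinations with fewer than ``min_zone_records`` records.
    ``record_counts``: columns species_id, zone, n_records.
    """
    df = design.frame
    if mode == "species":
        if traits is None or record_counts is None:
            raise ValueError("mode 'species' needs traits and record_counts")
        flagged = set(traits.loc[traits["flag_excluded"].astype(bool), "species_id"])
        tot = record_counts.groupby("species_id")["n_records"].sum()
        drop = set(flagged)
        gmap = traits.set_index("species_id")["group"]
        for g, members in tot.groupby(gmap):
            k = int(np.floor(lowest_fraction * len(members)))
            drop |= set(members.nsmallest(k).index)
        keep = ~df["species_id"].isin(drop)
    elif mode == "sparse_zones":
        if record_counts is None:
            raise ValueError("mode 'sparse_zones' needs record_counts")
        sparse = record_counts[record_counts["n_records"] < min_zone_records]
        bad = set(zip(sparse["species_id"], sparse["zone"]))
        keep = ~pd.Series(list(zip(df["species_id"], df["zone"])), index=df.index).isin(bad)
    else:
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    sub = df[keep]
    if sub.empty:
        raise ValueError(f"sensitivity filter {mode!r} removed every row")
    trends = sub[["species_id", "zone", "interval", "trend"]]
    drivers_part = sub[["zone", "interval"] + DRIVER_VARS].drop_duplicates()
    traits_part = sub.drop_duplicates("species_id")[
        ["species_id", "group", "temperature_niche", "habitat_specialisation",
         "agri_associated"]]
    return build_design(trends, drivers_part, traits_part, version=design.version)


# ---------------------------------------------------------------------------
# slice sampler for SD parameters
# ---------------------------------------------------------------------------

def _slice_positive(x0, logp, rng, w=0.5, max_steps=50):
    """Univariate slice sampling on (0, inf) with stepping-out."""
    logy = logp(x0) + np.log(rng.uniform())
    lo = max(1e-12, x0 - w * rng.uniform())
    hi = lo + w
    steps = 0
    while lo > 1e-12 and logp(lo) > logy and steps < max_steps:
        lo = max(1e-12, lo - w)
        steps += 1
    steps = 0
    while logp(hi) > logy and steps < max_steps:
        hi += w
        steps += 1
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logp(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class TrendRegression(BaseEstimator):
    """Bayesian linear mixed model for signed-sqrt short-term trends.

    Gaussian likelihood; Normal(0, ``fixed_sd``) priors on fixed effects,
    half-Normal(0, 1) priors on all SDs; zone random intercepts; species
    random intercepts and independent random slopes for drivers and their
    climate x land-use interactions.

    Attributes after ``fit``: ``draws_`` (dict of stacked chain-major
    arrays), ``summary_`` (posterior mean/sd/HDI per fixed effect),
    ``rhat_`` (per fixed effect), ``converged_``.
    """

    def __init__(self, chains=4, n_iter=1000, warmup=500, thin=1, seed=0,
                 fixed_sd=1.0, sd_scale=1.0):
        self.chains = chains
        self.n_iter = n_iter
        self.warmup = warmup
        self.thin = thin
        self.seed = seed
        self.fixed_sd = fixed_sd
        self.sd_scale = sd_scale

    def fit(self, design: RegressionDesign, y=None):
        X, W, yv = design.X, design.W, design.y
        n, p = X.shape
        q = W.shape[1]
        nsp = len(design.species)
        nz = len(design.zones)
        if n == 0:
            raise ValueError("empty design")
        sp, zo = design.sp_idx, design.zone_idx
        XtX = X.T @ X
        # per-species Gram matrices of the random-slope design
        G = np.zeros((nsp, q, q))
        for s in range(nsp):
            Ws = W[sp == s]
            G[s] = Ws.T @ Ws
        nz_counts = np.bincount(zo, minlength=nz).astype(float)

        n_store = max(1, self.n_iter // self.thin)
        out = {
            "beta": np.empty((self.chains, n_store, p)),
            "u": np.empty((self.chains, n_store, nz)),
            "b": np.empty((self.chains, n_store, nsp, q)),
            "tau_u": np.empty((self.chains, n_store)),
            "tau": np.empty((self.chains, n_store, q)),
            "sigma": np.empty((self.chains, n_store)),
        }
        seeds = np.random.SeedSequence(self.seed).spawn(self.chains)
        eye_p = np.eye(p)
        for c in range(self.chains):
            rng = np.random.default_rng(seeds[c])
            beta = np.zeros(p)
            u = np.zeros(nz)
            b = np.zeros((nsp, q))
            tau_u = 0.1
            tau = np.full(q, 0.1)
            sigma = max(float(yv.std()), 0.05)
            k = 0
            for it in range(self.warmup + self.n_iter):
                wb = np.einsum("nq,nq->n", W, b[sp])
                # fixed effects
                r = yv - u[zo] - wb
                prec = XtX / sigma ** 2 + eye_p / self.fixed_sd ** 2
                L = np.linalg.cholesky(prec)
                rhs = X.T @ r / sigma ** 2
                mean = np.linalg.solve(prec, rhs)
                beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
                xb = X @ beta
                # zone intercepts
                r = yv - xb - wb
                prec_u = nz_counts / sigma ** 2 + 1.0 / tau_u ** 2
                mean_u = np.bincount(zo, weights=r, minlength=nz) / sigma ** 2 / prec_u
                u = mean_u + rng.standard_normal(nz) / np.sqrt(prec_u)
                # species effects (batched conjugate draws)
                r = yv - xb - u[zo]
                rhs_s = np.zeros((nsp, q))
                np.add.at(rhs_s, sp, W * r[:, None])
                prec_s = G / sigma ** 2 + np.eye(q)[None] * (1.0 / tau ** 2)[None]
                Ls = np.linalg.cholesky(prec_s)
                mean_s = np.linalg.solve(prec_s, (rhs_s / sigma ** 2)[..., None])[..., 0]
                noise = np.linalg.solve(np.transpose(Ls, (0, 2, 1)),
                                        rng.standard_normal((nsp, q, 1)))[..., 0]
                b = mean_s + noise
                wb = np.einsum("nq,nq->n", W, b[sp])
                # SDs by slice sampling (half-Normal priors)
                ss_u = float(np.sum(u ** 2))
                tau_u = _slice_positive(
                    tau_u,
                    lambda s, ss=ss_u, m=nz: -m * np.log(s) - 0.5 * ss / s ** 2
                    - 0.5 * (s / self.sd_scale) ** 2, rng)
                for j in range(q):
                    ssj = float(np.sum(b[:, j] ** 2))
                    tau[j] = _slice_positive(
                        tau[j],
                        lambda s, ss=ssj, m=nsp: -m * np.log(s) - 0.5 * ss / s ** 2
                        - 0.5 * (s / self.sd_scale) ** 2, rng)
                resid = yv - xb - u[zo] - wb
                rss = float(np.sum(resid ** 2))
                sigma = _slice_positive(
                    sigma,
                    lambda s: -n * np.log(s) - 0.5 * rss / s ** 2
                    - 0.5 * (s / self.sd_scale) ** 2, rng)
                if it >= self.warmup and (it - self.warmup + 1) % self.thin == 0 and k < n_store:
                    out["beta"][c, k] = beta
                    out["u"][c, k] = u
                    out["b"][c, k] = b
                    out["tau_u"][c, k] = tau_u
                    out["tau"][c, k] = tau
                    out["sigma"][c, k] = sigma
                    k += 1
        self.design_ = design
        self.draws_ = out
        self._summarize(design)
        return self

    def _summarize(self, design):
        import arviz as az

        from .trends import hdi

        beta = self.draws_["beta"]
        flat = beta.reshape(-1, beta.shape[-1])
        rows = []
        rh = az.rhat(az.convert_to_dataset(beta))["x"].values if self.chains > 1 else \
            np.full(beta.shape[-1], np.nan)
        for j, name in enumerate(design.x_cols):
            lo, hi = hdi(flat[:, j], 0.95)
            rows.append({"term": name, "mean": float(flat[:, j].mean()),
                         "sd": float(flat[:, j].std()), "hdi_low": lo,
                         "hdi_high": hi, "rhat": float(rh[j])})
        self.summary_ = pd.DataFrame(rows).set_index("term")
        self.rhat_ = self.summary_["rhat"]
        finite = self.rhat_.dropna()
        self.converged_ = bool((finite < 1.1).all()) if len(finite) else True

    # ------------------------------------------------------------------
    def predict_linear(self, X, W, sp_idx, zone_idx, flat=True):
        """Per-draw linear predictor on the signed-sqrt scale."""
        beta = self.draws_["beta"].reshape(-1, self.draws_["beta"].shape[-1])
        u = self.draws_["u"].reshape(-1, self.draws_["u"].shape[-1])
        b = self.draws_["b"].reshape(-1, *self.draws_["b"].shape[-2:])
        eta = beta @ X.T + u[:, zone_idx]
        eta += np.einsum("dnq,nq->dn", b[:, sp_idx, :], W)
        return eta

    def residual_diagnostics(self) -> dict:
        """Residual normality and lag-1 temporal autocorrelation checks."""
        from scipy import stats

        d = self.design_
        beta = self.draws_["beta"].reshape(-1, len(d.x_cols)).mean(axis=0)
        u = self.draws_["u"].reshape(-1, len(d.zones)).mean(axis=0)
        b = self.draws_["b"].reshape(-1, len(d.species), len(d.w_cols)).mean(axis=0)
        fitted = d.X @ beta + u[d.zone_idx] + np.einsum("nq,nq->n", d.W, b[d.sp_idx])
        resid = d.y - fitted
        _, p_norm = stats.normaltest(resid)
        df = d.frame.assign(resid=resid).sort_values(["species_id", "zone", "interval"])
        ac = df.groupby(["species_id", "zone"])["resid"].apply(
            lambda s: s.autocorr(1) if len(s) > 2 else np.nan)
        ac = ac.to_numpy(dtype=float)
        ac_mean = float(np.nanmean(ac)) if np.isfinite(ac).any() else float("nan")
        return {"normality_p": float(p_norm), "lag1_autocorr_mean": ac_mean}


def fit_trend_regression(design, chains=4, n_iter=1000, warmup=500, thin=1,
                         seed=0, **priors) -> TrendRegression:
    m = TrendRegression(chains=chains, n_iter=n_iter, warmup=warmup, thin=thin,
                        seed=seed, **priors)
    return m.fit(design)
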