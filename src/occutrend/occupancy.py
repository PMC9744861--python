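"""Per-species hierarchical occupancy-detection model.

Each square ``i`` in year ``t`` has a latent occupancy state
``z[i,t] ~ Bern(psi[i,t])``; a visit ``j`` to that square yields a detection
``y[i,t,j] | z ~ Bern(z * p[i,t,j])``.  Occurrence probability is modelled on
the logit scale with a global intercept, linear and quadratic scaled
elevation, fine-region and square random intercepts, and a zone-specific
random-walk year effect ``gamma[r, t] ~ Normal(gamma[r, t-1], sigma_gamma_r^2)``
(first year ``Normal(0, 1.5^2)``, ``sigma_gamma_r ~ half-Cauchy(0, 1)``).
Detection probability is modelled on day-of-year (linear + quadratic), list
length (classes 1 / 2-3 / >3 as two dummies), data source (expert, project,
targeted project, red-list inventory against a common-naturalist reference)
and a year random intercept.

The latent state is marginalized analytically, so the likelihood of a
site-year with visits ``y_1..y_J`` is
``psi * prod_j Bern(y_j | p_j) + (1 - psi) * 1{all y_j = 0}``;
site-years with no visits contribute nothing.  Sampling uses a blocked
adaptive Metropolis-within-Gibbs scheme in which square effects, region
effects, zone-year effects (alternating even/odd years) and detection-year
effects are updated as vectorized independent Metropolis steps, exploiting
their conditional independence given the other blocks.

Derived quantities are the annual mean occupancy per bioclimatic zone (mean
of psi over the zone's squares) and country-wide (mean over all squares, with
squares in zones lacking any record of the species contributing zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    from sklearn.base import BaseEstimator
except Exception:  # pragma: no cover
    class BaseEstimator:  # minimal stand-in
        def get_params(self, deep=True):
            return dict(self.__dict__)

        def set_params(self, **p):
            self.__dict__.update(p)
            return self

__all__ = [
    "OccupancyDesign",
    "OccupancyParams",
    "OccupancyPosterior",
    "OccupancyModel",
    "marginal_loglik",
    "fit_occupancy_model",
    "derive_mean_occupancy",
    "check_convergence",
    "DEFAULT_PRIORS",
]

DETECTION_COVARIATES = [
    "yday_scaled", "yday_scaled_sq", "shortlist", "longlist",
    "expert", "project", "targeted_project", "redlist",
]

DEFAULT_PRIORS = {
    "intercept_sd": 1.5,        # mu_o, mu_d: wide on logit scale without piling mass at 0/1
    "slope_sd": 1.5,            # elevation and detection covariate effects
    "gamma_first_sd": 1.5,      # first-year zone effect
    "sd_prior": "half_normal",  # hierarchical SDs except the random-walk SD
    "sd_scale": 1.0,
    "gamma_sd_prior": "half_cauchy",
    "gamma_sd_scale": 1.0,
}


def _softplus(x):
    return np.logaddexp(0.0, x)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class OccupancyDesign:
    """Packed per-species design for the occupancy-detection model.

    ``sites`` must contain one row per square of the group's dataset with
    columns ``square_id``, ``elevation_scaled``, ``region`` and ``zone``;
    ``visits`` one row per (visit, species) with columns ``square_id``,
    ``year``, ``y`` and the detection covariates.  ``years`` spans the fitted
    range (including any warm-up years); ``analysis_years`` the subrange kept
    in derived occupancy series.
    """

    species_id: str
    sites: pd.DataFrame
    visits: pd.DataFrame
    years: np.ndarray
    analysis_years: np.ndarray | None = None

    # packed arrays, built in __post_init__
    elev: np.ndarray = field(init=False, repr=False)
    region_idx: np.ndarray = field(init=False, repr=False)
    zone_idx: np.ndarray = field(init=False, repr=False)
    zones: list = field(init=False, repr=False)
    regions: list = field(init=False, repr=False)
    zone_has_record: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        if self.analysis_years is None:
            self.analysis_years = self.years.copy()
        self.analysis_years = np.asarray(self.analysis_years, dtype=int)
        sites = self.sites.reset_index(drop=True)
        self.sites = sites
        self.zones = sorted(sites["zone"].unique().tolist())
        self.regions = sorted(sites["region"].unique().tolist())
        self.elev = sites["elevation_scaled"].to_numpy(dtype=float)
        zmap = {z: k for k, z in enumerate(self.zones)}
        rmap = {r: k for k, r in enumerate(self.regions)}
        self.zone_idx = sites["zone"].map(zmap).to_numpy(dtype=int)
        self.region_idx = sites["region"].map(rmap).to_numpy(dtype=int)
        smap = {s: k for k, s in enumerate(sites["square_id"])}
        v = self.visits.reset_index(drop=True).copy()
        if not set(v["square_id"]).issubset(smap):
            orphans = sorted(set(v["square_id"]) - set(smap))[:5]
            raise ValueError(f"visits reference unknown squares, e.g. {orphans}")
        ymap = {int(y): k for k, y in enumerate(self.years)}
        if not set(int(y) for y in v["year"]).issubset(ymap):
            raise ValueError("visits reference years outside the design range")
        v["_site"] = v["square_id"].map(smap)
        v["_year"] = v["year"].map(ymap)
        self.visits = v
        det = np.zeros(len(self.zones), dtype=bool)
        if len(v):
            got = v.loc[v["y"] == 1, "_site"]
            det_zones = np.unique(self.zone_idx[got.to_numpy(dtype=int)])
            det[det_zones] = True
        self.zone_has_record = det

    @property
    def n_sites(self):
        return len(self.sites)

    @property
    def n_years(self):
        return len(self.years)

    def packed(self):
        """Arrays used by the likelihood and sampler."""
        v = self.visits
        v_site = v["_site"].to_numpy(dtype=int)
        v_year = v["_year"].to_numpy(dtype=int)
        v_y = v["y"].to_numpy(dtype=float)
        Xd = np.column_stack([
            v["yday_scaled"].to_numpy(dtype=float),
            v["yday_scaled"].to_numpy(dtype=float) ** 2,
            v["shortlist"].to_numpy(dtype=float),
            v["longlist"].to_numpy(dtype=float),
            v["expert"].to_numpy(dtype=float),
            v["project"].to_numpy(dtype=float),
            v["targeted_project"].to_numpy(dtype=float),
            v["redlist"].to_numpy(dtype=float),
        ])
        code = v_site * self.n_years + v_year
        order = np.argsort(code, kind="stable")
        code_s = code[order]
        uniq, seg_start = np.unique(code_s, return_index=True)
        sy_site = uniq // self.n_years
        sy_year = uniq % self.n_years
        v_sy = np.searchsorted(uniq, code)  # visit -> site-year row
        any_det = np.zeros(uniq.size, dtype=bool)
        np.add.at(any_det, v_sy, v_y > 0)
        return {
            "v_site": v_site, "v_year": v_year, "v_y": v_y, "Xd": Xd,
            "v_sy": v_sy, "sy_site": sy_site, "sy_year": sy_year,
            "allzero": ~any_det, "n_sy": uniq.size,
        }


# ---------------------------------------------------------------------------
# parameters and likelihood
# ---------------------------------------------------------------------------

@dataclass
class OccupancyParams:
    """One point in parameter space (natural parameterisation)."""

    mu_o: float
    beta_o1: float
    beta_o2: float
    sigma_o1: float
    sigma_o2: float
    alpha_o1: np.ndarray          # region effects (R,)
    alpha_o2: np.ndarray          # square effects (S,)
    gamma: np.ndarray             # zone-year effects (Z, T)
    sigma_gamma: np.ndarray       # random-walk SDs (Z,)
    mu_d: float
    beta_d: np.ndarray            # detection covariate effects (8,)
    sigma_d1: float
    alpha_d1: np.ndarray          # detection year effects (T,)

    @classmethod
    def zeros(cls, n_regions, n_sites, n_zones, n_years):
        return cls(
            mu_o=0.0, beta_o1=0.0, beta_o2=0.0, sigma_o1=0.5, sigma_o2=0.5,
            alpha_o1=np.zeros(n_regions), alpha_o2=np.zeros(n_sites),
            gamma=np.zeros((n_zones, n_years)), sigma_gamma=np.full(n_zones, 0.3),
            mu_d=0.0, beta_d=np.zeros(8), sigma_d1=0.3, alpha_d1=np.zeros(n_years),
        )


def _occ_linpred_sy(design, params, packed):
    base = (params.mu_o + params.beta_o1 * design.elev + params.beta_o2 * design.elev ** 2
            + params.alpha_o1[design.region_idx] + params.alpha_o2)
    return base[packed["sy_site"]] + params.gamma[design.zone_idx[packed["sy_site"]], packed["sy_year"]]


def _det_linpred_v(params, packed):
    return params.mu_d + packed["Xd"] @ params.beta_d + params.alpha_d1[packed["v_year"]]


def _det_loglik_sy(lp_v, packed):
    per_visit = np.where(packed["v_y"] > 0, -_softplus(-lp_v), -_softplus(lp_v))
    out = np.zeros(packed["n_sy"])
    np.add.at(out, packed["v_sy"], per_visit)
    return out


def _sy_loglik(occ_lin_sy, dll_sy, allzero):
    log_psi = -_softplus(-occ_lin_sy)
    log_1mpsi = -_softplus(occ_lin_sy)
    with_det = log_psi + dll_sy
    return np.where(allzero, np.logaddexp(with_det, log_1mpsi), with_det)


def marginal_loglik(design: OccupancyDesign, params: OccupancyParams) -> float:
    """Data log-likelihood with the latent occupancy state summed out.

    For every site-year with visits:
    ``log[ psi * prod_j Bern(y_j|p_j) + (1-psi) * 1{all y_j=0} ]``.
    Site-years without visits contribute 0.
    """
    packed = design.packed()
    occ_lin = _occ_linpred_sy(design, params, packed)
    det_lin = _det_linpred_v(params, packed)
    for name, arr in (("occupancy", occ_lin), ("detection", det_lin)):
        if arr.size and not np.all(np.isfinite(arr)):
            bad = int(np.argmax(~np.isfinite(arr)))
            raise FloatingPointError(f"non-finite {name} linear predictor at row {bad}")
    dll = _det_loglik_sy(det_lin, packed)
    return float(_sy_loglik(occ_lin, dll, packed["allzero"]).sum())


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _log_half_normal(s, scale):
    return np.where(s > 0, -0.5 * (s / scale) ** 2, -np.inf)


def _log_half_cauchy(s, scale):
    return np.where(s > 0, -np.log1p((s / scale) ** 2), -np.inf)


def _log_sd_prior(s, kind, scale):
    if kind == "half_normal":
        return _log_half_normal(s, scale)
    if kind == "half_cauchy":
        return _log_half_cauchy(s, scale)
    raise ValueError(f"unknown SD prior {kind!r}")


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

class _Chain:
    """State and adaptive step sizes for one MCMC chain."""

    def __init__(self, design, packed, priors, rng):
        self.d = design
        self.pk = packed
        self.pr = priors
        self.rng = rng
        S, T = design.n_sites, design.n_years
        Z, R = len(design.zones), len(design.regions)
        p = OccupancyParams.zeros(R, S, Z, T)
        # crude initialisation from naive occupancy
        naive = max(0.02, min(0.98, float(np.mean(~packed["allzero"])) if packed["n_sy"] else 0.5))
        p.mu_o = float(np.log(naive / (1 - naive)))
        p.mu_d = -0.5
        self.p = p
        # adaptive scales
        self.s_occ = 0.1
        self.s_det = 0.1
        self.s_sq = np.full(S, 0.8)
        self.s_reg = np.full(R, 0.5)
        self.s_gam = np.full((Z, T), 0.5)
        self.s_dy = np.full(T, 0.5)
        self.s_sig = {"o1": 0.5, "o2": 0.5, "d1": 0.5}
        self.s_sg = np.full(Z, 0.5)
        # caches
        self.occ_lin = _occ_linpred_sy(design, p, packed)
        self.det_lin = _det_linpred_v(p, packed)
        self.dll = _det_loglik_sy(self.det_lin, packed)
        self.ll_sy = _sy_loglik(self.occ_lin, self.dll, packed["allzero"])

    # -- adaptation helpers -------------------------------------------------
    @staticmethod
    def _adapt(scale, acc, it, target):
        return scale * np.exp((acc - target) / np.sqrt(it + 1.0))

    # -- block updates ------------------------------------------------------
    def _update_occ_globals(self, it, adapt):
        p, pr = self.p, self.pr
        cur = np.array([p.mu_o, p.beta_o1, p.beta_o2])
        prop = cur + self.s_occ * self.rng.standard_normal(3) * np.array([1.0, 0.7, 0.7])
        delta = (prop[0] - cur[0]) + (prop[1] - cur[1]) * self.d.elev[self.pk["sy_site"]] \
            + (prop[2] - cur[2]) * self.d.elev[self.pk["sy_site"]] ** 2
        new_occ = self.occ_lin + delta
        new_ll = _sy_loglik(new_occ, self.dll, self.pk["allzero"])
        lp = (new_ll.sum() - self.ll_sy.sum()
              - 0.5 * (prop[0] ** 2 - cur[0] ** 2) / pr["intercept_sd"] ** 2
              - 0.5 * (prop[1] ** 2 - cur[1] ** 2) / pr["slope_sd"] ** 2
              - 0.5 * (prop[2] ** 2 - cur[2] ** 2) / pr["slope_sd"] ** 2)
        acc = float(np.log(self.rng.uniform()) < lp)
        if acc:
            p.mu_o, p.beta_o1, p.beta_o2 = prop
            self.occ_lin, self.ll_sy = new_occ, new_ll
        if adapt:
            self.s_occ = self._adapt(self.s_occ, acc, it, 0.25)

    def _update_det_globals(self, it, adapt):
        p, pr = self.p, self.pr
        cur = np.concatenate([[p.mu_d], p.beta_d])
        prop = cur + self.s_det * self.rng.standard_normal(9) * 0.6
        new_det_lin = prop[0] + self.pk["Xd"] @ prop[1:] + p.alpha_d1[self.pk["v_year"]]
        new_dll = _det_loglik_sy(new_det_lin, self.pk)
        new_ll = _sy_loglik(self.occ_lin, new_dll, self.pk["allzero"])
        pri = (-0.5 * (prop[0] ** 2 - cur[0] ** 2) / pr["intercept_sd"] ** 2
               - 0.5 * np.sum(prop[1:] ** 2 - cur[1:] ** 2) / pr["slope_sd"] ** 2)
        lp = new_ll.sum() - self.ll_sy.sum() + pri
        acc = float(np.log(self.rng.uniform()) < lp)
        if acc:
            p.mu_d, p.beta_d = float(prop[0]), prop[1:].copy()
            self.det_lin, self.dll, self.ll_sy = new_det_lin, new_dll, new_ll
        if adapt:
            self.s_det = self._adapt(self.s_det, acc, it, 0.25)

    def _vector_mh(self, unit_of_sy, n_units, prop_delta, prior_delta, it, scales, adapt,
                   target=0.44, active=None):
        """Vectorized independent MH over a partition of site-years.

        ``prop_delta`` is the per-unit proposed additive change to the
        occupancy linear predictor; units are conditionally independent given
        everything else because each site-year belongs to exactly one unit.
        ``active`` masks the units actually proposed this call (others are
        left untouched and not adapted).  Returns the per-unit accept mask
        and the applied deltas.
        """
        new_occ = self.occ_lin + prop_delta[unit_of_sy]
        new_ll = _sy_loglik(new_occ, self.dll, self.pk["allzero"])
        dll_unit = np.bincount(unit_of_sy, weights=new_ll - self.ll_sy, minlength=n_units)
        accept = np.log(self.rng.uniform(size=n_units)) < dll_unit + prior_delta
        if active is not None:
            accept &= active
        applied = np.where(accept, prop_delta, 0.0)
        if np.any(accept):
            self.occ_lin = self.occ_lin + applied[unit_of_sy]
            keep = accept[unit_of_sy]
            self.ll_sy = np.where(keep, new_ll, self.ll_sy)
        if adapt:
            step = (accept.astype(float) - target) / np.sqrt(it + 1.0)
            if active is not None:
                step = np.where(active, step, 0.0)
            scales *= np.exp(step)
        return accept, applied

    def _update_squares(self, it, adapt):
        p = self.p
        S = self.d.n_sites
        eps = self.s_sq * self.rng.standard_normal(S)
        prop = p.alpha_o2 + eps
        pri = -0.5 * (prop ** 2 - p.alpha_o2 ** 2) / p.sigma_o2 ** 2
        unit = self.pk["sy_site"]
        accept, applied = self._vector_mh(unit, S, eps, pri, it, self.s_sq, adapt)
        p.alpha_o2 = p.alpha_o2 + applied

    def _update_regions(self, it, adapt):
        p = self.p
        R = len(self.d.regions)
        eps = self.s_reg * self.rng.standard_normal(R)
        prop = p.alpha_o1 + eps
        pri = -0.5 * (prop ** 2 - p.alpha_o1 ** 2) / p.sigma_o1 ** 2
        unit = self.d.region_idx[self.pk["sy_site"]]
        accept, applied = self._vector_mh(unit, R, eps, pri, it, self.s_reg, adapt)
        p.alpha_o1 = p.alpha_o1 + applied

    def _gamma_prior_delta(self, g_new, g_old):
        """Change in the random-walk log-prior when single gamma entries move
        (neighbours held fixed)."""
        p, pr = self.p, self.pr
        Z, T = g_old.shape
        sg2 = p.sigma_gamma[:, None] ** 2
        d = np.zeros_like(g_old)
        # own term
        prev = np.concatenate([np.zeros((Z, 1)), g_old[:, :-1]], axis=1)
        var_own = np.concatenate(
            [np.full((Z, 1), pr["gamma_first_sd"] ** 2), np.broadcast_to(sg2, (Z, T))[:, 1:]], axis=1)
        d += -0.5 * ((g_new - prev) ** 2 - (g_old - prev) ** 2) / var_own
        # successor term
        if T > 1:
            succ = g_old[:, 1:]
            d[:, :-1] += -0.5 * ((succ - g_new[:, :-1]) ** 2 - (succ - g_old[:, :-1]) ** 2) / sg2
        return d

    def _update_gamma(self, it, adapt):
        p = self.p
        Z, T = p.gamma.shape
        zone_of_sy = self.d.zone_idx[self.pk["sy_site"]]
        unit_all = zone_of_sy * T + self.pk["sy_year"]
        for parity in (0, 1):
            tmask = np.zeros(T, dtype=bool)
            tmask[parity::2] = True
            eps = np.where(tmask[None, :], self.s_gam * self.rng.standard_normal((Z, T)), 0.0)
            g_new = p.gamma + eps
            pri = self._gamma_prior_delta(g_new, p.gamma)
            active = np.broadcast_to(tmask[None, :], (Z, T)).ravel()
            accept, applied = self._vector_mh(
                unit_all, Z * T, eps.ravel(), pri.ravel(), it,
                self.s_gam.ravel(), adapt, active=active)
            p.gamma = p.gamma + applied.reshape(Z, T)

    def _update_det_years(self, it, adapt):
        p = self.p
        T = self.d.n_years
        eps = self.s_dy * self.rng.standard_normal(T)
        prop = p.alpha_d1 + eps
        pri = -0.5 * (prop ** 2 - p.alpha_d1 ** 2) / p.sigma_d1 ** 2
        new_det_lin = self.det_lin + eps[self.pk["v_year"]]
        new_dll = _det_loglik_sy(new_det_lin, self.pk)
        new_ll = _sy_loglik(self.occ_lin, new_dll, self.pk["allzero"])
        unit = self.pk["sy_year"]
        dll_unit = np.bincount(unit, weights=new_ll - self.ll_sy, minlength=T)
        accept = np.log(self.rng.uniform(size=T)) < dll_unit + pri
        applied = np.where(accept, eps, 0.0)
        if np.any(accept):
            p.alpha_d1 = p.alpha_d1 + applied
            self.det_lin = self.det_lin + applied[self.pk["v_year"]]
            self.dll = _det_loglik_sy(self.det_lin, self.pk)
            self.ll_sy = _sy_loglik(self.occ_lin, self.dll, self.pk["allzero"])
        if adapt:
            self.s_dy *= np.exp((accept.astype(float) - 0.44) / np.sqrt(it + 1.0))

    def _update_sigma(self, name, effects, it, adapt, kind, scale):
        p = self.p
        cur = getattr(p, name)
        step = self.s_sig[name.split("_")[-1]]
        prop = cur * np.exp(step * self.rng.standard_normal())
        n = effects.size
        ss = float(np.sum(effects ** 2))

        def logpost(s):
            return (-n * np.log(s) - 0.5 * ss / s ** 2
                    + float(_log_sd_prior(np.asarray(s), kind, scale)) + np.log(s))  # + Jacobian

        lp = logpost(prop) - logpost(cur)
        acc = float(np.log(self.rng.uniform()) < lp)
        if acc:
            setattr(p, name, float(prop))
        if adapt:
            self.s_sig[name.split("_")[-1]] = self._adapt(step, acc, it, 0.44)

    def _update_sigma_gamma(self, it, adapt):
        p, pr = self.p, self.pr
        Z, T = p.gamma.shape
        if T < 2:
            return
        inc = np.diff(p.gamma, axis=1)
        n = inc.shape[1]
        ss = np.sum(inc ** 2, axis=1)
        cur = p.sigma_gamma
        prop = cur * np.exp(self.s_sg * self.rng.standard_normal(Z))

        def logpost(s):
            return (-n * np.log(s) - 0.5 * ss / s ** 2
                    + _log_sd_prior(s, pr["gamma_sd_prior"], pr["gamma_sd_scale"]) + np.log(s))

        accept = np.log(self.rng.uniform(size=Z)) < logpost(prop) - logpost(cur)
        p.sigma_gamma = np.where(accept, prop, cur)
        if adapt:
            self.s_sg *= np.exp((accept.astype(float) - 0.44) / np.sqrt(it + 1.0))

    def sweep(self, it, adapt):
        self._update_occ_globals(it, adapt)
        self._update_squares(it, adapt)
        self._update_regions(it, adapt)
        self._update_gamma(it, adapt)
        self._update_det_globals(it, adapt)
        self._update_det_years(it, adapt)
        p, pr = self.p, self.pr
        self._update_sigma("sigma_o1", p.alpha_o1, it, adapt, pr["sd_prior"], pr["sd_scale"])
        self._update_sigma("sigma_o2", p.alpha_o2, it, adapt, pr["sd_prior"], pr["sd_scale"])
        self._update_sigma("sigma_d1", p.alpha_d1, it, adapt, pr["sd_prior"], pr["sd_scale"])
        self._update_sigma_gamma(it, adapt)


# ---------------------------------------------------------------------------
# posterior container and derived quantities
# ---------------------------------------------------------------------------

@dataclass
class OccupancyPosterior:
    """Posterior draws (chain-major) and derived mean-occupancy series."""

    species_id: str
    draws: dict                 # name -> array (chains, draws, ...)
    zones: list
    years: np.ndarray
    analysis_years: np.ndarray
    zone_occ: np.ndarray        # (chains, draws, Z, T_analysis)
    country_occ: np.ndarray     # (chains, draws, T_analysis)
    zone_has_record: np.ndarray
    n_squares_per_zone: np.ndarray

    @property
    def n_chains(self):
        return self.country_occ.shape[0]

    @property
    def n_draws(self):
        return self.country_occ.shape[1]

    def flat(self, name):
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def zone_occ_flat(self):
        return self.zone_occ.reshape(-1, *self.zone_occ.shape[2:])

    def country_occ_flat(self):
        return self.country_occ.reshape(-1, self.country_occ.shape[2])

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        flat_zone = self.zone_occ_flat()
        flat_cty = self.country_occ_flat()
        for d in range(flat_cty.shape[0]):
            for t, yr in enumerate(self.analysis_years):
                rows.append({"draw": d, "zone": "CH", "year": int(yr),
                             "mean_occupancy": float(flat_cty[d, t])})
                for z, zn in enumerate(self.zones):
                    rows.append({"draw": d, "zone": zn, "year": int(yr),
                                 "mean_occupancy": float(flat_zone[d, z, t])})
        return pd.DataFrame(rows)


def derive_mean_occupancy(draw_params: dict, design: OccupancyDesign) -> tuple[np.ndarray, np.ndarray]:
    """Zone and country-wide annual mean occupancy for stored draws.

    ``draw_params`` holds stacked arrays over (chain, draw).  Returns
    ``(zone_occ, country_occ)`` restricted to the analysis years; squares in
    zones where the species was never recorded count as unoccupied in the
    country-wide mean.
    """
    mu = draw_params["mu_o"]
    C, D = mu.shape
    S, T = design.n_sites, design.n_years
    Z = len(design.zones)
    keep = np.isin(design.years, design.analysis_years)
    Ta = int(keep.sum())
    n_per_zone = np.bincount(design.zone_idx, minlength=Z)
    zone_occ = np.empty((C, D, Z, Ta))
    country = np.empty((C, D, Ta))
    rec = design.zone_has_record.astype(float)
    w_zone = n_per_zone / n_per_zone.sum()
    elev, elev2 = design.elev, design.elev ** 2
    for c in range(C):
        for d in range(D):
            base = (mu[c, d] + draw_params["beta_o1"][c, d] * elev
                    + draw_params["beta_o2"][c, d] * elev2
                    + draw_params["alpha_o1"][c, d][design.region_idx]
                    + draw_params["alpha_o2"][c, d])
            psi = _expit(base[:, None] + draw_params["gamma"][c, d][design.zone_idx][:, keep])
            zsum = np.zeros((Z, Ta))
            np.add.at(zsum, design.zone_idx, psi)
            zmean = zsum / n_per_zone[:, None]
            zone_occ[c, d] = zmean
            country[c, d] = (w_zone * rec) @ zmean
    return zone_occ, country


def check_convergence(posterior: OccupancyPosterior, threshold: float = 1.1) -> dict:
    """Split-R-hat for every derived mean-occupancy value.

    Returns the diagnostic table and the fraction of values below the
    threshold; with a single chain the diagnostic is marked unavailable.
    """
    import arviz as az

    if posterior.n_chains < 2:
        return {"available": False, "reason": "need >=2 chains for split-R-hat"}
    vals = {}
    rz = az.rhat(az.convert_to_dataset(posterior.zone_occ))["x"].values  # (Z, Ta)
    rc = az.rhat(az.convert_to_dataset(posterior.country_occ))["x"].values  # (Ta,)
    table = pd.DataFrame({
        "series": (["country"] * rc.size
                   + [f"zone:{z}" for z in posterior.zones for _ in posterior.analysis_years]),
        "year": (list(posterior.analysis_years) * (1 + len(posterior.zones))),
        "rhat": np.concatenate([rc.ravel(), rz.ravel()]),
    })
    finite = table["rhat"].to_numpy()
    finite = finite[np.isfinite(finite)]
    vals = {
        "available": True,
        "table": table,
        "fraction_below_threshold": float(np.mean(finite < threshold)) if finite.size else np.nan,
        "max_rhat": float(np.max(finite)) if finite.size else np.nan,
        "threshold": threshold,
    }
    return vals


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class OccupancyModel(BaseEstimator):
    """Hierarchical occupancy-detection model, one species at a time.

    Parameters
    ----------
    chains, n_iter, warmup : MCMC settings; ``n_iter`` counts post-warmup
        sweeps per chain.  Defaults follow a 4-chain, 1000-draw scheme.
    thin : store every ``thin``-th post-warmup draw.
    priors : dict overriding :data:`DEFAULT_PRIORS`.
    seed : base seed; chains use independent spawned streams.

    Attributes (after ``fit``)
    ----------
    posterior_ : OccupancyPosterior
    rhat_ : convergence summary dict from :func:`check_convergence`
    """

    def __init__(self, chains=4, n_iter=1000, warmup=1000, thin=2, priors=None, seed=0):
        self.chains = chains
        self.n_iter = n_iter
        self.warmup = warmup
        self.thin = thin
        self.priors = priors
        self.seed = seed

    def fit(self, design: OccupancyDesign, y=None):
        if design.n_years < 2:
            raise ValueError("design degenerate: need >=2 years")
        if len(design.visits) == 0 or not (design.visits["y"] > 0).any():
            raise ValueError("design degenerate: need at least one detection")
        priors = dict(DEFAULT_PRIORS)
        if self.priors:
            priors.update(self.priors)
        packed = design.packed()
        n_store = max(1, self.n_iter // self.thin)
        store = {
            "mu_o": np.empty((self.chains, n_store)),
            "beta_o1": np.empty((self.chains, n_store)),
            "beta_o2": np.empty((self.chains, n_store)),
            "sigma_o1": np.empty((self.chains, n_store)),
            "sigma_o2": np.empty((self.chains, n_store)),
            "sigma_d1": np.empty((self.chains, n_store)),
            "mu_d": np.empty((self.chains, n_store)),
            "beta_d": np.empty((self.chains, n_store, 8)),
            "alpha_o1": np.empty((self.chains, n_store, len(design.regions))),
            "alpha_o2": np.empty((self.chains, n_store, design.n_sites)),
            "alpha_d1": np.empty((self.chains, n_store, design.n_years)),
            "gamma": np.empty((self.chains, n_store, len(design.zones), design.n_years)),
            "sigma_gamma": np.empty((self.chains, n_store, len(design.zones))),
        }
        seeds = np.random.SeedSequence(self.seed).spawn(self.chains)
        for c in range(self.chains):
            rng = np.random.default_rng(seeds[c])
            chain = _Chain(design, packed, priors, rng)
            for it in range(self.warmup):
                chain.sweep(it, adapt=True)
            k = 0
            for it in range(self.n_iter):
                chain.sweep(self.warmup + it, adapt=False)
                if (it + 1) % self.thin == 0 and k < n_store:
                    p = chain.p
                    store["mu_o"][c, k] = p.mu_o
                    store["beta_o1"][c, k] = p.beta_o1
                    store["beta_o2"][c, k] = p.beta_o2
                    store["sigma_o1"][c, k] = p.sigma_o1
                    store["sigma_o2"][c, k] = p.sigma_o2
                    store["sigma_d1"][c, k] = p.sigma_d1
                    store["mu_d"][c, k] = p.mu_d
                    store["beta_d"][c, k] = p.beta_d
                    store["alpha_o1"][c, k] = p.alpha_o1
                    store["alpha_o2"][c, k] = p.alpha_o2
                    store["alpha_d1"][c, k] = p.alpha_d1
                    store["gamma"][c, k] = p.gamma
                    store["sigma_gamma"][c, k] = p.sigma_gamma
                    k += 1
        zone_occ, country = derive_mean_occupancy(store, design)
        self.posterior_ = OccupancyPosterior(
            species_id=design.species_id, draws=store, zones=design.zones,
            years=design.years, analysis_years=design.analysis_years,
            zone_occ=zone_occ, country_occ=country,
            zone_has_record=design.zone_has_record,
            n_squares_per_zone=np.bincount(design.zone_idx, minlength=len(design.zones)),
        )
        self.rhat_ = check_convergence(self.posterior_)
        return self


def fit_occupancy_model(design, priors=None, chains=4, n_iter=1000, warmup=1000,
                        thin=2, seed=0) -> OccupancyPosterior:
    """Functional wrapper around :class:`OccupancyModel`."""
    m = OccupancyModel(chains=chains, n_iter=n_iter, warmup=warmup, thin=thin,
                       priors=priors, seed=seed)
    m.fit(design)
    return m.posterior_
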