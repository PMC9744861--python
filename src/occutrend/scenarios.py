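"""Counterfactual driver scenarios and explained variance of long-term trends.

A scenario switches each of the six driver-change variables either to its
measured trajectory or to "no change": the uncentred value 0, which maps to
``-mean/sd`` in standardized space via the scaling constants stored when the
driver table was standardized.  The scenario set is the null scenario (all
six zeroed), six single-driver scenarios, nine climate x land-use pairs and
the full scenario — 17 in total.

Predictions are made at the replication unit of the regression (species x
zone x interval) with random effects kept at their posterior draw values,
back-transformed by sign-preserving squaring, summed over the eight
intervals per species and zone, and averaged over zones weighted by the
number of squares per zone, yielding a country-wide 40-year occupancy change
per species and draw.  Explained variance per scenario is the squared
Pearson correlation with the observed trends aggregated the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drivers import CLIMATE_VARS, LANDUSE_VARS, DRIVER_VARS
from .regression import RegressionDesign, TrendRegression, _build_matrices
from .trends import hdi, signed_square

__all__ = ["Scenario", "make_scenarios", "predict_scenario", "scenario_r2",
           "observed_longterm", "run_scenarios"]


@dataclass(frozen=True)
class Scenario:
    name: str
    observed: tuple  # driver names following their measured trajectory

    def switches(self) -> dict:
        return {d: ("observed" if d in self.observed else "zeroed") for d in DRIVER_VARS}


def make_scenarios(driver_names=None) -> list[Scenario]:
    """The 17 scenarios: 1 null + 6 singles + 9 climate x land-use pairs + full."""
    drivers = list(driver_names) if driver_names is not None else list(DRIVER_VARS)
    climate = [d for d in drivers if d in CLIMATE_VARS]
    landuse = [d for d in drivers if d in LANDUSE_VARS]
    if len(climate) != 3 or len(landuse) != 3:
        raise ValueError("need exactly 3 climate and 3 land-use drivers")
    out = [Scenario("null", ())]
    out += [Scenario(d, (d,)) for d in drivers]
    out += [Scenario(f"{c}+{l}", (c, l)) for c in climate for l in landuse]
    out.append(Scenario("full", tuple(drivers)))
    return out


def _scenario_frame(design: RegressionDesign, scenario: Scenario,
                    scaling: pd.DataFrame) -> pd.DataFrame:
    unknown = set(scenario.observed) - set(DRIVER_VARS)
    if unknown:
        raise ValueError(f"scenario references unknown drivers {sorted(unknown)}")
    df = design.frame.copy()
    for d in DRIVER_VARS:
        if d not in scenario.observed:
            # uncentred 0 mapped through the stored standardization constants
            df[d] = -scaling.loc[d, "mean"] / scaling.loc[d, "sd"]
    return df


def _aggregate_longterm(values: np.ndarray, frame: pd.DataFrame,
                        species: list, n_squares_per_zone: pd.Series) -> np.ndarray:
    """Back-transform, sum over intervals per species x zone, weight zones.

    ``values`` is (n_draws, n_rows) on the signed-sqrt scale; returns
    (n_draws, n_species) country-wide 40-year changes.
    """
    raw = signed_square(values)
    sp_codes = pd.Categorical(frame["species_id"], categories=species).codes
    zones = sorted(frame["zone"].unique())
    z_codes = pd.Categorical(frame["zone"], categories=zones).codes
    nz = len(zones)
    nsp = len(species)
    cell = sp_codes.astype(np.int64) * nz + z_codes
    n_draws = raw.shape[0]
    sums = np.zeros((n_draws, nsp * nz))
    for d in range(n_draws):
        sums[d] = np.bincount(cell, weights=raw[d], minlength=nsp * nz)
    sums = sums.reshape(n_draws, nsp, nz)
    present = np.zeros((nsp, nz), dtype=bool)
    present[sp_codes, z_codes] = True
    w = np.asarray([float(n_squares_per_zone.get(z, 0.0)) for z in zones])
    wmat = np.where(present, w[None, :], 0.0)
    wsum = wmat.sum(axis=1, keepdims=True)
    wsum[wsum == 0] = 1.0
    return np.einsum("dsz,sz->ds", sums, wmat / wsum)


def observed_longterm(design: RegressionDesign, n_squares_per_zone: pd.Series) -> np.ndarray:
    """Aggregate the observed short-term trend estimates to 40-year changes."""
    return _aggregate_longterm(design.y[None, :], design.frame, design.species,
                               n_squares_per_zone)[0]


def predict_scenario(fit: TrendRegression, design: RegressionDesign,
                     scenario: Scenario, scaling: pd.DataFrame,
                     n_squares_per_zone: pd.Series) -> np.ndarray:
    """Per-draw country-wide 40-year change per species under a scenario.

    Random effects stay at their posterior draw values; only driver columns
    (and the interactions built from them) change with the scenario.
    """
    df = _scenario_frame(design, scenario, scaling)
    X, W, _, _ = _build_matrices(df, design.groups, design.intervals,
                                 design.version, design.agri_of_species)
    eta = fit.predict_linear(X, W, design.sp_idx, design.zone_idx)
    return _aggregate_longterm(eta, design.frame, design.species, n_squares_per_zone)


def scenario_r2(predicted: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Per-draw squared Pearson correlation of predicted vs observed trends.

    Draws with zero variance in the predictions score 0 (with a warning).
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    observed = np.asarray(observed, dtype=float)
    if observed.size < 3:
        raise ValueError("need >=3 species for a meaningful R^2")
    pc = predicted - predicted.mean(axis=1, keepdims=True)
    oc = observed - observed.mean()
    denom_o = np.sqrt(np.sum(oc ** 2))
    denom_p = np.sqrt(np.sum(pc ** 2, axis=1))
    out = np.zeros(predicted.shape[0])
    # constant predictions (up to floating-point residue) count as degenerate
    tol = 1e-10 * np.sqrt(predicted.shape[1]) * (1.0 + np.abs(predicted).max())
    ok = denom_p > tol
    if not ok.all():
        warnings.warn("zero variance in scenario predictions for some draws; R^2 set to 0")
    out[ok] = (pc[ok] @ oc / (denom_p[ok] * denom_o)) ** 2
    return out


def run_scenarios(fit: TrendRegression, design: RegressionDesign,
                  scaling: pd.DataFrame, n_squares_per_zone: pd.Series,
                  level: tuple = (0.8, 0.95)) -> pd.DataFrame:
    """R-squared summary for all 17 scenarios."""
    obs = observed_longterm(design, n_squares_per_zone)
    rows = []
    for sc in make_scenarios():
        pred = predict_scenario(fit, design, sc, scaling, n_squares_per_zone)
        r2 = scenario_r2(pred, obs)
        lo80, hi80 = hdi(r2, level[0])
        lo95, hi95 = hdi(r2, level[1])
        rows.append({"scenario": sc.name, "r2_mean": float(r2.mean()),
                     "hdi80_low": lo80, "hdi80_high": hi80,
                     "hdi95_low": lo95, "hdi95_high": hi95})
    return pd.DataFrame(rows)
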