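"""Climate-change and land-use-change variables, and species traits.

Three climate variables are derived from monthly series per bioclimatic zone:
annual mean temperature (BIO1), temperature seasonality (BIO4, the standard
deviation of the twelve monthly temperature means) and summer precipitation
(BIO18, precipitation of the warmest consecutive three-month window).  Climate
change over a short-term interval is the OLS slope over the interval plus the
five preceding years (a 10-year regression window), scaled to the interval
length; the longer window damps the influence of single extreme years.

Three land-use variables are built from zonal agricultural series: the
proportion of agricultural area, grassland-use intensity (livestock units per
grassland area) and crop-use intensity (area-weighted insecticide application
rate relative to the zone area).  Irregularly observed series are gap-filled
with a smoothing spline before changes are taken as interval endpoint
differences.

Two species traits are computed: a temperature niche (mean temperature of the
grid cells where a species was ever recorded) and a habitat-specialisation
index (one minus the fraction of the group's habitat universe the species
uses, min-max rescaled within each insect group).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .trends import ols_slope

__all__ = [
    "compute_bioclim",
    "climate_change",
    "gapfill_landuse",
    "landuse_variables",
    "standardize_changes",
    "species_temperature_index",
    "habitat_specialisation",
    "CLIMATE_VARS",
    "LANDUSE_VARS",
    "DRIVER_VARS",
]

CLIMATE_VARS = ["temp_mean_change", "temp_seasonality_change", "summer_precip_change"]
LANDUSE_VARS = ["agri_area_change", "grassland_intensity_change", "crop_intensity_change"]
DRIVER_VARS = CLIMATE_VARS + LANDUSE_VARS


def compute_bioclim(monthly_temp, monthly_precip) -> tuple[float, float, float]:
    """(BIO1, BIO4, BIO18) from 12 monthly temperature means and precip sums.

    BIO4 is reported as the plain standard deviation of the monthly means (not
    multiplied by 100).  BIO18 is the precipitation sum of the warmest
    consecutive 3-month window, December-January wrap-around allowed.
    """
    t = np.asarray(monthly_temp, dtype=float)
    p = np.asarray(monthly_precip, dtype=float)
    if t.shape != (12,) or p.shape != (12,):
        raise ValueError("need exactly 12 monthly values for temperature and precipitation")
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(p)):
        raise ValueError("missing month in climate series")
    bio1 = float(t.mean())
    bio4 = float(t.std(ddof=0))
    # warmest consecutive quarter with wrap-around: 12 candidate windows
    idx = np.arange(12)
    windows = np.stack([idx, (idx + 1) % 12, (idx + 2) % 12], axis=1)
    warm = int(np.argmax(t[windows].mean(axis=1)))
    bio18 = float(p[windows[warm]].sum())
    return bio1, bio4, bio18


def climate_change(zone_year_series: pd.Series, interval: tuple[int, int], lead_years: int = 5) -> float:
    """Change of a climate variable attributed to a short-term interval.

    OLS slope of annual values over the interval extended backwards by
    ``lead_years`` (e.g. 1975-1985 for the 1980-1985 interval), multiplied by
    the interval length.
    """
    lo, hi = interval
    years = np.arange(lo - lead_years, hi + 1)
    s = zone_year_series.reindex(years)
    if s.isna().any():
        missing = s.index[s.isna()].tolist()
        raise ValueError(f"climate window {years[0]}-{years[-1]} incomplete: missing {missing}")
    slope = float(ols_slope(s.to_numpy(dtype=float), years.astype(float)))
    return slope * (hi - lo)


def gapfill_landuse(years, values, out_years) -> np.ndarray:
    """Fill gaps in an irregular yearly series with a smoothing spline.

    The fit reproduces dense noise-free inputs and yields smooth, gradual
    interpolation in gaps (the series modelled change slowly by nature).
    Fewer than 4 observed points fall back to linear interpolation with a
    warning.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    years, values = years[ok], values[ok]
    order = np.argsort(years)
    years, values = years[order], values[order]
    out_years = np.asarray(out_years, dtype=float)
    if years.size < 4:
        warnings.warn("fewer than 4 observed years: falling back to linear interpolation")
        if years.size < 2:
            raise ValueError("need at least 2 observed years")
        return np.interp(out_years, years, values)
    if np.ptp(values) == 0.0:
        return np.full(out_years.shape, values[0])
    spl = make_smoothing_spline(years, values)
    out = spl(out_years)
    # no extrapolation beyond observed range: clamp to boundary fit values
    out = np.where(out_years < years[0], spl(years[0]), out)
    out = np.where(out_years > years[-1], spl(years[-1]), out)
    return out


def landuse_variables(
    zone_series: pd.DataFrame,
    crop_rates: dict[str, float],
    study_area_km2: float,
) -> pd.DataFrame:
    """Three yearly land-use intensity series for one zone.

    Parameters
    ----------
    zone_series : DataFrame indexed by year
        Gap-filled columns: ``agri_area_km2``, ``grassland_area_km2``, ``lsu``
        and one ``crop_<name>_km2`` column per crop type in ``crop_rates``.
    crop_rates : mapping crop name -> mean insecticide application rate
        (kg/km2/yr) attributed to that crop type.
    study_area_km2 : total area of the zone.

    Returns yearly ``agri_area_prop``, ``grassland_intensity`` (LSU per km2 of
    grassland) and ``crop_intensity`` (zone-wide mean application rate).
    """
    if study_area_km2 <= 0:
        raise ValueError("study area must be positive")
    grass = zone_series["grassland_area_km2"].to_numpy(dtype=float)
    if np.any(grass <= 0):
        bad = zone_series.index[grass <= 0].tolist()
        raise ValueError(f"zero grassland area in years {bad}: intensity undefined")
    out = pd.DataFrame(index=zone_series.index)
    out["agri_area_prop"] = zone_series["agri_area_km2"] / study_area_km2
    out["grassland_intensity"] = zone_series["lsu"] / zone_series["grassland_area_km2"]
    total_applied = np.zeros(len(zone_series), dtype=float)
    for crop, rate in crop_rates.items():
        col = f"crop_{crop}_km2"
        if col in zone_series:
            total_applied += rate * zone_series[col].to_numpy(dtype=float)
    out["crop_intensity"] = total_applied / study_area_km2
    return out


def landuse_change(series: pd.Series, interval: tuple[int, int]) -> float:
    """Interval change of a (gap-filled) yearly land-use series.

    Endpoint difference over the interval; the slope-based alternative is
    ``ols_slope`` over the interval scaled by its length.
    """
    lo, hi = interval
    try:
        return float(series.loc[hi] - series.loc[lo])
    except KeyError as e:
        raise ValueError(f"land-use series missing endpoint year {e}") from None


def standardize_changes(table: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centre and scale change variables over their zone x interval replicates.

    Returns the standardized table and a scaling frame (mean, sd per column)
    that inverts the transform exactly; counterfactual scenarios use it to map
    an uncentred 0 ("no change") to ``-mean/sd`` in standardized space.
    """
    if columns is None:
        columns = [c for c in DRIVER_VARS if c in table.columns]
    out = table.copy()
    scale_rows = []
    for c in columns:
        v = table[c].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"column {c}: need >=2 replicates to standardize")
        m, s = float(v.mean()), float(v.std(ddof=0))
        if s == 0.0:
            raise ValueError(f"column {c} has zero variance; cannot standardize")
        out[c] = (v - m) / s
        scale_rows.append({"variable": c, "mean": m, "sd": s})
    return out, pd.DataFrame(scale_rows).set_index("variable")


def species_temperature_index(grid_records: pd.DataFrame, cell_mean_temps: pd.Series) -> pd.Series:
    """Species Temperature Index: mean temperature over occupied grid cells.

    Each cell counts once regardless of the number of records in it.  Species
    whose records all fall in cells with no temperature value get NaN.
    """
    cells = grid_records[["species_id", "cell_id"]].drop_duplicates()
    temps = cells["cell_id"].map(cell_mean_temps)
    sti = temps.groupby(cells["species_id"]).mean()
    sti.name = "temperature_niche"
    return sti


def habitat_specialisation(habitat_lists: dict[str, list[str]], group_of: dict[str, str],
                           group_universe: dict[str, list[str]]) -> pd.Series:
    """Habitat-specialisation index, min-max rescaled within insect groups.

    Raw index for species i: ``1 - n_i / N_group``, where ``n_i`` is the
    number of preferred habitats and ``N_group`` the size of the group's
    habitat universe.  The raw index is then rescaled so each group spans
    [0, 1] (a group with a single distinct value maps to 0).
    """
    raw = {}
    for sp, habs in habitat_lists.items():
        g = group_of[sp]
        n_group = len(group_universe[g])
        if n_group == 0:
            raise ValueError(f"group {g} has an empty habitat universe")
        n_i = len(set(habs))
        if not 1 <= n_i <= n_group:
            raise ValueError(f"species {sp}: {n_i} habitats outside [1, {n_group}]")
        raw[sp] = 1.0 - n_i / n_group
    s = pd.Series(raw, name="habitat_specialisation")
    groups = pd.Series({sp: group_of[sp] for sp in s.index})
    out = s.copy()
    for g, idx in s.groupby(groups).groups.items():
        v = s.loc[idx]
        rng_ = v.max() - v.min()
        out.loc[idx] = 0.0 if rng_ == 0 else (v - v.min()) / rng_
    return out
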