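"""Record and visit filtering, and per-species detection histories.

All records by one observer (or project) on one day in one square form a
visit, the replicate unit of the observation model.  Filters applied before
modelling:

* non-adult records are dropped;
* squares whose records fall in a single year are dropped (they carry no
  information on change between years);
* records outside the study range are dropped, with an optional warm-up
  decade per group that is fitted but trimmed from derived series;
* species are kept only if recorded in at least a configurable fraction
  (default 25%) of the analysed years;
* per species, visits are removed if they (a) come from a project with a
  taxonomic focus that excludes the species, (b) fall outside the 5%-95%
  empirical quantile range of the species' recorded day-of-year, or (c) come
  from a bioclimatic zone where the species was never recorded.

Observers qualify as experts when they are in the top 2.5% by total record
count and made at least one visit in the top 2.5% of visits by number of
records.  Quantiles are empirical (type 7) with inclusive boundaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "build_visits",
    "filter_records",
    "select_species",
    "classify_observers",
    "build_detection_histories",
    "list_length_class",
]


def list_length_class(n: int) -> str:
    """Effort class from the number of species on a visit: 1 / 2-3 / >3."""
    if n <= 1:
        return "1"
    if n <= 3:
        return "2-3"
    return ">3"


def _visit_key(records: pd.DataFrame) -> pd.Series:
    key = records["project_id"].astype(object).where(
        records["project_id"].notna(), records["observer_id"])
    return key


def build_visits(records: pd.DataFrame) -> pd.DataFrame:
    """Group records into visits (observer/project x day x square).

    Records missing both observer and project keys are rejected with a
    logged warning.  Returns one row per visit with the species list, list
    length and its class, and a source class hint.
    """
    rec = records.copy()
    bad = rec["observer_id"].isna() & rec["project_id"].isna()
    if bad.any():
        logger.warning("dropping %d records with neither observer nor project key",
                       int(bad.sum()))
        rec = rec[~bad]
    rec["_key"] = _visit_key(rec)
    rec["_day"] = pd.to_datetime(rec["date"]).dt.normalize()
    if "source_hint" not in rec:
        rec["source_hint"] = "private"
    if "group" not in rec:
        rec["group"] = None
    gb = rec.groupby(["_key", "_day", "square_id"], sort=True, dropna=False)
    visits = gb.agg(
        observer_id=("observer_id", "first"),
        project_id=("project_id", "first"),
        group=("group", "first"),
        source_hint=("source_hint", "first"),
        n_records=("species_id", "size"),
        n_species_recorded=("species_id", "nunique"),
    ).reset_index().rename(columns={"_key": "key", "_day": "date"})
    visits["species_list"] = gb["species_id"].agg(lambda s: sorted(s.unique())).to_numpy()
    n_sp = visits["n_species_recorded"].to_numpy()
    visits["list_length_class"] = np.select(
        [n_sp <= 1, n_sp <= 3], ["1", "2-3"], default=">3")
    visits.insert(0, "visit_id", [f"v{i:07d}" for i in range(len(visits))])
    if len(visits):
        visits["year"] = pd.to_datetime(visits["date"]).dt.year
        visits["yday"] = pd.to_datetime(visits["date"]).dt.dayofyear
    return visits


def filter_records(records: pd.DataFrame, start_year: int, end_year: int,
                   warmup_start: dict | None = None) -> pd.DataFrame:
    """Stage-one record filters.

    ``warmup_start`` optionally maps a group name to an earlier first year
    (warm-up records are fitted but later trimmed from derived series).
    Raises if a filter empties the table, naming the filter.
    """
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec["year"] = rec["date"].dt.year

    def _check(df, name):
        if df.empty:
            raise ValueError(f"record filter '{name}' removed all records")
        return df

    n0 = len(rec)
    rec = _check(rec[rec["life_stage"] == "adult"], "non-adult stages")
    logger.info("filter non-adult: %d -> %d records", n0, len(rec))

    lo = rec["group"].map(lambda g: (warmup_start or {}).get(g, start_year))
    n0 = len(rec)
    rec = _check(rec[(rec["year"] >= lo) & (rec["year"] <= end_year)], "study range")
    logger.info("filter study range: %d -> %d records", n0, len(rec))

    # squares visited in a single year only (per group dataset)
    n0 = len(rec)
    span = rec.groupby(["group", "square_id"])["year"].nunique()
    multi = span[span >= 2].reset_index()[["group", "square_id"]]
    rec = _check(rec.merge(multi, on=["group", "square_id"], how="inner"),
                 "single-year squares")
    logger.info("filter single-year squares: %d -> %d records", n0, len(rec))
    return rec


def select_species(records: pd.DataFrame, analysis_years,
                   min_year_fraction: float = 0.25) -> list[str]:
    """Species recorded in at least ``min_year_fraction`` of analysed years."""
    analysis_years = set(int(y) for y in np.asarray(analysis_years))
    years = pd.to_datetime(records["date"]).dt.year
    in_range = records[years.isin(analysis_years)]
    n_years = in_range.groupby("species_id")["date"].apply(
        lambda d: pd.to_datetime(d).dt.year.nunique())
    keep = n_years[n_years / len(analysis_years) >= min_year_fraction]
    return sorted(keep.index.tolist())


def _upper_quantile_cut(values: np.ndarray, q: float = 0.975) -> float:
    # type-7 empirical quantile; boundary values kept inclusive
    return float(np.quantile(values, q, method="linear"))


def classify_observers(visits: pd.DataFrame, quantile: float = 0.975) -> pd.Series:
    """Expert flags per observer.

    Expert = in the upper 2.5% of observers by total records AND has at
    least one visit in the upper 2.5% of visits by number of records.
    Project-only visits (no observer key) are ignored.
    """
    v = visits[visits["observer_id"].notna()]
    if v.empty:
        return pd.Series(dtype=bool)
    totals = v.groupby("observer_id")["n_records"].sum()
    cut_obs = _upper_quantile_cut(totals.to_numpy(), quantile)
    top_observers = totals[totals >= cut_obs].index
    cut_visit = _upper_quantile_cut(v["n_records"].to_numpy(), quantile)
    has_long = v[v["n_records"] >= cut_visit].groupby("observer_id").size()
    expert = pd.Series(False, index=totals.index, name="expert")
    expert.loc[[o for o in top_observers if o in has_long.index]] = True
    return expert


def build_detection_histories(
    species_ids: list[str],
    visits: pd.DataFrame,
    records: pd.DataFrame,
    squares: pd.DataFrame,
    projects: pd.DataFrame | None = None,
    yday_quantiles: tuple[float, float] = (0.05, 0.95),
) -> dict[str, pd.DataFrame]:
    """Per-species detection/non-detection rows with covariates.

    ``squares`` maps square_id to zone.  ``projects`` optionally carries the
    project coverage table (columns project_id, group, target_species); a
    visit from a project whose focus excludes the species fails filter (a).
    Day-of-year quantiles for filter (b) are computed per species from its
    own records, pooled over years and zones.  Species without eligible
    visits are flagged (empty frame) for exclusion downstream.
    """
    rec = records.copy()
    rec["_day"] = pd.to_datetime(rec["date"]).dt.normalize()
    rec["yday"] = pd.to_datetime(rec["date"]).dt.dayofyear
    zone_of = squares.set_index("square_id")["zone"]
    v = visits.copy()
    v["zone"] = v["square_id"].map(zone_of)
    expert = classify_observers(visits)
    v["expert_flag"] = v["observer_id"].map(expert).eq(True)

    proj_info = None
    if projects is not None and len(projects):
        proj_info = projects.set_index("project_id")

    group_of_species = None
    if "group" in rec:
        group_of_species = rec.drop_duplicates("species_id").set_index(
            "species_id")["group"]

    # detections per (visit key, species): visits indexed by key/day/square
    rec["_key"] = rec["project_id"].astype(object).where(
        rec["project_id"].notna(), rec["observer_id"])
    det_keys = rec.groupby("species_id").apply(
        lambda g: set(zip(g["_key"], g["_day"], g["square_id"])),
        include_groups=False)

    out = {}
    for sp in species_ids:
        sp_rec = rec[rec["species_id"] == sp]
        if sp_rec.empty:
            out[sp] = pd.DataFrame()
            continue
        grp = group_of_species.get(sp) if group_of_species is not None else None
        vv = v if grp is None else v[v["group"] == grp]
        # (a) project focus
        if proj_info is not None:
            pid = vv["project_id"]
            has_proj = pid.notna()
            keep = np.ones(len(vv), dtype=bool)
            if has_proj.any():
                pk = proj_info.reindex(pid[has_proj])
                ok = (pk["group"].to_numpy() == (grp or pk["group"].to_numpy()))
                tgt = pk["target_species"]
                is_targeted = tgt.notna().to_numpy()
                ok &= ~is_targeted | (tgt.to_numpy(dtype=object) == sp)
                keep[np.flatnonzero(has_proj.to_numpy())] = ok
            vv = vv[keep]
        # (b) day-of-year window from the species' own records
        qlo, qhi = np.quantile(sp_rec["yday"].to_numpy(), yday_quantiles, method="linear")
        vv = vv[(vv["yday"] >= qlo) & (vv["yday"] <= qhi)]
        # (c) zones with at least one record of the species
        sp_zones = set(sp_rec["square_id"].map(zone_of).dropna().unique())
        vv = vv[vv["zone"].isin(sp_zones)]
        if vv.empty:
            logger.warning("species %s: no eligible visits after filters", sp)
            out[sp] = pd.DataFrame()
            continue
        dk = det_keys.get(sp, set())
        y = np.fromiter(
            ((k, d, s) in dk for k, d, s in zip(vv["key"], pd.to_datetime(vv["date"]).dt.normalize(), vv["square_id"])),
            dtype=bool, count=len(vv))
        mu, sd = sp_rec["yday"].mean(), max(sp_rec["yday"].std(ddof=0), 1.0)
        lcls = vv["list_length_class"]
        src = vv["source_hint"].map({"private": "naturalist", "project": "project",
                                     "targeted_project": "targeted_project",
                                     "redlist": "redlist"}).fillna("naturalist")
        hist = pd.DataFrame({
            "visit_id": vv["visit_id"].to_numpy(),
            "square_id": vv["square_id"].to_numpy(),
            "year": vv["year"].to_numpy(),
            "zone": vv["zone"].to_numpy(),
            "y": y.astype(int),
            "yday_scaled": ((vv["yday"] - mu) / sd).to_numpy(),
            "shortlist": (lcls == "2-3").astype(int).to_numpy(),
            "longlist": (lcls == ">3").astype(int).to_numpy(),
            "expert": (vv["expert_flag"] & (src == "naturalist")).astype(int).to_numpy(),
            "project": (src == "project").astype(int).to_numpy(),
            "targeted_project": (src == "targeted_project").astype(int).to_numpy(),
            "redlist": (src == "redlist").astype(int).to_numpy(),
        })
        out[sp] = hist
    return out
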