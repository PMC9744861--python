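"""Trend extraction from posterior mean-occupancy series.

Mean-occupancy series (one per posterior draw, per zone or country-wide) are
reduced to linear trends: a single 40-year national trend per species and
short-term trends over consecutive 5-year intervals per bioclimatic zone.
Trends are expressed as the change in mean occupancy over the window
(OLS slope multiplied by window length), so a 40-year trend of 0.08 means the
proportion of occupied squares grew by 8 percentage points over the study
period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "signed_sqrt",
    "signed_square",
    "hdi",
    "ols_slope",
    "fit_window_trend",
    "intervals_for",
    "summarize_trends",
]


def signed_sqrt(x):
    """Sign-preserving square root, ``sign(x) * sqrt(|x|)``.

    Used to normalise trend residuals before regression; inverted exactly by
    :func:`signed_square`.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.sqrt(np.abs(x))


def signed_square(x):
    """Inverse of :func:`signed_sqrt`: ``sign(x) * x**2``."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.square(x)


def hdi(draws, level: float = 0.95) -> tuple[float, float]:
    """Highest density interval: the shortest interval holding ``level`` mass.

    Parameters
    ----------
    draws : array-like
        Posterior draws (flattened).
    level : float
        Probability mass of the interval, in (0, 1).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"HDI level must be in (0, 1), got {level}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws for an HDI")
    n_in = max(2, int(np.ceil(level * n)))
    n_in = min(n_in, n)
    widths = x[n_in - 1 :] - x[: n - n_in + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + n_in - 1])


def ols_slope(y: np.ndarray, x: np.ndarray | None = None) -> np.ndarray:
    """Closed-form OLS slope of ``y`` against ``x`` along the last axis."""
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(y.shape[-1], dtype=float)
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = np.sum(xc * xc)
    if denom == 0:
        raise ValueError("degenerate x: needs >=2 distinct points")
    return (y - y.mean(axis=-1, keepdims=True)) @ xc / denom


def fit_window_trend(series: np.ndarray, years: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Per-draw occupancy change over ``window`` = OLS slope x window length.

    ``series`` has shape (n_draws, n_years) aligned with ``years``; the window
    is inclusive of both endpoint years and every year inside it must be
    present.
    """
    years = np.asarray(years)
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    mask = (years >= lo) & (years <= hi)
    got = np.sort(years[mask])
    expect = np.arange(lo, hi + 1)
    if got.size != expect.size or np.any(got != expect):
        missing = sorted(set(expect) - set(got.tolist()))
        raise ValueError(f"window {window} incomplete: missing years {missing}")
    sub = np.asarray(series, dtype=float)[..., mask]
    return ols_slope(sub) * (hi - lo)


def intervals_for(start_year: int, end_year: int, length: int = 5) -> list[tuple[int, int]]:
    """Consecutive short-term intervals covering [start_year, end_year].

    Default gives the 8 five-year spans 1980-1985, 1985-1990, ..., 2015-2020.
    """
    out = []
    lo = start_year
    while lo + length <= end_year:
        out.append((lo, lo + length))
        lo += length
    return out


def _percent_change(trend_draws: np.ndarray, mean_occ_draws: np.ndarray) -> np.ndarray:
    # change relative to the species' 40-year mean occupancy, in percent
    return 100.0 * trend_draws / mean_occ_draws


def summarize_trends(
    trend_draws: np.ndarray,
    mean_occ_draws: np.ndarray,
    species_ids,
    n_boot: int = 9999,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> dict:
    """Summary statistics of national long-term trends across species.

    Parameters
    ----------
    trend_draws : (n_draws, n_species)
        Posterior draws of the 40-year change in country-wide mean occupancy.
    mean_occ_draws : (n_draws, n_species)
        Posterior draws of the species' 40-year mean occupancy.
    species_ids : sequence of str
    n_boot : int
        Bootstrap resamples for the sign-change-position CI.

    Returns a dict with per-draw counts of increasing/decreasing species,
    quarter (strongest 25%) membership and average changes, percent changes
    relative to 40-year mean occupancy, the bootstrap CI of the rank where
    trends switch sign, and the mean-occupancy comparison between increasing
    and decreasing species.

    Quarter membership is fixed by ranking posterior-mean trends; uncertainty
    is then propagated by averaging within that fixed set per draw.  Exact
    zero trends count as negative (deterministic tie-break).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    trend_draws = np.asarray(trend_draws, dtype=float)
    mean_occ_draws = np.asarray(mean_occ_draws, dtype=float)
    n_draws, n_species = trend_draws.shape
    species_ids = list(species_ids)
    if n_species < 4:
        raise ValueError(f"need >=4 species to define quarters, got {n_species}")

    point = trend_draws.mean(axis=0)

    # (i) per-draw counts of species with positive / non-positive trends
    pos_counts = (trend_draws > 0).sum(axis=1)
    neg_counts = n_species - pos_counts
    # (ii) quarter membership from posterior-mean ranking
    order = np.argsort(point, kind="stable")
    n_quarter = n_species // 4
    declining = order[:n_quarter]
    increasing = order[-n_quarter:]
    decl_change = trend_draws[:, declining].mean(axis=1)
    incr_change = trend_draws[:, increasing].mean(axis=1)
    # (iii) percent change relative to 40-year mean occupancy, per quarter
    pct = _percent_change(trend_draws, mean_occ_draws)
    decl_pct = pct[:, declining].mean(axis=1)
    incr_pct = pct[:, increasing].mean(axis=1)
    # (iv) bootstrap CI of the rank position where trends change sign
    boot = rng.choice(point, size=(n_boot, n_species), replace=True)
    boot_pos = (boot <= 0).sum(axis=1)  # rank position after which trends turn positive
    sign_change = int((point <= 0).sum())
    lo_q, hi_q = np.quantile(boot_pos, [(1 - level) / 2, (1 + level) / 2])
    # (v) 40-yr mean occupancy of increasing vs decreasing species (point sets)
    inc_set = point > 0
    dec_set = ~inc_set
    occ_inc = mean_occ_draws[:, inc_set].mean(axis=1) if inc_set.any() else np.zeros(n_draws)
    occ_dec = mean_occ_draws[:, dec_set].mean(axis=1) if dec_set.any() else np.zeros(n_draws)
    occ_diff = occ_inc - occ_dec

    def _summ(draws):
        draws = np.asarray(draws, dtype=float)
        lo, hi = hdi(draws, level)
        return {"mean": float(draws.mean()), "hdi_low": lo, "hdi_high": hi}

    return {
        "n_species": n_species,
        "n_positive": _summ(pos_counts.astype(float)),
        "n_negative": _summ(neg_counts.astype(float)),
        "declining_quarter": {
            "species": [species_ids[i] for i in declining],
            "change": _summ(decl_change),
            "percent_change": _summ(decl_pct),
        },
        "increasing_quarter": {
            "species": [species_ids[i] for i in increasing],
            "change": _summ(incr_change),
            "percent_change": _summ(incr_pct),
        },
        "sign_change_position": {
            "estimate": sign_change,
            "boot_ci_low": float(lo_q),
            "boot_ci_high": float(hi_q),
            "n_boot": n_boot,
        },
        "mean_occupancy_increasing": _summ(occ_inc),
        "mean_occupancy_decreasing": _summ(occ_dec),
        "mean_occupancy_difference": _summ(occ_diff),
    }


def trend_table(
    trend_draws: np.ndarray,
    species_ids,
    scope: str,
    level: float = 0.95,
    **keys,
) -> pd.DataFrame:
    """Tidy per-species trend summary (posterior mean and HDI)."""
    trend_draws = np.asarray(trend_draws, dtype=float)
    rows = []
    for j, sp in enumerate(species_ids):
        lo, hi = hdi(trend_draws[:, j], level)
        rows.append(
            {"species_id": sp, "scope": scope, **keys,
             "trend_mean": float(trend_draws[:, j].mean()),
             "hdi_low": lo, "hdi_high": hi}
        )
    return pd.DataFrame(rows)
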