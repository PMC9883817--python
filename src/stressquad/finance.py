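"""Long-term stock growth aggregated on the multiplicative scale.

Growth of a company over a window is the ratio of its average adjusted
closing price in the end year to that of the start year (2009 -> 2019 by
default).  Because growth ratios across companies are heavy-tailed
(approximately log-normal), groups are summarised with the geometric mean

    GM = (prod_i g_i)^(1/N) = exp(mean(log g_i))

and the geometric standard error

    GSE = GM / sqrt(N) * sd(log g_i)

with natural logarithms and the population standard deviation.  Companies
of each stress type are ranked on their association score (or, optionally,
their raw stress score) and cut into equal-count percentile bins; each
(type, bin) is summarised by N, GM and GSE, alongside a pooled per-type
summary.  A stratified variant repeats the computation within externally
supplied strata (industry sector, rating band) for robustness checks.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .quadrant import STRESS_TYPES

__all__ = [
    "yearly_average_prices",
    "stock_growth",
    "geometric_mean",
    "geometric_standard_error",
    "growth_by_type_and_percentile",
    "stratified_growth",
]

OVERALL_BIN = "all"


def yearly_average_prices(prices: pd.DataFrame) -> pd.DataFrame:
    """Normalise a stock table to yearly averages.

    Accepts either yearly rows ``(company_id, year, adj_close_avg)`` —
    returned as-is — or daily rows ``(company_id, date, adj_close)``, which
    are averaged per company and calendar year.
    """
    if "adj_close_avg" in prices.columns and "year" in prices.columns:
        return prices[["company_id", "year", "adj_close_avg"]].copy()
    if "date" in prices.columns and "adj_close" in prices.columns:
        daily = prices.copy()
        daily["year"] = pd.to_datetime(daily["date"]).dt.year
        out = (
            daily.groupby(["company_id", "year"], sort=True)["adj_close"]
            .mean()
            .rename("adj_close_avg")
            .reset_index()
        )
        return out
    raise ValueError(
        "stock table needs (company_id, year, adj_close_avg) or (company_id, date, adj_close)"
    )


def stock_growth(
    prices: pd.DataFrame, start_year: int = 2009, end_year: int = 2019
) -> pd.DataFrame:
    """Per-company growth ratio between two years' average prices.

    Companies missing either year are dropped (their number reported in a
    warning); a nonpositive price is an error naming the offending record.
    Returns ``(company_id, growth)``.
    """
    yearly = yearly_average_prices(prices)
    bad = yearly.loc[yearly["adj_close_avg"] <= 0]
    if not bad.empty:
        rec = bad.iloc[0]
        raise ValueError(
            f"nonpositive price for company {rec['company_id']!r} in {int(rec['year'])}"
        )
    wide = yearly.pivot_table(
        index="company_id", columns="year", values="adj_close_avg", aggfunc="mean"
    )
    for year in (start_year, end_year):
        if year not in wide.columns:
            wide[year] = np.nan
    both = wide[[start_year, end_year]].dropna()
    dropped = len(wide) - len(both)
    if dropped:
        warnings.warn(f"{dropped} companies missing {start_year} or {end_year} prices")
    out = (both[end_year] / both[start_year]).rename("growth").reset_index()
    return out


def geometric_mean(values: Iterable[float]) -> float:
    """exp(mean(log values)); requires strictly positive inputs."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty set is undefined")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def geometric_standard_error(values: Iterable[float], ddof: int = 0) -> float:
    """GM / sqrt(N) * sd(log values); NaN with a warning when N < 2."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        warnings.warn("geometric standard error undefined for N < 2")
        return float("nan")
    gm = geometric_mean(arr)
    return float(gm / np.sqrt(arr.size) * np.std(np.log(arr), ddof=ddof))


def _percentile_bins(n: int, n_bins: int) -> np.ndarray:
    """Equal-count bin index for ranks 0..n-1 cut into n_bins groups."""
    return (np.arange(n) * n_bins) // n


def _bin_label(i: int, n_bins: int) -> str:
    lo = round(100 * i / n_bins)
    hi = round(100 * (i + 1) / n_bins)
    return f"p{lo:02d}-{hi:03d}"


def _summarise(sub: pd.DataFrame, stress_type: str, label: str) -> dict:
    g = sub["growth"].to_numpy()
    return {
        "stress_type": stress_type,
        "percentile_bin": label,
        "N": int(g.size),
        "gm": geometric_mean(g),
        "gse": geometric_standard_error(g) if g.size >= 2 else np.nan,
    }


def growth_by_type_and_percentile(
    growth: pd.DataFrame,
    quadrant_scores: pd.DataFrame,
    n_bins: int = 10,
    bin_on: str = "f",
) -> pd.DataFrame:
    """Summarise growth per stress type and association-percentile bin.

    Parameters
    ----------
    growth
        ``(company_id, growth)`` from :func:`stock_growth`.
    quadrant_scores
        Scored cohort with ``company_id, stress_type`` and the binning
        column.
    n_bins
        Number of equal-count bins per type (deciles by default).
    bin_on
        ``"f"`` ranks companies on their association score,
        ``"stress_score"`` on the raw stress score.

    Returns ``(stress_type, percentile_bin, N, gm, gse)`` with one extra
    row per type (bin ``"all"``) pooling all its companies.  Empty bins are
    omitted; companies without a growth value or without a score do not
    contribute.
    """
    if bin_on not in quadrant_scores.columns:
        raise ValueError(f"binning column {bin_on!r} not in quadrant scores")
    merged = growth.merge(
        quadrant_scores[["company_id", "stress_type", bin_on]],
        on="company_id",
        how="inner",
    )
    rows = []
    for stress_type in STRESS_TYPES:
        sub = merged.loc[merged["stress_type"] == stress_type]
        if sub.empty:
            continue
        sub = sub.sort_values([bin_on, "company_id"], kind="mergesort").reset_index(
            drop=True
        )
        bins = _percentile_bins(len(sub), n_bins)
        for i in np.unique(bins):
            rows.append(
                _summarise(sub.loc[bins == i], stress_type, _bin_label(int(i), n_bins))
            )
        rows.append(_summarise(sub, stress_type, OVERALL_BIN))
    return pd.DataFrame(rows, columns=["stress_type", "percentile_bin", "N", "gm", "gse"])


def stratified_growth(
    growth: pd.DataFrame,
    quadrant_scores: pd.DataFrame,
    strata: pd.DataFrame,
    n_bins: int = 10,
    bin_on: str = "f",
) -> pd.DataFrame:
    """Repeat the type x percentile summary within each stratum.

    ``strata`` has columns ``(company_id, stratum)`` — e.g. industry sector
    or rating band; scored companies without a label fall in stratum
    ``"unknown"``.  Returns the same columns as
    :func:`growth_by_type_and_percentile` with ``stratum`` prepended.
    """
    labels = strata.set_index("company_id")["stratum"]
    scored = quadrant_scores.copy()
    scored["stratum"] = (
        scored["company_id"].map(labels).fillna("unknown").astype(str)
    )
    frames = []
    for stratum, sub in scored.groupby("stratum", sort=True):
        summary = growth_by_type_and_percentile(growth, sub, n_bins=n_bins, bin_on=bin_on)
        summary.insert(0, "stratum", stratum)
        frames.append(summary)
    if not frames:
        return pd.DataFrame(
            columns=["stratum", "stress_type", "percentile_bin", "N", "gm", "gse"]
        )
    return pd.concat(frames, ignore_index=True)
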