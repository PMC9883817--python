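"""Yearly stress-type indices: volume-weighted sums of associations.

For each calendar year y the cohort is re-scored with the window T = {y}
(so moments, quadrant membership and the association f are all yearly), and
the amount of stress type s expressed in year y is

    m(s, y) = sum over companies c of type s of  f(c, s, y) * w(c, y)

with the post-volume weight

    w(c, y) = (# of c's posts in year y) / (total # of posts in year y)

and w = 0 for companies with no reviews in y.  Weights are shared across
types (the denominator is the cohort-wide yearly post count), so the four
indices are on a common scale and doubling every company's review volume in
a year leaves the index unchanged.

The ``dispersion`` column is the population standard deviation across
contributing companies of their individual contributions f*w within
(s, y) — the spread behind a shaded uncertainty band on an index plot.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .extraction import StressLexicon, compute_company_period_stats
from .quadrant import STRESS_TYPES, DegenerateAxisError, score_companies

__all__ = ["yearly_weights", "yearly_stress_index", "overlay_external_series"]


def _years(reviews: pd.DataFrame) -> pd.Series:
    if "year" in reviews.columns:
        return reviews["year"].astype(int)
    return pd.to_datetime(reviews["date"]).dt.year


def yearly_weights(reviews: pd.DataFrame, year: int) -> pd.DataFrame:
    """Per-company post-volume weights for one year.

    Returns ``(company_id, year, w)`` for every company present in the
    reviews table, w = 0 for companies without posts in ``year``.  The
    weights over companies with posts sum to 1 (all weights are 0, with a
    warning, if the year has no posts at all).
    """
    years = _years(reviews)
    in_year = reviews.loc[years == int(year)]
    total = len(in_year)
    companies = pd.Index(reviews["company_id"].unique(), name="company_id")
    if total == 0:
        warnings.warn(f"no posts in year {year}: all weights 0")
        w = pd.Series(0.0, index=companies)
    else:
        counts = in_year.groupby("company_id").size()
        w = counts.reindex(companies, fill_value=0) / total
    out = w.rename("w").reset_index()
    out.insert(1, "year", int(year))
    return out


def yearly_stress_index(
    reviews: pd.DataFrame,
    lexicon: StressLexicon,
    years: Iterable[int],
    min_reviews: int = 0,
) -> pd.DataFrame:
    """Compute m(s, y) for every stress type and every requested year.

    Each year is scored independently: per-company statistics with
    T = {y}, yearly z-scoring and quadrant assignment, then the weighted
    sum of associations.  All four types are emitted for every year; a year
    whose cohort is degenerate (fewer than two active companies, or zero
    dispersion on an axis, e.g. no stress-matching post anywhere) is emitted
    with missing values and a warning rather than failing the run.

    Returns ``(year, stress_type, m, dispersion, n_companies)``.
    """
    rows = []
    for year in years:
        year = int(year)
        try:
            stats = compute_company_period_stats(reviews, lexicon, (year, year))
            if stats.empty:
                raise DegenerateAxisError(f"no reviews in {year}")
            scored = score_companies(stats, min_reviews=min_reviews)
        except DegenerateAxisError as err:
            warnings.warn(f"year {year} not scorable ({err}); emitting NaN")
            for s in STRESS_TYPES:
                rows.append((year, s, np.nan, np.nan, 0))
            continue
        weights = yearly_weights(reviews, year).set_index("company_id")["w"]
        contrib = scored.set_index("company_id")
        contrib["w"] = weights.reindex(contrib.index, fill_value=0.0)
        contrib["fw"] = contrib["f"] * contrib["w"]
        for s in STRESS_TYPES:
            members = contrib.loc[contrib["stress_type"] == s, "fw"]
            if len(members) == 0:
                rows.append((year, s, 0.0, 0.0, 0))
            else:
                rows.append(
                    (
                        year,
                        s,
                        float(members.sum()),
                        float(members.std(ddof=0)),
                        int(len(members)),
                    )
                )
    return pd.DataFrame(
        rows, columns=["year", "stress_type", "m", "dispersion", "n_companies"]
    )


def overlay_external_series(
    index: pd.DataFrame, external: pd.DataFrame
) -> pd.DataFrame:
    """Correlate each stress-type index with an external yearly series.

    ``external`` has columns ``(year, value)`` — e.g. a national yearly
    unemployment rate.  For each stress type the Pearson and Spearman
    coefficients are computed over the overlapping years; no significance
    claim is attached beyond the coefficient and n.  Requires >= 3
    overlapping years; a constant series (zero variance on either side)
    yields missing coefficients.
    """
    ext = external.dropna().astype({"year": int}).set_index("year")["value"]
    rows = []
    for s, sub in index.dropna(subset=["m"]).groupby("stress_type", sort=False):
        merged = sub.astype({"year": int}).set_index("year")["m"].to_frame("m")
        merged["value"] = ext.reindex(merged.index)
        merged = merged.dropna()
        n = len(merged)
        if n < 3:
            raise ValueError(
                f"need >=3 overlapping years for {s}, found {n}"
            )
        if merged["m"].nunique() < 2 or merged["value"].nunique() < 2:
            pearson = spearman = np.nan
        else:
            pearson = float(sstats.pearsonr(merged["m"], merged["value"])[0])
            spearman = float(sstats.spearmanr(merged["m"], merged["value"])[0])
        rows.append((s, n, pearson, spearman))
    return pd.DataFrame(rows, columns=["stress_type", "n_years", "pearson_r", "spearman_r"])
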