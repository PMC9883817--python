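"""Stress-by-rating quadrant placement and geometric association scoring.

Companies are z-scored on two axes over an observation window T — mean
review rating and stress score — and assigned a stress type by the signs of
the pair:

* ``low_stress``       z_rating >= 0, z_stress <  0
* ``passive``          z_rating <  0, z_stress <  0
* ``negative_stress``  z_rating <  0, z_stress >= 0
* ``positive_stress``  z_rating >= 0, z_stress >= 0

The strength of a company's membership in its quadrant is

    f = R / (gamma + pi)

where R is the radius from the origin to the company's point,
alpha = arccos(|z_rating| / R) and beta = arccos(|z_stress| / R) are the
angles between the radius and the two axes, and
gamma = max(alpha - pi/4, beta - pi/4) is the angular distance from the
quadrant diagonal.  f rewards companies that are far from the origin and
close to their quadrant's diagonal: for fixed direction it grows linearly
with R, and for fixed R it is maximal (R/pi) on the diagonal and minimal
(4R/(5pi)) on an axis.  A company with no reviews during T has f = 0 by
definition, as does a company sitting exactly at the origin.

Z-scores use the population standard deviation (divide by n): mu and sigma
are treated as cohort moments, not sample estimates.  Quadrant boundaries
are half-open with z = 0 counting as the nonnegative side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STRESS_TYPES",
    "CohortMoments",
    "QuadrantScore",
    "zscore_companies",
    "assign_stress_type",
    "association",
    "score_companies",
    "DegenerateAxisError",
]

#: The four stress types in quadrant order used throughout the package.
STRESS_TYPES = ("low_stress", "passive", "negative_stress", "positive_stress")


class DegenerateAxisError(ValueError):
    """Raised when a cohort has zero dispersion on an axis, so z-scores
    are undefined."""


@dataclass(frozen=True)
class CohortMoments:
    """Cohort mean and standard deviation on both axes over window T."""

    mu_rating: float
    sigma_rating: float
    mu_stress: float
    sigma_stress: float
    period: tuple[int, int] | None = None


@dataclass(frozen=True)
class QuadrantScore:
    """A single company's placement and association geometry."""

    z_rating: float
    z_stress: float
    stress_type: str
    R: float
    alpha: float
    beta: float
    gamma: float
    f: float


def zscore_companies(
    stats: pd.DataFrame, ddof: int = 0
) -> tuple[pd.DataFrame, CohortMoments]:
    """Z-score the cohort on mean rating and stress score.

    Parameters
    ----------
    stats
        Per-company window statistics with ``mean_rating`` and
        ``stress_score`` columns (one row per company).
    ddof
        Delta degrees of freedom for the standard deviation; 0 (population
        convention) by default.

    Returns the input with ``z_rating`` and ``z_stress`` columns appended,
    plus the cohort moments used.  Raises :class:`DegenerateAxisError` when
    either axis has zero dispersion (fewer than two distinct values).
    """
    if len(stats) < 2:
        raise DegenerateAxisError("need at least 2 companies to z-score a cohort")
    mu_r = float(stats["mean_rating"].mean())
    mu_s = float(stats["stress_score"].mean())
    sd_r = float(stats["mean_rating"].std(ddof=ddof))
    sd_s = float(stats["stress_score"].std(ddof=ddof))
    if sd_r == 0.0:
        raise DegenerateAxisError("rating axis is degenerate: zero dispersion")
    if sd_s == 0.0:
        raise DegenerateAxisError("stress axis is degenerate: zero dispersion")
    out = stats.copy()
    out["z_rating"] = (stats["mean_rating"] - mu_r) / sd_r
    out["z_stress"] = (stats["stress_score"] - mu_s) / sd_s
    moments = CohortMoments(mu_r, sd_r, mu_s, sd_s)
    return out, moments


def assign_stress_type(z_rating: float, z_stress: float) -> str:
    """Map a z-score pair to its quadrant's stress type.

    z = 0 counts as the nonnegative side, so the origin falls in
    ``positive_stress``.
    """
    if z_stress < 0:
        return "low_stress" if z_rating >= 0 else "passive"
    return "positive_stress" if z_rating >= 0 else "negative_stress"


def association(z_rating: float, z_stress: float) -> QuadrantScore:
    """Compute the full association geometry for one z-score pair.

    At the origin (R = 0) the angles alpha and beta are undefined (0/0); by
    convention the point lies on the diagonal (gamma = 0) with f = 0, the
    weakest possible association.
    """
    z_r = float(z_rating)
    z_s = float(z_stress)
    stress_type = assign_stress_type(z_r, z_s)
    R = float(np.hypot(z_r, z_s))
    if R == 0.0:
        return QuadrantScore(z_r, z_s, stress_type, 0.0, np.pi / 4, np.pi / 4, 0.0, 0.0)
    alpha = float(np.arccos(min(abs(z_r) / R, 1.0)))
    beta = float(np.arccos(min(abs(z_s) / R, 1.0)))
    gamma = max(alpha - np.pi / 4, beta - np.pi / 4)
    f = R / (gamma + np.pi)
    return QuadrantScore(z_r, z_s, stress_type, R, alpha, beta, gamma, f)


def _association_arrays(
    z_rating: np.ndarray, z_stress: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised association geometry (origin handled by convention)."""
    z_r = np.asarray(z_rating, dtype=float)
    z_s = np.asarray(z_stress, dtype=float)
    R = np.hypot(z_r, z_s)
    safe_R = np.where(R == 0, 1.0, R)
    alpha = np.arccos(np.clip(np.abs(z_r) / safe_R, -1.0, 1.0))
    beta = np.arccos(np.clip(np.abs(z_s) / safe_R, -1.0, 1.0))
    gamma = np.maximum(alpha - np.pi / 4, beta - np.pi / 4)
    alpha = np.where(R == 0, np.pi / 4, alpha)
    beta = np.where(R == 0, np.pi / 4, beta)
    gamma = np.where(R == 0, 0.0, gamma)
    f = R / (gamma + np.pi)
    stress_type = np.where(
        z_s < 0,
        np.where(z_r >= 0, "low_stress", "passive"),
        np.where(z_r >= 0, "positive_stress", "negative_stress"),
    )
    return {
        "z_rating": z_r,
        "z_stress": z_s,
        "stress_type": stress_type,
        "R": R,
        "alpha": alpha,
        "beta": beta,
        "gamma": gamma,
        "f": f,
    }


def score_companies(stats: pd.DataFrame, min_reviews: int = 0) -> pd.DataFrame:
    """Z-score a cohort, assign stress types and compute associations.

    Parameters
    ----------
    stats
        Output of :func:`stressquad.extraction.compute_company_period_stats`.
    min_reviews
        Drop companies with fewer than this many posts in the window before
        computing cohort moments (0 = keep everyone, the default).

    Returns one row per scored company:
    ``company_id, n_posts, mean_rating, stress_score, z_rating, z_stress,
    stress_type, R, gamma, f``.
    """
    kept = stats
    if min_reviews > 0 and "n_posts" in stats.columns:
        kept = stats.loc[stats["n_posts"] >= min_reviews]
    if kept.empty:
        return pd.DataFrame(
            columns=[
                "company_id", "n_posts", "mean_rating", "stress_score",
                "z_rating", "z_stress", "stress_type", "R", "gamma", "f",
            ]
        )
    scored, _ = zscore_companies(kept)
    geo = _association_arrays(
        scored["z_rating"].to_numpy(), scored["z_stress"].to_numpy()
    )
    for col in ("stress_type", "R", "gamma", "f"):
        scored[col] = geo[col]
    keep = [
        c
        for c in (
            "company_id", "n_posts", "n_stress_posts", "mean_rating",
            "stress_score", "z_rating", "z_stress", "stress_type",
            "R", "gamma", "f",
        )
        if c in scored.columns
    ]
    return scored[keep].reset_index(drop=True)
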