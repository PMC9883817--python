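"""Synthetic review corpora and stock series with planted stress structure.

The generator emulates the kind of data the pipeline targets — a decade-plus
stream of employee reviews about a cohort of public companies, plus yearly
average stock prices — with the structure the analysis is meant to recover
planted explicitly:

* each company belongs to one of four archetypes (the four stress types);
* its yearly review count is Poisson with the archetype's mean volume;
* each rating is Normal around the archetype mean, rounded and clamped to
  the 1-5 star scale;
* with the archetype's stress-post probability a review embeds one lexicon
  phrase verbatim (case may vary), otherwise only neutral filler phrases;
* ten-year stock growth is log-normal with an archetype-specific log-mean,
  and intermediate years are geometric interpolations.

Default volumes (about 50 reviews per company-year) mirror the order of
magnitude of large public-company review corpora (hundreds of thousands of
posts over ~500 companies and ~12 years); default rating means (4.2 vs 2.8),
stress-post probabilities (0.03 vs 0.002) and growth log-means (ln 5.07 for
the positive-stress archetype, ln 3.70 for the rest) plant well-separated
archetypes whose recovery downstream is a meaningful end-to-end check.

Ground-truth labels live in a sidecar table that no pipeline stage ever
reads.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .extraction import StressLexicon
from .quadrant import STRESS_TYPES

__all__ = [
    "ArchetypeSpec",
    "SyntheticCohortConfig",
    "ConfigurationError",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_FILLER_VOCAB",
    "generate_reviews",
    "generate_stocks",
]


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters of one stress-type archetype.

    Parameters
    ----------
    stress_type
        One of ``low_stress, passive, negative_stress, positive_stress``.
    rating_mean, rating_sd
        Mean and sd of the latent Normal rating, before rounding/clamping
        to integers 1-5.
    stress_post_prob
        Probability that a generated review embeds a lexicon phrase.
    reviews_per_year_mean
        Poisson mean of the company-year review count.
    growth_log_mean, growth_log_sd
        Mean and sd of the log of ten-year stock growth.
    """

    stress_type: str
    rating_mean: float
    stress_post_prob: float
    growth_log_mean: float
    rating_sd: float = 0.8
    reviews_per_year_mean: float = 50.0
    growth_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.stress_type not in STRESS_TYPES:
            raise ConfigurationError(f"unknown stress type {self.stress_type!r}")
        if not 1.0 <= self.rating_mean <= 5.0:
            raise ConfigurationError("rating_mean must lie in [1, 5]")
        if self.rating_sd <= 0:
            raise ConfigurationError("rating_sd must be > 0")
        if not 0.0 <= self.stress_post_prob <= 1.0:
            raise ConfigurationError("stress_post_prob must lie in [0, 1]")
        if self.reviews_per_year_mean <= 0:
            raise ConfigurationError("reviews_per_year_mean must be > 0")
        if self.growth_log_sd < 0:
            raise ConfigurationError("growth_log_sd must be >= 0")


DEFAULT_ARCHETYPES: Mapping[str, ArchetypeSpec] = {
    "low_stress": ArchetypeSpec(
        "low_stress", rating_mean=4.2, stress_post_prob=0.002,
        growth_log_mean=math.log(3.70),
    ),
    "passive": ArchetypeSpec(
        "passive", rating_mean=2.8, stress_post_prob=0.002,
        growth_log_mean=math.log(3.70),
    ),
    "negative_stress": ArchetypeSpec(
        "negative_stress", rating_mean=2.8, stress_post_prob=0.03,
        growth_log_mean=math.log(3.70),
    ),
    "positive_stress": ArchetypeSpec(
        "positive_stress", rating_mean=4.2, stress_post_prob=0.03,
        growth_log_mean=math.log(5.07),
    ),
}

DEFAULT_FILLER_VOCAB: tuple[str, ...] = (
    "great benefits",
    "friendly coworkers",
    "good pay",
    "long commute",
    "nice office space",
    "decent management",
    "room to grow",
    "flexible schedule",
    "solid training",
    "interesting projects",
    "smart colleagues",
    "slow promotions",
    "free snacks",
    "good culture",
    "limited parking",
    "fair salary",
    "modern tools",
    "clear goals",
    "steady hours",
    "quiet floors",
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full description of a synthetic cohort; (config, seed) fixes the data."""

    n_companies_per_type: int = 50
    years: tuple[int, int] = (2008, 2020)
    seed: int = 0
    archetypes: Mapping[str, ArchetypeSpec] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    lexicon: Sequence[str] = ()
    filler_vocab: Sequence[str] = DEFAULT_FILLER_VOCAB
    growth_anchor_years: tuple[int, int] = (2009, 2019)

    def __post_init__(self) -> None:
        if self.n_companies_per_type < 1:
            raise ConfigurationError("n_companies_per_type must be >= 1")
        if self.years[0] > self.years[1]:
            raise ConfigurationError("years range is empty")
        if set(self.archetypes) != set(STRESS_TYPES):
            raise ConfigurationError("archetypes must cover exactly the four stress types")
        if not self.lexicon:
            object.__setattr__(self, "lexicon", StressLexicon.default().phrases)
        if not tuple(self.lexicon):
            raise ConfigurationError("lexicon must be non-empty")
        if not tuple(self.filler_vocab):
            raise ConfigurationError("filler_vocab must be non-empty")
        self._check_separation()

    def _check_separation(self) -> None:
        # The archetype geometry must agree with the quadrant semantics:
        # high raters are the low/positive-stress types, high stress-post
        # probability marks the negative/positive-stress types.  Skipped on
        # a degenerate (constant) axis, which is a legitimate edge case.
        means = {s: a.rating_mean for s, a in self.archetypes.items()}
        probs = {s: a.stress_post_prob for s, a in self.archetypes.items()}
        mid_rating = sum(means.values()) / 4
        mid_prob = sum(probs.values()) / 4
        if len(set(means.values())) > 1:
            for s, m in means.items():
                high = s in ("low_stress", "positive_stress")
                if high != (m > mid_rating):
                    raise ConfigurationError(
                        f"rating_mean of {s} on the wrong side of the cohort midpoint"
                    )
        if len(set(probs.values())) > 1:
            for s, p in probs.items():
                high = s in ("negative_stress", "positive_stress")
                if high != (p > mid_prob):
                    raise ConfigurationError(
                        f"stress_post_prob of {s} on the wrong side of the cohort midpoint"
                    )

    def with_seed(self, seed: int) -> "SyntheticCohortConfig":
        return replace(self, seed=int(seed))


def _company_table(config: SyntheticCohortConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for stress_type in STRESS_TYPES:
        for _ in range(config.n_companies_per_type):
            rows.append((f"C{i:04d}", stress_type))
            i += 1
    return pd.DataFrame(rows, columns=["company_id", "stress_type"])


def _compose_text(
    rng: np.random.Generator,
    filler: Sequence[str],
    lexicon: Sequence[str],
    stressful: bool,
) -> str:
    n_filler = int(rng.integers(2, 4))
    idx = rng.choice(len(filler), size=n_filler, replace=False)
    parts = [filler[j] for j in idx]
    if stressful:
        phrase = lexicon[int(rng.integers(len(lexicon)))]
        # surface form varies in case only, never in wording
        form = [phrase, phrase.capitalize()][int(rng.integers(2))]
        carrier = f"there is {form} most days" if form == phrase else f"{form} most days"
        parts.insert(int(rng.integers(len(parts) + 1)), carrier)
    sentence = ". ".join(p[0].upper() + p[1:] for p in parts) + "."
    return sentence


def generate_reviews(
    config: SyntheticCohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the review stream and the ground-truth sidecar.

    Returns
    -------
    reviews
        Columns ``company_id, date (ISO-8601 string), rating, text``, one
        row per review, ordered by company then date.  Every company has at
        least one review over the full period (a single review is forced
        into a random year for companies whose Poisson draws all came up
        zero).
    ground_truth
        Columns ``company_id, stress_type`` — the planted labels.  Pipeline
        stages must never read this table; it exists only to evaluate
        recovery.
    """
    rng = np.random.default_rng(config.seed)
    companies = _company_table(config)
    lexicon = tuple(str(p).lower() for p in config.lexicon)
    filler = tuple(config.filler_vocab)
    years = range(config.years[0], config.years[1] + 1)
    records: list[tuple[str, str, int, str]] = []
    for company_id, stress_type in companies.itertuples(index=False):
        spec = config.archetypes[stress_type]
        counts = rng.poisson(spec.reviews_per_year_mean, size=len(years))
        if counts.sum() == 0:
            counts[int(rng.integers(len(counts)))] = 1
        for year, n in zip(years, counts):
            if n == 0:
                continue
            ratings = np.clip(
                np.rint(rng.normal(spec.rating_mean, spec.rating_sd, size=n)), 1, 5
            ).astype(int)
            stressful = rng.random(n) < spec.stress_post_prob
            days = rng.integers(0, 365, size=n)
            for k in range(int(n)):
                date = (
                    pd.Timestamp(year=year, month=1, day=1)
                    + pd.Timedelta(days=int(days[k]))
                ).strftime("%Y-%m-%d")
                text = _compose_text(rng, filler, lexicon, bool(stressful[k]))
                records.append((company_id, date, int(ratings[k]), text))
    reviews = pd.DataFrame(records, columns=["company_id", "date", "rating", "text"])
    reviews = reviews.sort_values(["company_id", "date"], kind="mergesort").reset_index(
        drop=True
    )
    return reviews, companies


def generate_stocks(
    config: SyntheticCohortConfig, company_types: pd.DataFrame
) -> pd.DataFrame:
    """Generate yearly average adjusted closing prices for every company.

    The anchor-start price is log-normal around $50; the anchor-end price
    multiplies it by exp(Normal(growth_log_mean, growth_log_sd)) for the
    company's archetype; every other year in the configured range lies on
    the geometric path through the two anchors.  Returns
    ``(company_id, year, adj_close_avg)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    start, end = config.growth_anchor_years
    span = end - start
    if span <= 0:
        raise ConfigurationError("growth anchor years must be increasing")
    years = np.arange(config.years[0], config.years[1] + 1)
    rows = []
    for company_id, stress_type in company_types.itertuples(index=False):
        spec = config.archetypes[stress_type]
        base = float(np.exp(rng.normal(np.log(50.0), 0.6)))
        log_growth = float(rng.normal(spec.growth_log_mean, spec.growth_log_sd))
        prices = base * np.exp(log_growth * (years - start) / span)
        rows.extend(
            (company_id, int(y), float(p)) for y, p in zip(years, prices)
        )
    return pd.DataFrame(rows, columns=["company_id", "year", "adj_close_avg"])
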