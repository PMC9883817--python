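"""Lexicon-based detection of workplace-stress mentions in review text.

A review "relates to stress" when it contains at least one phrase from a
closed stress-condition lexicon, matched case-insensitively at word
boundaries.  Per company and observation window the module aggregates the
two quantities everything downstream builds on:

* ``mean_rating`` -- the arithmetic mean of the company's star ratings, and
* ``stress_score`` -- the fraction of the company's posts that relate to
  stress (posts, not mentions: a post with three matches counts once).

The matcher is a deliberate surface-form replacement for neural medical
entity extraction: the end of that pipeline is membership of an extracted
span in a closed phrase list, which plain phrase matching reproduces for the
listed surface forms.  No negation or figurative-use handling is attempted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "StressLexicon",
    "PhraseMatch",
    "match_stress_mentions",
    "compute_company_period_stats",
    "condition_frequency_table",
]

_DEFAULT_LEXICON_RESOURCE = "stress_conditions.txt"


class PhraseMatch(NamedTuple):
    """One resolved lexicon hit: the canonical phrase and its char span."""

    phrase: str
    start: int
    end: int


@dataclass(frozen=True)
class StressLexicon:
    """An ordered list of lowercase stress-condition phrases.

    Parameters
    ----------
    phrases
        Non-empty, duplicate-free phrases; stored lowercase.
    name
        Provenance label carried into reports.
    """

    phrases: tuple[str, ...]
    name: str = "custom"
    _pattern: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        phrases = tuple(p.strip().lower() for p in self.phrases)
        if not phrases:
            raise ValueError("lexicon must contain at least one phrase")
        if any(not p for p in phrases):
            raise ValueError("lexicon phrases must be non-blank")
        if len(set(phrases)) != len(phrases):
            raise ValueError("lexicon phrases must be unique")
        object.__setattr__(self, "phrases", phrases)
        object.__setattr__(self, "_pattern", _compile_pattern(phrases))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "StressLexicon":
        """Read a lexicon file: one phrase per line, ``#`` starts a comment."""
        path = Path(path)
        phrases = []
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                phrases.append(line)
        return cls(tuple(phrases), name=name or path.stem)

    @classmethod
    def default(cls) -> "StressLexicon":
        """The bundled 15-condition workplace-stress lexicon."""
        text = (
            resources.files("stressquad.data")
            .joinpath(_DEFAULT_LEXICON_RESOURCE)
            .read_text(encoding="utf-8")
        )
        phrases = tuple(
            stripped
            for line in text.splitlines()
            if (stripped := line.split("#", 1)[0].strip())
        )
        return cls(phrases, name="stress_conditions")

    def __len__(self) -> int:
        return len(self.phrases)

    def __iter__(self):
        return iter(self.phrases)


def _compile_pattern(phrases: Iterable[str]) -> re.Pattern:
    # Longest alternative first so the scan is leftmost-longest: at a given
    # start the longer phrase wins ("extreme stress" suppresses the inner
    # "stress"), and backtracking still finds the shorter phrase when the
    # longer one fails its trailing word boundary.
    parts = [
        r"\s+".join(re.escape(w) for w in p.split())
        for p in sorted(phrases, key=lambda p: (-len(p), p))
    ]
    return re.compile(r"\b(?:%s)\b" % "|".join(parts), re.IGNORECASE)


def _canonical(lexicon: StressLexicon, surface: str) -> str:
    return re.sub(r"\s+", " ", surface.lower())


def match_stress_mentions(text: str, lexicon: StressLexicon) -> list[PhraseMatch]:
    """Find all stress-condition mentions in ``text``.

    Matching is case-insensitive and respects word boundaries; overlapping
    candidates are resolved leftmost-first, longest phrase winning at a
    shared start position.  Returns the resolved, non-overlapping matches in
    order of appearance; an empty list means the review does not relate to
    stress.
    """
    if not text:
        return []
    return [
        PhraseMatch(_canonical(lexicon, m.group(0)), m.start(), m.end())
        for m in lexicon._pattern.finditer(text)
    ]


def _require_columns(reviews: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in reviews.columns]
    if missing:
        raise ValueError(f"reviews table missing columns: {missing}")


def _year_series(reviews: pd.DataFrame) -> pd.Series:
    if "year" in reviews.columns:
        return reviews["year"].astype(int)
    return pd.to_datetime(reviews["date"]).dt.year


def relates_to_stress(texts: pd.Series, lexicon: StressLexicon) -> pd.Series:
    """Vectorised per-review indicator of >=1 lexicon mention."""
    return texts.fillna("").str.contains(lexicon._pattern)


def compute_company_period_stats(
    reviews: pd.DataFrame,
    lexicon: StressLexicon,
    period: tuple[int, int],
) -> pd.DataFrame:
    """Aggregate reviews into per-company window statistics.

    Parameters
    ----------
    reviews
        Columns ``company_id``, ``date`` (or ``year``), ``rating``, ``text``.
    lexicon
        Stress-condition lexicon used for the post-level indicator.
    period
        Inclusive ``(first_year, last_year)`` observation window T.

    Returns
    -------
    DataFrame with one row per company that posted at least once in T:
    ``company_id, n_posts, n_stress_posts, mean_rating, stress_score``.
    Companies silent during T are simply absent (downstream they carry an
    association of zero).
    """
    first, last = int(period[0]), int(period[1])
    if first > last:
        raise ValueError(f"empty period: ({first}, {last})")
    _require_columns(reviews, ["company_id", "rating", "text"])
    if reviews.empty:
        warnings.warn("empty reviews table: no company statistics computed")
        return pd.DataFrame(
            columns=["company_id", "n_posts", "n_stress_posts", "mean_rating", "stress_score"]
        )
    years = _year_series(reviews)
    window = reviews.loc[(years >= first) & (years <= last)].copy()
    if window.empty:
        warnings.warn(f"no reviews fall in period {first}-{last}")
        return pd.DataFrame(
            columns=["company_id", "n_posts", "n_stress_posts", "mean_rating", "stress_score"]
        )
    window["_stress"] = relates_to_stress(window["text"], lexicon)
    grouped = window.groupby("company_id", sort=True)
    stats = pd.DataFrame(
        {
            "n_posts": grouped.size(),
            "n_stress_posts": grouped["_stress"].sum().astype(int),
            "mean_rating": grouped["rating"].mean(),
        }
    )
    stats["stress_score"] = stats["n_stress_posts"] / stats["n_posts"]
    return stats.reset_index()


def condition_frequency_table(
    reviews: pd.DataFrame, lexicon: StressLexicon
) -> pd.DataFrame:
    """Count total mentions per lexicon phrase across the corpus.

    Counts mentions, not posts: a review containing "stress" twice adds two.
    Returns ``(phrase, n_mentions)`` sorted by descending count, phrases with
    zero mentions included.
    """
    counts = {p: 0 for p in lexicon.phrases}
    texts = reviews["text"] if not reviews.empty else pd.Series([], dtype=str)
    # Pre-filter with the vectorised indicator; finditer only on hits.
    if len(texts):
        hits = texts.fillna("")[relates_to_stress(texts, lexicon)]
        for text in hits:
            for match in match_stress_mentions(text, lexicon):
                counts[match.phrase] += 1
    table = pd.DataFrame(
        {"phrase": list(counts), "n_mentions": list(counts.values())}
    )
    return table.sort_values(
        ["n_mentions", "phrase"], ascending=[False, True], ignore_index=True
    )
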