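"""Tabular input/output, input validation and pipeline orchestration.

All tables are comma-delimited UTF-8 text with a header row; free-text
fields are quoted.  Stage outputs (but not raw review tables, whose text
could contain any character) start with ``#``-prefixed provenance comments
recording the configuration hash and seed, so a rerun with identical inputs
and configuration is byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import extraction, finance, quadrant, temporal, topics
from .extraction import StressLexicon

__all__ = [
    "read_table",
    "write_table",
    "read_reviews",
    "write_reviews",
    "validate_reviews",
    "PipelineConfig",
    "run_all",
]

REVIEW_COLUMNS = ("company_id", "date", "rating", "text")


def read_table(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    """Read a delimited stage artifact, skipping ``#`` comment lines."""
    return pd.read_csv(path, comment="#", **kwargs)


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict[str, Any] | None = None
) -> Path:
    """Write a table with optional ``# key=value`` provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
    return path


def write_reviews(reviews: pd.DataFrame, path: str | Path) -> Path:
    """Write a review table (no comment header: text is arbitrary)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    reviews.to_csv(path, index=False)
    return path


def read_reviews(path: str | Path) -> pd.DataFrame:
    """Read a review table without validation (see :func:`validate_reviews`)."""
    return pd.read_csv(path)


def validate_reviews(path: str | Path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a review table, dropping malformed rows and counting why.

    Checks column presence (missing columns are fatal), integer ratings in
    1-5 and ISO-parseable dates.  Returns the cleaned table and a report of
    dropped-row counts keyed by reason (``rating_range``, ``bad_date``,
    ``missing_value``), plus ``n_kept``.
    """
    df = pd.read_csv(path)
    missing = [c for c in REVIEW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"review file {path} missing columns: {missing}")
    report = {"rating_range": 0, "bad_date": 0, "missing_value": 0}
    essential = df[list(REVIEW_COLUMNS)].drop(columns="text")
    bad_missing = essential.isna().any(axis=1)
    report["missing_value"] = int(bad_missing.sum())
    df = df.loc[~bad_missing].copy()
    rating = pd.to_numeric(df["rating"], errors="coerce")
    bad_rating = rating.isna() | (rating != rating.round()) | (rating < 1) | (rating > 5)
    report["rating_range"] = int(bad_rating.sum())
    df = df.loc[~bad_rating].copy()
    df["rating"] = df["rating"].astype(int)
    parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad_date = parsed.isna()
    report["bad_date"] = int(bad_date.sum())
    df = df.loc[~bad_date].copy()
    report["n_kept"] = int(len(df))
    return df.reset_index(drop=True), report


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, loadable from YAML."""

    reviews: str = "reviews.csv"
    stocks: str = "stocks.csv"
    lexicon: str | None = None          # None = bundled default lexicon
    out_dir: str = "out"
    window: tuple[int, int] = (2009, 2019)
    index_years: tuple[int, int] = (2008, 2020)
    growth_start: int = 2009
    growth_end: int = 2019
    min_reviews: int = 0
    n_bins: int = 10
    bin_on: str = "f"
    top_k: int = 3
    alpha: float = 0.05
    seed: int = 0
    log_ctfidf: bool = False
    yates: bool = False
    bh: bool = False
    strata: str | None = None

    def __post_init__(self) -> None:
        self.window = (int(self.window[0]), int(self.window[1]))
        self.index_years = (int(self.index_years[0]), int(self.index_years[1]))
        if self.window[0] > self.window[1]:
            raise ValueError("window start must be <= end")
        if self.n_bins < 1 or self.top_k < 1:
            raise ValueError("n_bins and top_k must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bin_on not in ("f", "stress_score"):
            raise ValueError("bin_on must be 'f' or 'stress_score'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        fields = asdict(self)
        fields.pop("out_dir")  # where results land does not affect them
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict[str, Any]:
        return {"config_hash": self.config_hash(), "seed": self.seed}


def _load_lexicon(config: PipelineConfig) -> StressLexicon:
    if config.lexicon:
        return StressLexicon.from_file(config.lexicon)
    return StressLexicon.default()


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Execute extraction -> quadrant -> temporal -> topics -> finance.

    Writes every stage artifact under ``config.out_dir`` and returns a map
    of artifact name to path.  On failure, partially written artifacts are
    removed before the exception propagates.  Reruns with the same inputs
    and configuration are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = config.provenance()
    written: dict[str, Path] = {}
    try:
        reviews, report = validate_reviews(config.reviews)
        lexicon = _load_lexicon(config)

        stats = extraction.compute_company_period_stats(reviews, lexicon, config.window)
        written["company_stats"] = write_table(stats, out_dir / "company_stats.csv", meta)
        freq = extraction.condition_frequency_table(reviews, lexicon)
        written["condition_frequency"] = write_table(
            freq, out_dir / "condition_frequency.csv", meta
        )

        scores = quadrant.score_companies(stats, min_reviews=config.min_reviews)
        written["quadrant_scores"] = write_table(
            scores, out_dir / "quadrant_scores.csv", meta
        )
        if scores.empty:
            warnings.warn("no company passed the min-review filter; stopping early")
            return written

        index = temporal.yearly_stress_index(
            reviews,
            lexicon,
            range(config.index_years[0], config.index_years[1] + 1),
            min_reviews=config.min_reviews,
        )
        written["yearly_index"] = write_table(index, out_dir / "yearly_index.csv", meta)

        corpora = topics.build_class_corpora(reviews, quadrant_scores=scores)
        kw = topics.ctfidf_scores(corpora, log_variant=config.log_ctfidf)
        written["keyword_scores"] = write_table(kw, out_dir / "keyword_scores.csv", meta)
        top = topics.top_keywords(kw, k=config.top_k)
        written["top_keywords"] = write_table(top, out_dir / "top_keywords.csv", meta)
        contingency = kw.pivot_table(
            index="class_id", columns="keyword", values="k_l", fill_value=0
        )
        verdicts = topics.topic_quadrant_chisq(
            contingency, alpha=config.alpha, correction=config.yates, fdr=config.bh
        )
        written["keyword_associations"] = write_table(
            verdicts, out_dir / "keyword_associations.csv", meta
        )

        prices = read_table(config.stocks)
        growth = finance.stock_growth(prices, config.growth_start, config.growth_end)
        written["stock_growth"] = write_table(growth, out_dir / "stock_growth.csv", meta)
        summary = finance.growth_by_type_and_percentile(
            growth, scores, n_bins=config.n_bins, bin_on=config.bin_on
        )
        written["growth_summary"] = write_table(
            summary, out_dir / "growth_summary.csv", meta
        )
        if config.strata:
            strata = read_table(config.strata)
            strat = finance.stratified_growth(
                growth, scores, strata, n_bins=config.n_bins, bin_on=config.bin_on
            )
            written["growth_stratified"] = write_table(
                strat, out_dir / "growth_stratified.csv", meta
            )

        company_summary = scores.merge(growth, on="company_id", how="left")
        written["company_summary"] = write_table(
            company_summary, out_dir / "company_summary.csv", meta
        )
        validation = pd.DataFrame(
            sorted(report.items()), columns=["reason", "n_rows"]
        )
        written["validation_report"] = write_table(
            validation, out_dir / "validation_report.csv", meta
        )
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    return written
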