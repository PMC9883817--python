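"""Class-based TF-IDF keyword scoring and keyword-quadrant association.

Reviews are pooled into document classes — by default the four stress types
of their companies, alternatively any externally supplied review-to-cluster
assignment — and each keyword k is scored per class l with

    c-TF-IDF_l(k) = (k_l / o_l) * (p / q)

where k_l is k's frequency in class l, o_l the total keyword count in l,
p the total number of documents across classes, and q the total frequency
of k across all classes.  The formula is linear (no logarithm); a damped
log variant (k_l / o_l) * log(1 + p / q) is available behind a flag.  Note
the score is invariant under duplicating the whole corpus and, within a
class, ranking is invariant to positive rescaling of all frequencies.

Keyword-quadrant association follows a two-sided rule: a keyword is
"associated" with class s when its in-class frequency is positive, a
chi-square test shows dependence on s, and no significant dependence is
found with any other class (tested among the remaining classes with s's
documents held out).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "ClassCorpus",
    "build_class_corpora",
    "tokenize",
    "ctfidf_scores",
    "top_keywords",
    "topic_quadrant_chisq",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:/[a-z0-9]+)*")


@dataclass(frozen=True)
class ClassCorpus:
    """All documents belonging to one class (stress type or cluster id)."""

    class_id: str
    documents: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.documents:
            raise ValueError(f"class {self.class_id!r} has no documents")


def tokenize(
    text: str, stop_words: Iterable[str] = (), bigrams: bool = False
) -> list[str]:
    """Lowercase alphanumeric word tokens (slash-compounds kept whole)."""
    stop = set(stop_words)
    tokens = [t for t in _TOKEN_RE.findall(text.lower()) if t not in stop]
    if bigrams:
        tokens = tokens + [f"{a} {b}" for a, b in zip(tokens, tokens[1:])]
    return tokens


def build_class_corpora(
    reviews: pd.DataFrame,
    quadrant_scores: pd.DataFrame | None = None,
    cluster_assignment: pd.DataFrame | None = None,
) -> list[ClassCorpus]:
    """Group review texts into document classes.

    Default classing maps each review to its company's stress type via
    ``quadrant_scores`` (columns ``company_id, stress_type``).  An external
    ``cluster_assignment`` (columns ``review_id, cluster_id`` with
    ``review_id`` indexing rows of ``reviews``) overrides it — this is the
    hook for externally computed embedding/clustering pipelines.  Reviews
    whose company is unscored (or whose id is unassigned) are dropped, with
    the count reported in a warning.
    """
    if cluster_assignment is not None:
        labels = (
            cluster_assignment.set_index("review_id")["cluster_id"]
            .reindex(reviews.index)
        )
    elif quadrant_scores is not None:
        mapping = quadrant_scores.set_index("company_id")["stress_type"]
        labels = reviews["company_id"].map(mapping)
    else:
        raise ValueError("provide quadrant_scores or cluster_assignment")
    dropped = int(labels.isna().sum())
    if dropped:
        warnings.warn(f"{dropped} reviews dropped: no class assignment")
    kept = reviews.loc[labels.notna(), "text"].fillna("")
    labels = labels.dropna().astype(str)
    return [
        ClassCorpus(class_id, tuple(kept.loc[labels == class_id]))
        for class_id in sorted(labels.unique())
    ]


def ctfidf_scores(
    corpora: Sequence[ClassCorpus],
    stop_words: Iterable[str] = (),
    bigrams: bool = False,
    log_variant: bool = False,
) -> pd.DataFrame:
    """Score every (class, keyword) pair with class-based TF-IDF.

    Returns ``(class_id, keyword, k_l, o_l, p, q_sum, score)`` covering the
    full class x vocabulary cross, so absent keywords appear with score 0.
    Raises if fewer than two classes are given or the vocabulary is empty
    after stop-word filtering.
    """
    if len(corpora) < 2:
        raise ValueError("need at least 2 classes for c-TF-IDF")
    counts: dict[str, dict[str, int]] = {}
    p = 0
    for corpus in corpora:
        p += len(corpus.documents)
        c: dict[str, int] = {}
        for doc in corpus.documents:
            for tok in tokenize(doc, stop_words, bigrams):
                c[tok] = c.get(tok, 0) + 1
        counts[corpus.class_id] = c
    vocab = sorted(set().union(*(c.keys() for c in counts.values())))
    if not vocab:
        raise ValueError("empty vocabulary after filtering")
    mat = pd.DataFrame(
        {cid: [counts[cid].get(k, 0) for k in vocab] for cid in counts},
        index=pd.Index(vocab, name="keyword"),
    )
    o = mat.sum(axis=0)          # total keyword count per class
    q = mat.sum(axis=1)          # total frequency of each keyword
    idf = np.log1p(p / q) if log_variant else p / q
    rows = []
    for cid in mat.columns:
        tf = mat[cid] / o[cid]
        score = tf * idf
        rows.append(
            pd.DataFrame(
                {
                    "class_id": cid,
                    "keyword": mat.index,
                    "k_l": mat[cid].to_numpy(),
                    "o_l": int(o[cid]),
                    "p": p,
                    "q_sum": q.to_numpy(),
                    "score": score.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def top_keywords(scores: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """The k highest-scoring keywords per class, ties broken alphabetically.

    Only keywords that actually occur in the class (score > 0) are ranked;
    if a class offers fewer than k such keywords, all are emitted with a
    warning.  Returns ``(class_id, rank, keyword, score)`` with rank 1-based.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    for cid, sub in scores.groupby("class_id", sort=True):
        present = sub.loc[sub["score"] > 0]
        ranked = present.sort_values(
            ["score", "keyword"], ascending=[False, True], kind="mergesort"
        )
        if len(ranked) < k:
            warnings.warn(f"class {cid}: only {len(ranked)} scored keywords (< {k})")
        for rank, (_, row) in enumerate(ranked.head(k).iterrows(), start=1):
            rows.append((cid, rank, row["keyword"], float(row["score"])))
    return pd.DataFrame(rows, columns=["class_id", "rank", "keyword", "score"])


def _chi2_2x2(table: np.ndarray, correction: bool) -> tuple[float, float, bool]:
    """Chi-square independence test; (stat, p, reliable).

    Degenerate margins (an all-zero row or column) mean the factor carries
    no information, which we read as exact independence: stat 0, p 1.
    ``reliable`` is False when any expected cell count is below 1.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    stat, p, _, expected = sstats.chi2_contingency(table, correction=correction)
    return float(stat), float(p), bool((expected >= 1).all())


def topic_quadrant_chisq(
    keyword_counts: pd.DataFrame,
    alpha: float = 0.05,
    correction: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Test each keyword's association with each class of a contingency.

    Parameters
    ----------
    keyword_counts
        Class x keyword contingency of nonnegative integer counts (classes
        as the index, keywords as columns) — e.g. the pivoted ``k_l`` from
        :func:`ctfidf_scores`.
    alpha
        Significance level for the dependence/independence verdicts.
    correction
        Apply the Yates continuity correction to the 2x2 tests (off by
        default so the statistic is the plain sum of (O-E)^2/E).
    fdr
        Benjamini-Hochberg-adjust all p-values before the verdicts.

    For each (keyword, class s): a 2x2 test of the keyword against
    membership in s, plus, for every other class s', a 2x2 test of the
    keyword against s' restricted to documents outside s.  The verdict
    ``associated`` requires in-class frequency > 0, significant dependence
    on s and no significant dependence on any other class.  ``reliable`` is
    False when the dependence test has an expected cell below 1.
    """
    mat = keyword_counts.astype(float)
    classes = list(mat.index)
    col_tot = mat.sum(axis=0)
    row_tot = mat.sum(axis=1)
    total = float(mat.to_numpy().sum())
    rows = []
    for keyword in mat.columns:
        for s in classes:
            k_in = float(mat.loc[s, keyword])
            dep = np.array(
                [
                    [k_in, row_tot[s] - k_in],
                    [col_tot[keyword] - k_in, total - row_tot[s] - col_tot[keyword] + k_in],
                ]
            )
            stat, p_dep, reliable = _chi2_2x2(dep, correction)
            p_others = []
            for s2 in classes:
                if s2 == s:
                    continue
                rest = [c for c in classes if c not in (s, s2)]
                k_s2 = float(mat.loc[s2, keyword])
                k_rest = float(mat.loc[rest, keyword].sum())
                n_s2 = float(row_tot[s2])
                n_rest = float(row_tot[rest].sum())
                other = np.array(
                    [[k_s2, n_s2 - k_s2], [k_rest, n_rest - k_rest]]
                )
                _, p_other, _ = _chi2_2x2(other, correction)
                p_others.append(p_other)
            rows.append(
                {
                    "keyword": keyword,
                    "class_id": s,
                    "freq": k_in,
                    "chi2": stat,
                    "p_dependence": p_dep,
                    "p_other_min": min(p_others) if p_others else np.nan,
                    "reliable": reliable,
                    "_p_others": p_others,
                }
            )
    out = pd.DataFrame(rows)
    if fdr:
        all_p = np.concatenate(
            [out["p_dependence"].to_numpy()] + [np.concatenate(out["_p_others"]) if len(out) else np.array([])]
        )
        adj = sstats.false_discovery_control(all_p, method="bh")
        n = len(out)
        out["p_dependence"] = adj[:n]
        flat = adj[n:]
        i = 0
        new_others = []
        for p_list in out["_p_others"]:
            new_others.append(list(flat[i : i + len(p_list)]))
            i += len(p_list)
        out["_p_others"] = new_others
        out["p_other_min"] = [min(p) if p else np.nan for p in new_others]
    out["associated"] = (
        (out["freq"] > 0)
        & (out["p_dependence"] < alpha)
        & (out["p_other_min"].fillna(1.0) >= alpha)
    )
    return out.drop(columns=["_p_others"])
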