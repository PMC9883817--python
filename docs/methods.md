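# Methods

This note documents the models, conventions and design choices behind
`stressquad`, in the order the pipeline runs them.

## Stress-mention extraction

A review "relates to stress" when it contains at least one phrase from a
closed stress-condition lexicon.  Matching is case-insensitive and respects
word boundaries (`overload` does not fire inside "overloaded").  Overlapping
candidates are resolved by a leftmost-longest rule: the scan proceeds left
to right, and at a shared start position the longest boundary-valid phrase
wins, so "extreme stress and pressure" yields *extreme stress* + *pressure*,
never the inner *stress*.  For overlaps that do not share a start (e.g.
"high stress levels", where *high stress* and *stress levels* cross), the
leftmost candidate wins — the standard lexer convention; it is deterministic
and identical to what a single combined regular expression with
length-ordered alternatives produces.

Two counting rules coexist deliberately: `stress_score` counts **posts**
(a review with three mentions contributes once), while the condition
frequency table counts **mentions**.  No negation or figurative-use handling
is attempted ("he was a pain to work with" would count if "pain" were in the
lexicon); this is a stated limitation of surface matching.  The bundled
lexicon has 15 conditions; it is a plain text file (one phrase per line,
`#` comments) and fully user-extensible.

## Quadrant placement and association

Per-company `mean_rating` and `stress_score` over window *T* are z-scored
against the cohort.  Conventions, each fixed once for reproducibility:

- **population σ** (divide by n): μ and σ are treated as cohort moments,
  not sample estimates (configurable via `ddof`);
- **half-open quadrants**: z = 0 counts as the nonnegative side.  The paper
  of record for this construction states signs only; z = 0 has measure zero
  and any deterministic rule works, so the simplest was chosen;
- **origin**: at R = 0 the angles are 0/0-undefined; f = 0 by convention
  (the origin is the point of weakest association);
- **silent companies**: companies with no reviews in *T* are excluded from
  the cohort moments and carry f = 0;
- **no minimum-review filter by default** (`min_reviews` available): review
  volume already enters through the temporal weights, and thresholds change
  cohort composition, so filtering is opt-in.

The association f = R/(γ+π) with γ = max(α−π/4, β−π/4) ∈ [0, π/4] ranges in
[4R/(5π), R/π]: linear in the radius for a fixed direction, maximal on the
quadrant diagonal, minimal on an axis.  The test suite checks these
properties and cross-validates f against an independent atan2-based
evaluation on 10,000 random points.

## Yearly indices

`m(s,y)` re-scores the cohort **within each year** (T = {y}): moments,
quadrant membership and f are yearly, so a company's type may legitimately
change from year to year — this is how a per-year membership condition in
the weight definition can be satisfied.  The weight denominator is the
cohort-wide post total for the year (not within-type), keeping the four
indices on a common scale; consequently m is invariant to uniformly scaling
a year's review volume.  Reviews are bucketed by calendar year of their
date.  The `dispersion` column is the population standard deviation across
companies of their contributions f·w within (s,y) — the natural spread
statistic for a shaded band around the index; the population whose spread is
reported is a documented choice.  A year whose cohort is degenerate (fewer
than two active companies, or zero dispersion on an axis, e.g. no stress
mention anywhere) is emitted with missing values and a warning rather than
aborting a multi-year run.

The external-series overlay reports per-type Pearson and Spearman
coefficients with n over overlapping years (≥ 3 required) and deliberately
attaches no significance model: temporal autocorrelation makes naive p
values misleading, and lagged/causal analysis is out of scope.

## Keyword scoring and association tests

Default document classes are the four stress types of the reviews'
companies; any external review→cluster assignment can be substituted, which
is the integration point for embedding/clustering pipelines.  Tokenisation
is lowercase alphanumeric words with slash-compounds kept whole
("vacation/sick"), optional stop words and bigrams.

The class-based TF-IDF is implemented in its linear form,
score = (k_l/o_l)·(p/q): k_l the keyword's frequency in class l, o_l the
class's total token count, p the total number of documents, q the keyword's
corpus-wide frequency.  Published variants of this statistic damp the
second factor with a logarithm; the linear form is the primary
implementation here and a log-damped variant
(k_l/o_l)·log(1+p/q) is available behind `log_variant=True`.  The linear
score is scale-free (duplicating the whole corpus changes nothing) and
class-exclusive keywords dominate spread ones at equal within-class
frequency.  Top-k keywords (k = 3 default) break ties lexicographically.

A keyword is declared *associated* with class s when (i) its frequency in s
is positive, (ii) a 2×2 chi-square test (keyword vs membership in s) is
significant at α, and (iii) for every other class s′, a 2×2 test restricted
to documents outside s (keyword vs membership in s′) is **not** significant.
Holding out s in step (iii) matters: a keyword concentrated in s is depleted
everywhere else, and testing the other classes against a pool that still
contains s would flag that depletion as dependence.  Yates correction is off
by default (the statistic is exactly Σ(O−E)²/E; configurable), no
multiple-testing correction is applied by default (Benjamini–Hochberg behind
`fdr=True`), and a test with any expected cell below 1 is flagged
unreliable.  Degenerate margins (all-zero row/column) are read as exact
independence.

## Stock growth

Growth is the ratio of yearly average adjusted closing prices between the
window ends (2009→2019 default; a 5-year 2014→2019 window is a flag away).
Daily price input is averaged per calendar year first.  Because growth
ratios are heavy-tailed, groups are summarised by the geometric mean, with
geometric standard error GSE = GM/√N · σ(log growth) using natural logs and
population σ (both conventions fixed once; the formula's source does not
specify them).  Within each stress type companies are ranked and cut into
equal-count bins — deciles by default, ties broken by stable company-id
order — on the association score f (default) or the raw stress score; the
phrase "stress score percentiles" is ambiguous between the two, so both are
exposed.  The pooled per-type row (`percentile_bin = "all"`) is the GM of
all that type's companies, not the mean of bin GMs.  Stratified summaries
(by sector, rating band, …) repeat the computation within externally
supplied strata, with unlabeled companies pooled under "unknown".

## Synthetic cohort generator

The generator emulates a review site's company cohort with the structure
the pipeline is meant to recover planted explicitly.  Defaults, chosen once
as realistic for a large public-company review corpus:

| parameter | default | rationale |
|---|---|---|
| companies per type | 50 | a few hundred companies, like a large stock index |
| years | 2008–2020 | a 13-year stream spanning a full analysis window |
| reviews per company-year | Poisson, mean 50 | large corpora run ~10⁵–10⁶ posts over ~500 companies and ~12 years |
| rating | Normal(4.2 or 2.8, 0.8), rounded, clamped to 1–5 | clearly separated high/low raters on a 1–5 scale |
| stress-post probability | 0.03 (stressed types) / 0.002 (others) | stress posts are ~1% of a real corpus; the planted contrast is an order of magnitude |
| growth | log-normal, log-mean ln 5.07 (positive stress) / ln 3.70 (others), log-sd 0.5 | log-normal ten-year growth with a planted positive-stress advantage |

Reviews are short filler-phrase concatenations; a stress post embeds one
lexicon phrase verbatim (case may vary, wording never does), so the
matcher's hit condition is unambiguous.  Review counts are Poisson, ratings
Normal-rounded-clamped — the simplest laws with controllable means, since
real per-company volume and rating distributions are idiosyncratic.  Stock
prices start log-normal around $50 in the anchor-start year and follow a
geometric path to the anchor-end price.  Ground-truth labels live in a
sidecar table that no pipeline stage reads.

What the generator does **not** emulate: realistic prose (so keyword
analyses on synthetic data exercise mechanics, not semantics), review-length
variation, reviewer identity, companies joining/leaving the site mid-window,
rating–text correlation beyond the archetype means, and market covariance
between companies.  Passing tests on synthetic data therefore demonstrate
correctness of the computations and recoverability of planted effects, not
validity of the stress construct on real reviews.

## Problem sizes and determinism

The end-to-end recovery check runs 4 × 50 companies (~130k reviews), sized
so planted-archetype recovery is statistically comfortable (≥ 95% with
margin) while the whole suite stays fast.  The brute-force index oracle uses
20 companies × 3 years.  Every stochastic component takes an explicit seed;
identical (config, seed) reproduce byte-identical artifacts, and stage
outputs carry a `# config_hash=… seed=…` header (the hash excludes the
output directory) so reruns are verifiable.

## Known limitations

- Surface-form matching cannot distinguish personal from figurative
  mentions, and inherits the lexicon's coverage.
- Quadrant typing is relative to the cohort: the same company can change
  type if the cohort changes. This is intrinsic to z-scoring, not a bug.
- The growth analysis is associational only; no causal claim connects
  stress type to performance, and no market-model adjustment is attempted.
- Chi-square verdicts treat keywords as the tested unit; topic-level
  testing would require an external clustering.
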