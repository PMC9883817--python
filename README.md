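# stressquad

Quantify workplace stress — including *positive* stress — from employee
review corpora, and relate it to long-term company performance.

Occupational-health research distinguishes *distress* (stress experienced as
draining) from *eustress* (stress experienced as an opportunity for growth).
Company review sites make both visible at scale: employees write free-text
reviews and leave a 1–5 star rating, and whether a company's reviews mention
stress a lot tells a different story depending on whether its ratings are
high or low.  `stressquad` operationalises this with a **stress-by-rating
quadrant**: companies are placed in a 2×2 space by the signs of two
z-scores, yielding four stress types, and each company's strength of
membership in its type is scored geometrically.  The package is aimed at
computational social scientists and digital-epidemiology researchers who
have (or simulate) a review corpus and want the whole analysis — extraction,
typing, temporal indices, keywords, stock growth — as tested, reusable code.

## The method

For each company *c* over a window *T* (default 2009–2019):

- `stress(c,T)` = fraction of *c*'s posts in *T* containing a phrase from a
  closed stress-condition lexicon (15 conditions bundled, e.g. *stress*,
  *high stress*, *pressure*, *burnout*; user-extensible);
- `rating(c,T)` = mean star rating in *T*.

Both are z-scored against the cohort (population σ).  The sign pair assigns
the stress type: high rating/low stress → **low stress**; low/low →
**passive**; low rating/high stress → **negative stress**; high/high →
**positive stress**.  The association of *c* with its type *s* is

```
f(c,s,T) = R / (γ + π),    R = √(z_rating² + z_stress²),
γ = max(α − π/4, β − π/4), α = arccos(|z_rating|/R), β = arccos(|z_stress|/R)
```

— largest for companies far from the origin and near their quadrant's
diagonal; 0 for companies with no reviews in *T*.  Three downstream analyses
build on *f*:

- **temporal**: yearly indices `m(s,y) = Σ_{c∈s} f(c,s,y)·w(c,y)` with
  post-volume weights `w = (c's posts in y) / (all posts in y)`, for
  tracking stress types against exogenous series such as unemployment;
- **topics**: class-based TF-IDF `(k_l/o_l)·(p/q)` keywords per stress
  type, with chi-square verdicts on keyword–quadrant association;
- **finance**: ten-year stock growth `stock_2019/stock_2009` summarised per
  type and association percentile by geometric mean GM and geometric
  standard error `GSE = GM/√N · σ(log growth)`.

A seeded synthetic-cohort generator plants all of this structure (archetype
rating means, stress-post probabilities, log-normal growth), so the entire
pipeline is testable offline; see `docs/methods.md` for the model details.

## Worked example

```python
from stressquad import synthetic_data as sd, extraction, quadrant, finance

cfg = sd.SyntheticCohortConfig(n_companies_per_type=50, seed=1)
reviews, truth = sd.generate_reviews(cfg)        # ~130k reviews, 200 companies
lx = extraction.StressLexicon.default()
stats = extraction.compute_company_period_stats(reviews, lx, (2009, 2019))
scores = quadrant.score_companies(stats)
print(scores.head(3).round(3).to_string(index=False))
```

```
company_id  n_posts  n_stress_posts  mean_rating  stress_score  z_rating  z_stress stress_type     R  gamma     f
     C0000      543               0        4.147           0.0     1.004    -1.054  low_stress 1.455  0.024 0.460
     C0001      572               0        4.157           0.0     1.018    -1.054  low_stress 1.466  0.017 0.464
     C0002      552               0        4.163           0.0     1.027    -1.054  low_stress 1.471  0.013 0.466
```

Company `C0000` rates well above the cohort mean (z ≈ +1.0) and mentions
stress less than average (z ≈ −1.1), so it lands in the low-stress quadrant,
close to that quadrant's diagonal (γ ≈ 0.02 rad) with association f ≈ 0.46.
Growth by recovered type:

```python
stocks = sd.generate_stocks(cfg, truth)
growth = finance.stock_growth(stocks, 2009, 2019)
summary = finance.growth_by_type_and_percentile(growth, scores)
print(summary[summary.percentile_bin == "all"].round(3).to_string(index=False))
```

```
    stress_type percentile_bin  N    gm   gse
     low_stress            all 51 3.841 0.220
        passive            all 50 3.615 0.248
negative_stress            all 50 4.092 0.281
positive_stress            all 49 4.683 0.320
```

The positive-stress group shows the highest geometric-mean growth (4.68×,
GSE 0.32, N = 49), consistent with the planted generator parameters
(exp log-mean 5.07× for positive stress vs 3.70× for the rest).  For a real
single company: a stock averaging \$61 in 2009 and \$485 in 2019 has growth
485/61 ≈ 7.95, i.e. it climbed about 695%.

The same pipeline is available from the shell:

```sh
stressquad simulate --out data --seed 1
stressquad extract --reviews data/reviews.csv --out stats.csv
stressquad score --stats stats.csv --out scores.csv
stressquad run-all --config pipeline.yaml      # everything, from a YAML config
```

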