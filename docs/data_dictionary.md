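# Data dictionary

All artifacts are comma-delimited UTF-8 with a header row; stage outputs
begin with `# config_hash=… seed=…` comment lines.

## Inputs

### reviews.csv
| column | type | meaning |
|---|---|---|
| company_id | string | opaque company identifier |
| date | ISO-8601 date | posting date of the review |
| rating | int 1–5 | overall star rating |
| text | string (quoted) | free-text review body |

### stocks.csv (yearly form)
| column | type | meaning |
|---|---|---|
| company_id | string | company identifier |
| year | int | calendar year |
| adj_close_avg | float > 0 | average of daily adjusted closing prices over the year |

Daily form accepted instead: `company_id, date, adj_close` (averaged per year).

### lexicon file
Plain text, one stress-condition phrase per line, `#` starts a comment.

### ground_truth.csv (synthetic only)
`company_id, stress_type` — planted archetype labels; never read by the pipeline.

## Stage outputs

### company_stats.csv
| column | meaning |
|---|---|
| company_id | company identifier |
| n_posts | reviews in the window T |
| n_stress_posts | reviews in T containing ≥1 lexicon phrase |
| mean_rating | arithmetic mean rating in T |
| stress_score | n_stress_posts / n_posts ∈ [0,1] |

### condition_frequency.csv
`phrase, n_mentions` — total resolved matches per lexicon phrase
(mentions, not posts), sorted descending.

### quadrant_scores.csv
| column | meaning |
|---|---|
| z_rating, z_stress | cohort z-scores (population σ) |
| stress_type | quadrant by sign pair (z = 0 → nonnegative side) |
| R | radius √(z_rating² + z_stress²) |
| gamma | angular distance from the quadrant diagonal, rad ∈ [0, π/4] |
| f | association R/(γ+π) ∈ [4R/(5π), R/π]; 0 at the origin |

### yearly_index.csv
| column | meaning |
|---|---|
| year, stress_type | index cell |
| m | Σ_{c∈s} f(c,s,y)·w(c,y); NaN for degenerate years |
| dispersion | population sd of the f·w contributions within (s,y) |
| n_companies | companies of type s active in y |

### keyword_scores.csv
| column | meaning |
|---|---|
| class_id, keyword | score cell |
| k_l | keyword frequency in the class |
| o_l | total token count of the class |
| p | total number of documents over all classes |
| q_sum | keyword frequency over all classes |
| score | (k_l/o_l)·(p/q_sum), or log-damped variant |

### top_keywords.csv
`class_id, rank, keyword, score` — k best keywords per class, ties alphabetical.

### keyword_associations.csv
| column | meaning |
|---|---|
| keyword, class_id | tested pair |
| freq | keyword count in the class |
| chi2, p_dependence | 2×2 test of keyword vs class membership |
| p_other_min | smallest p over the other-class tests (class held out) |
| reliable | False if an expected cell of the dependence test < 1 |
| associated | freq>0 ∧ p_dependence<α ∧ p_other_min≥α |

### stock_growth.csv
`company_id, growth` — end-year / start-year average price ratio.

### growth_summary.csv / growth_stratified.csv
| column | meaning |
|---|---|
| stratum | (stratified output only) external stratum label |
| stress_type | quadrant type |
| percentile_bin | `pLO-HI` equal-count bin on the binning variable, or `all` (pooled) |
| N | companies in the bin |
| gm | geometric mean of growth |
| gse | GM/√N · population sd of log growth; empty for N < 2 |

### company_summary.csv
quadrant_scores columns joined with `growth` per company.

### validation_report.csv
`reason, n_rows` — dropped-row counts (`rating_range`, `bad_date`,
`missing_value`) plus `n_kept`.
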