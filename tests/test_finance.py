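"""Stock growth ratios and geometric-mean summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from stressquad.finance import (
    geometric_mean,
    geometric_standard_error,
    growth_by_type_and_percentile,
    stock_growth,
    stratified_growth,
    yearly_average_prices,
)


def yearly_prices(records):
    return pd.DataFrame(records, columns=["company_id", "year", "adj_close_avg"])


class TestStockGrowth:
    def test_tenfold_window_ratio(self):
        prices = yearly_prices([("EQIX", 2009, 61.0), ("EQIX", 2019, 485.0)])
        growth = stock_growth(prices).set_index("company_id")["growth"]
        assert growth["EQIX"] == pytest.approx(485 / 61)
        assert growth["EQIX"] == pytest.approx(7.95, abs=0.005)

    def test_equal_prices_give_unit_growth(self):
        prices = yearly_prices([("A", 2009, 50.0), ("A", 2019, 50.0)])
        assert stock_growth(prices)["growth"].iloc[0] == pytest.approx(1.0)

    def test_missing_year_dropped_with_warning(self):
        prices = yearly_prices(
            [("A", 2009, 10.0), ("A", 2019, 20.0), ("B", 2009, 10.0)]
        )
        with pytest.warns(UserWarning, match="1 companies"):
            growth = stock_growth(prices)
        assert growth["company_id"].tolist() == ["A"]

    def test_nonpositive_price_is_an_error(self):
        prices = yearly_prices([("A", 2009, -1.0), ("A", 2019, 20.0)])
        with pytest.raises(ValueError, match="A"):
            stock_growth(prices)

    def test_daily_input_averaged_per_year(self):
        daily = pd.DataFrame(
            {
                "company_id": "A",
                "date": pd.date_range("2009-01-01", periods=250, freq="D").astype(str),
                "adj_close": 100.0,
            }
        )
        yearly = yearly_average_prices(daily)
        assert yearly.loc[yearly["year"] == 2009, "adj_close_avg"].iloc[0] == pytest.approx(100.0)

    def test_custom_window(self):
        prices = yearly_prices([("A", 2014, 10.0), ("A", 2019, 30.0)])
        growth = stock_growth(prices, start_year=2014, end_year=2019)
        assert growth["growth"].iloc[0] == pytest.approx(3.0)


class TestGeometricStatistics:
    def test_geometric_mean_examples(self):
        assert geometric_mean([2, 8]) == pytest.approx(4.0)
        assert geometric_mean([7.3]) == pytest.approx(7.3)

    def test_geometric_mean_homogeneity(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(0, 1, 50)
        for k in (0.5, 3.0):
            assert geometric_mean(k * values) == pytest.approx(k * geometric_mean(values))

    def test_geometric_mean_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            geometric_mean([1.0, 0.0])

    def test_gse_hand_example(self):
        # GM = 4, population sd of {ln 2, ln 8} = ln 2, N = 2
        assert geometric_standard_error([2, 8]) == pytest.approx(
            4 / math.sqrt(2) * math.log(2)
        )
        assert geometric_standard_error([2, 8]) == pytest.approx(1.9605, abs=1e-4)

    def test_gse_zero_when_values_equal(self):
        assert geometric_standard_error([3.3, 3.3, 3.3]) == pytest.approx(0.0)

    def test_gse_scales_linearly(self):
        rng = np.random.default_rng(4)
        values = rng.lognormal(0.2, 0.6, 30)
        assert geometric_standard_error(5 * values) == pytest.approx(
            5 * geometric_standard_error(values)
        )

    def test_gse_undefined_for_singleton(self):
        with pytest.warns(UserWarning):
            assert math.isnan(geometric_standard_error([2.0]))

    def test_gm_at_most_arithmetic_mean(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            values = rng.lognormal(0, 0.8, 25)
            assert geometric_mean(values) <= values.mean() + 1e-12
        assert geometric_mean([4, 4, 4]) == pytest.approx(np.mean([4, 4, 4]))

    def test_log_gm_unbiased_for_lognormal_growth(self):
        # over many replicates the log of the geometric mean estimates the
        # planted log-mean without bias
        rng = np.random.default_rng(8)
        mu, sigma, n, reps = math.log(4.0), 0.5, 20, 250
        estimates = [
            math.log(geometric_mean(rng.lognormal(mu, sigma, n))) for _ in range(reps)
        ]
        se = sigma / math.sqrt(n * reps)
        assert np.mean(estimates) == pytest.approx(mu, abs=4 * se)


def scored_cohort(rng, n_per_type=30):
    rows = []
    i = 0
    for stype, log_mu in [
        ("low_stress", math.log(3.7)), ("passive", math.log(3.7)),
        ("negative_stress", math.log(3.7)), ("positive_stress", math.log(5.07)),
    ]:
        for _ in range(n_per_type):
            rows.append(
                (f"C{i:03d}", stype, rng.uniform(0, 1.5), rng.lognormal(log_mu, 0.5))
            )
            i += 1
    df = pd.DataFrame(rows, columns=["company_id", "stress_type", "f", "growth"])
    return df[["company_id", "stress_type", "f"]], df[["company_id", "growth"]]


class TestGrowthSummaries:
    def test_single_bin_equals_pooled_gm(self):
        rng = np.random.default_rng(9)
        scores, growth = scored_cohort(rng)
        out = growth_by_type_and_percentile(growth, scores, n_bins=1)
        merged = growth.merge(scores, on="company_id")
        for stype, sub in merged.groupby("stress_type"):
            rows = out[out["stress_type"] == stype]
            assert len(rows) == 2  # the single bin plus the pooled row
            for gm in rows["gm"]:
                assert gm == pytest.approx(geometric_mean(sub["growth"]))

    def test_pooled_row_is_pooled_not_mean_of_bins(self):
        rng = np.random.default_rng(10)
        scores, growth = scored_cohort(rng, n_per_type=23)  # ragged bins
        out = growth_by_type_and_percentile(growth, scores, n_bins=10)
        merged = growth.merge(scores, on="company_id")
        for stype, sub in merged.groupby("stress_type"):
            pooled = out[(out["stress_type"] == stype) & (out["percentile_bin"] == "all")]
            assert pooled["gm"].iloc[0] == pytest.approx(geometric_mean(sub["growth"]))
            assert pooled["N"].iloc[0] == len(sub)

    def test_bins_are_equal_count(self):
        rng = np.random.default_rng(11)
        scores, growth = scored_cohort(rng, n_per_type=30)
        out = growth_by_type_and_percentile(growth, scores, n_bins=10)
        bins = out[out["percentile_bin"] != "all"]
        assert set(bins["N"]) == {3}

    def test_planted_type_effect_recovered(self):
        rng = np.random.default_rng(12)
        scores, growth = scored_cohort(rng, n_per_type=50)
        out = growth_by_type_and_percentile(growth, scores, n_bins=10)
        pooled = out[out["percentile_bin"] == "all"].set_index("stress_type")
        for stype, planted in [("positive_stress", 5.07), ("passive", 3.70)]:
            row = pooled.loc[stype]
            assert abs(row["gm"] - planted) < 3 * row["gse"]
        assert pooled["gm"].idxmax() == "positive_stress"

    def test_bin_on_stress_score(self):
        rng = np.random.default_rng(13)
        scores, growth = scored_cohort(rng)
        scores = scores.rename(columns={"f": "stress_score"})
        out = growth_by_type_and_percentile(growth, scores, bin_on="stress_score")
        assert not out.empty
        with pytest.raises(ValueError):
            growth_by_type_and_percentile(growth, scores, bin_on="f")


class TestStratified:
    def test_single_stratum_matches_unstratified(self):
        rng = np.random.default_rng(14)
        scores, growth = scored_cohort(rng)
        strata = pd.DataFrame({"company_id": scores["company_id"], "stratum": "tech"})
        plain = growth_by_type_and_percentile(growth, scores)
        strat = stratified_growth(growth, scores, strata)
        assert (strat["stratum"] == "tech").all()
        pd.testing.assert_frame_equal(
            strat.drop(columns="stratum"), plain, check_like=True
        )

    def test_disjoint_strata_partition_cohort(self):
        rng = np.random.default_rng(15)
        scores, growth = scored_cohort(rng)
        half = len(scores) // 2
        strata = pd.DataFrame(
            {
                "company_id": scores["company_id"],
                "stratum": ["a"] * half + ["b"] * (len(scores) - half),
            }
        )
        strat = stratified_growth(growth, scores, strata, n_bins=1)
        pooled = strat[strat["percentile_bin"] == "all"]
        assert pooled.groupby("stratum")["N"].sum().sum() == len(scores)

    def test_unlabeled_companies_fall_in_unknown(self):
        rng = np.random.default_rng(16)
        scores, growth = scored_cohort(rng)
        strata = pd.DataFrame({"company_id": scores["company_id"][:10], "stratum": "x"})
        strat = stratified_growth(growth, scores, strata, n_bins=1)
        assert "unknown" in set(strat["stratum"])

    def test_planted_advantage_detected_only_in_carrier_stratum(self):
        rng = np.random.default_rng(17)
        rows = []
        for i in range(60):
            stratum = "carrier" if i < 30 else "neutral"
            stype = "positive_stress" if i % 2 else "passive"
            mu = math.log(6.0) if (stratum == "carrier" and stype == "positive_stress") else math.log(3.0)
            rows.append((f"C{i:03d}", stype, rng.uniform(0, 1), rng.lognormal(mu, 0.2), stratum))
        df = pd.DataFrame(rows, columns=["company_id", "stress_type", "f", "growth", "stratum"])
        strat = stratified_growth(
            df[["company_id", "growth"]],
            df[["company_id", "stress_type", "f"]],
            df[["company_id", "stratum"]],
            n_bins=1,
        )
        pooled = strat[strat["percentile_bin"] == "all"].set_index(["stratum", "stress_type"])
        carrier_gap = pooled.loc[("carrier", "positive_stress"), "gm"] / pooled.loc[("carrier", "passive"), "gm"]
        neutral_gap = pooled.loc[("neutral", "positive_stress"), "gm"] / pooled.loc[("neutral", "passive"), "gm"]
        assert carrier_gap > 1.5 and abs(neutral_gap - 1.0) < 0.3
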