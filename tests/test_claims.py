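"""Pooling, frequency filtering, ranking and demographic summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nhsc import (
    apply_frequency_threshold,
    merge_insurer_tables,
    rank_and_cumulate,
    summarize_demographics,
)
from nhsc.claims import InsurerClaimsTable

from _oracles import merge_pooled_oracle
from conftest import make_claims_table


class TestMerge:
    def test_single_table_is_identity(self):
        t = make_claims_table("a", 1000, [("X10", 10, 1000.0), ("X11", 5, 2000.0)])
        pooled = merge_insurer_tables([t])
        assert pooled.pooled
        assert pooled.population == 1000
        merged = dict(zip(pooled.rows["icd3"], zip(pooled.rows["cases"], pooled.rows["mean_cost"])))
        assert merged == {"X10": (10, 1000.0), "X11": (5, 2000.0)}

    def test_case_weighted_mean_cost(self):
        a = make_claims_table("a", 1000, [("X10", 10, 1000.0)])
        b = make_claims_table("b", 1000, [("X10", 30, 2000.0)])
        pooled = merge_insurer_tables([a, b])
        assert pooled.rows.loc[0, "cases"] == 40
        assert pooled.rows.loc[0, "mean_cost"] == pytest.approx(1750.0)

    def test_order_invariance_and_conservation(self):
        tables = [
            make_claims_table("a", 500, [("X10", 10, 1200.0), ("X12", 7, 900.0)]),
            make_claims_table("b", 700, [("X10", 4, 800.0), ("X11", 9, 3000.0)]),
            make_claims_table("c", 300, [("X12", 1, 100.0)]),
        ]
        ref = merge_insurer_tables(tables)
        for perm in itertools.permutations(tables):
            p = merge_insurer_tables(list(perm))
            pd.testing.assert_frame_equal(p.rows, ref.rows)
        assert ref.total_cases == sum(t.total_cases for t in tables)
        # pooled mean within the span of contributing insurer means
        x10 = ref.rows.set_index("icd3").loc["X10", "mean_cost"]
        assert 800.0 <= x10 <= 1200.0

    def test_matches_expanded_per_case_oracle(self):
        rng = np.random.default_rng(7)
        codes = ["X10", "X11", "X12", "X13", "X14"]
        rows_flat = []
        tables = []
        for i in range(3):
            rows = [
                (c, int(rng.integers(0, 9)), float(rng.integers(5, 40) * 100))
                for c in codes
            ]
            rows = [r for r in rows if r[1] > 0]
            rows_flat.extend(rows)
            tables.append(make_claims_table(f"i{i}", 1000, rows))
        expected = merge_pooled_oracle(rows_flat)
        pooled = merge_insurer_tables(tables)
        got = {
            r.icd3: (r.cases, r.mean_cost) for r in pooled.rows.itertuples()
        }
        assert set(got) == set(expected)
        for code in expected:
            assert got[code][0] == expected[code][0]
            assert got[code][1] == pytest.approx(expected[code][1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            merge_insurer_tables([])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_claims_table("a", 100, [("X10", -1, 500.0)])


class TestFrequencyThreshold:
    def test_zero_threshold_keeps_every_nonempty_code(self):
        t = make_claims_table("a", 100, [("X10", 1, 10.0), ("X11", 0, 0.0)])
        assert apply_frequency_threshold(t, threshold=0.0) == {"X10"}

    def test_just_below_threshold_dropped(self):
        t = make_claims_table("a", 100_000, [("X10", 99, 10.0)])
        assert apply_frequency_threshold(t, threshold=0.001) == set()
        t2 = make_claims_table("a", 100_000, [("X10", 101, 10.0)])
        assert apply_frequency_threshold(t2, threshold=0.001) == {"X10"}

    def test_per_insurer_vs_pooled_scope(self):
        # X10 is common in the small insurer only; diluted after pooling
        small = make_claims_table("s", 1_000, [("X10", 5, 10.0), ("X11", 900, 10.0)])
        big = make_claims_table("b", 99_000, [("X10", 10, 10.0), ("X11", 500, 10.0)])
        per_insurer = apply_frequency_threshold([small, big], 0.001, scope="per_insurer")
        pooled = apply_frequency_threshold([small, big], 0.001, scope="pooled")
        # brute-force shares
        assert 5 / 1_000 > 0.001 and (5 + 10) / 100_000 < 0.001
        assert "X10" in per_insurer
        assert "X10" not in pooled
        assert "X11" in per_insurer and "X11" in pooled

    def test_invalid_threshold(self):
        t = make_claims_table("a", 10, [("X10", 1, 1.0)])
        with pytest.raises(ValueError):
            apply_frequency_threshold(t, threshold=1.5)


class TestRankAndCumulate:
    def test_single_code_normalizes_to_100(self):
        t = make_claims_table("a", 10, [("X10", 4, 100.0)])
        agg = rank_and_cumulate(t, {"X10"})
        assert agg.rows.loc[0, "pct_of_cases"] == pytest.approx(100.0)
        assert agg.rows.loc[0, "cum_pct"] == pytest.approx(100.0)
        assert agg.remainder_cases == 0

    def test_ties_break_lexicographically(self):
        t = make_claims_table("a", 10, [("X11", 3, 1.0), ("X10", 3, 1.0), ("X09", 5, 1.0)])
        agg = rank_and_cumulate(t, {"X09", "X10", "X11"})
        assert list(agg.rows["icd3"]) == ["X09", "X10", "X11"]

    def test_cum_pct_reaches_100_with_remainder(self):
        t = make_claims_table(
            "a", 100, [("X10", 50, 1.0), ("X11", 30, 2.0), ("X12", 20, 3.0)]
        )
        agg = rank_and_cumulate(t, {"X10", "X11"})
        assert agg.remainder_cases == 20
        assert np.all(np.diff(agg.rows["cum_pct"]) >= 0)
        total = agg.rows["cum_pct"].iloc[-1] + agg.remainder_cases / agg.total_cases * 100
        assert total == pytest.approx(100.0, abs=0.01)

    def test_zero_cases_rejected(self):
        t = make_claims_table("a", 10, [("X10", 0, 1.0)])
        with pytest.raises(ValueError, match="zero"):
            rank_and_cumulate(t, set())

    def test_study_table_rank1_and_cumulative_shares(self, diagnosis_table):
        rows = diagnosis_table.rows
        assert rows.loc[0, "icd3"] == "I50"
        assert round(rows.loc[0, "pct_of_cases"], 2) == 5.19
        assert rows.loc[8, "icd3"] == "I63"
        assert round(rows.loc[8, "cum_pct"], 2) == 30.15


class TestDemographics:
    def test_study_population_aged_65_plus(self, claims_table):
        rep = summarize_demographics(claims_table, total_hospitalizations=191_174)
        older = rep.strata[
            rep.strata["age_band"].isin(["65-69", "70-74", "75-79", "80-84", "85-89", ">=90"])
        ]
        assert int(older["residents"].sum()) == 206_503
        assert rep.strata["pct_of_total"].sum() == pytest.approx(100.0, abs=0.01)

    def test_study_ratio_and_incidence(self, claims_table):
        rep = summarize_demographics(claims_table, total_hospitalizations=191_174)
        total = rep.by_gender.set_index("gender").loc["total"]
        assert round(total["ratio"], 2) == 1.79
        assert round(total["incidence"], 2) == 0.79
        assert total["incidence"] == pytest.approx(total["proportion"] * total["ratio"])

    def test_no_hospitalized_persons_gives_null_ratio(self):
        t = InsurerClaimsTable(
            insurer_id="a",
            population=10,
            rows=pd.DataFrame([("X10", 0, 0.0)], columns=["icd3", "cases", "mean_cost"]),
            demographics=pd.DataFrame(
                [{"age_band": "80-84", "gender": "female", "residents": 10}]
            ),
            hospitalized_persons={"female": 0},
            hospitalizations={"female": 0},
        )
        rep = summarize_demographics(t)
        female = rep.by_gender.set_index("gender").loc["female"]
        assert female["proportion"] == 0
        assert np.isnan(female["ratio"])

    def test_inconsistent_counts_rejected(self):
        t = InsurerClaimsTable(
            insurer_id="a",
            population=10,
            rows=pd.DataFrame([("X10", 3, 1.0)], columns=["icd3", "cases", "mean_cost"]),
            demographics=pd.DataFrame(
                [{"age_band": "80-84", "gender": "female", "residents": 10}]
            ),
            hospitalized_persons={"female": 0},
            hospitalizations={"female": 3},
        )
        with pytest.raises(ValueError, match="without hospitalized"):
            summarize_demographics(t)
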