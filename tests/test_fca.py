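"""Two-step floating catchment area scoring and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dentaccess import (
    EuclideanTravelTimeProvider,
    accessibility_scores,
    build_catchments,
    classify_deficiency,
    provider_ratio_to_threshold,
    quartile_grouping,
    step1_supply_demand_ratios,
    step2_accessibility,
)
from dentaccess.fca import percentage

from conftest import random_instance


def frame_villages(rows):
    return pd.DataFrame(rows, columns=["village_id", "x", "y", "population",
                                       "township_id", "county_id"])


def frame_facilities(rows):
    return pd.DataFrame(rows, columns=["facility_id", "x", "y", "dentists"])


class TestCatchments:
    def test_single_pair_within_threshold(self):
        villages = frame_villages([("V0", 0.0, 0.0, 1000, "T0", "C0")])
        facilities = frame_facilities([("F0", 5000.0, 0.0, 1)])  # 5 min at 60 km/h
        provider = EuclideanTravelTimeProvider(villages, facilities)
        catch = build_catchments(facilities, villages, provider, t0=10)
        assert catch["F0"] == {"V0"}

    def test_boundary_is_closed(self):
        villages = frame_villages([("V0", 10_000.0, 0.0, 1000, "T0", "C0")])
        facilities = frame_facilities([("F0", 0.0, 0.0, 1)])  # exactly 10 min
        provider = EuclideanTravelTimeProvider(villages, facilities)
        catch = build_catchments(facilities, villages, provider, t0=10)
        assert catch["F0"] == {"V0"}

    def test_matches_brute_force_double_loop(self):
        villages, facilities, provider = random_instance(20, 3, seed=8)
        catch = build_catchments(facilities, villages, provider, t0=10)
        for f in facilities["facility_id"]:
            expected = {
                v for v in villages["village_id"] if provider.time(v, f) <= 10
            }
            assert catch[f] == expected

    def test_nonpositive_threshold_rejected(self):
        villages, facilities, provider = random_instance(3, 1, seed=0)
        with pytest.raises(ValueError, match="t0"):
            build_catchments(facilities, villages, provider, t0=0)


class TestStep1:
    def test_ratio_arithmetic(self):
        villages = frame_villages([("V0", 0, 0, 4000, "T0", "C0")])
        facilities = frame_facilities([("F0", 0, 0, 2)])
        ratios = step1_supply_demand_ratios({"F0": {"V0"}}, villages, facilities)
        assert ratios["F0"] == pytest.approx(0.0005)

    def test_empty_catchment_gets_zero_with_warning(self, caplog):
        villages = frame_villages([("V0", 0, 0, 100, "T0", "C0")])
        facilities = frame_facilities([("F0", 0, 0, 1)])
        with caplog.at_level("WARNING"):
            ratios = step1_supply_demand_ratios({"F0": set()}, villages, facilities)
        assert ratios["F0"] == 0.0
        assert "empty" in caplog.text

    def test_five_facility_enumeration(self):
        villages, facilities, provider = random_instance(12, 5, seed=3)
        catch = build_catchments(facilities, villages, provider, t0=10)
        ratios = step1_supply_demand_ratios(catch, villages, facilities)
        pop = villages.set_index("village_id")["population"]
        sup = facilities.set_index("facility_id")["dentists"]
        for f in facilities["facility_id"]:
            demand = sum(pop[v] for v in catch[f])
            expected = sup[f] / demand if demand else 0.0
            assert ratios[f] == pytest.approx(expected, rel=1e-12)


class TestStep2:
    def test_single_pair_identity(self):
        villages = frame_villages([("V0", 0, 0, 2000, "T0", "C0")])
        facilities = frame_facilities([("F0", 1000.0, 0, 1)])
        provider = EuclideanTravelTimeProvider(villages, facilities)
        table = accessibility_scores(villages, facilities, provider, t0=10)
        # one dentist per 2000 people: 0.0005 service trips per person-year
        assert table["R"].iloc[0] == pytest.approx(0.0005)

    def test_matches_brute_force_double_loop(self):
        villages, facilities, provider = random_instance(30, 5, seed=5)
        table = accessibility_scores(villages, facilities, provider, t0=10)
        catch = build_catchments(facilities, villages, provider, t0=10)
        ratios = step1_supply_demand_ratios(catch, villages, facilities)
        for _, row in table.iterrows():
            expected = sum(
                ratios[f]
                for f in facilities["facility_id"]
                if provider.time(row["village_id"], f) <= 10
            )
            assert row["R"] == pytest.approx(expected, rel=1e-12)

    def test_unreachable_village_scores_zero(self):
        villages = frame_villages(
            [("V0", 0, 0, 100, "T0", "C0"), ("V1", 500_000.0, 0, 100, "T1", "C0")]
        )
        facilities = frame_facilities([("F0", 0, 0, 1)])
        provider = EuclideanTravelTimeProvider(villages, facilities)
        table = accessibility_scores(villages, facilities, provider, t0=10)
        assert table.set_index("village_id").loc["V1", "R"] == 0.0


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_of_supply(self, seed):
        # symmetric times, every facility reaches someone: total population-
        # weighted accessibility equals total dentist supply
        villages, facilities, provider = random_instance(40, 8, seed, box_km=15)
        table = accessibility_scores(villages, facilities, provider, t0=10)
        catch = build_catchments(facilities, villages, provider, t0=10)
        if any(len(c) == 0 for c in catch.values()):
            pytest.skip("random instance produced an empty catchment")
        lhs = float(table["R"].to_numpy() @ villages["population"].to_numpy())
        rhs = float(facilities["dentists"].sum())
        assert abs(lhs - rhs) / rhs < 1e-9

    def test_accessibility_nondecreasing_in_threshold(self):
        villages, facilities, provider = random_instance(25, 6, seed=2)
        catch = build_catchments(facilities, villages, provider, t0=8)
        ratios = step1_supply_demand_ratios(catch, villages, facilities)
        a8 = step2_accessibility(villages, facilities, provider, 8, ratios)
        a12 = step2_accessibility(villages, facilities, provider, 12, ratios)
        assert (a12["R"].to_numpy() >= a8["R"].to_numpy() - 1e-15).all()

    @given(scale=st.floats(min_value=0.25, max_value=4.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, scale):
        villages, facilities, provider = random_instance(15, 4, seed=11)
        base = accessibility_scores(villages, facilities, provider, t0=10)
        sup = facilities.assign(dentists=facilities["dentists"] * scale)
        up = accessibility_scores(villages, sup, provider, t0=10)
        np.testing.assert_allclose(up["R"], base["R"] * scale, rtol=1e-12)
        dem = villages.assign(population=villages["population"] * 2)
        half = accessibility_scores(dem, facilities, provider, t0=10)
        np.testing.assert_allclose(half["R"], base["R"] / 2, rtol=1e-12)

    def test_row_order_permutation_invariance(self):
        villages, facilities, provider = random_instance(18, 5, seed=13)
        base = accessibility_scores(villages, facilities, provider, t0=10)
        rng = np.random.default_rng(0)
        vperm = villages.sample(frac=1, random_state=1).reset_index(drop=True)
        fperm = facilities.sample(frac=1, random_state=2).reset_index(drop=True)
        shuffled = accessibility_scores(vperm, fperm, provider, t0=10)
        merged = base.merge(shuffled, on="village_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["R_a"], merged["R_b"], rtol=1e-12)


class TestThresholds:
    @pytest.mark.parametrize(
        "persons, expected", [(2000, 0.0005), (4000, 0.00025), (1, 1.0)]
    )
    def test_provider_ratio_conversion(self, persons, expected):
        assert provider_ratio_to_threshold(persons) == expected

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            provider_ratio_to_threshold(0)


class TestDeficiency:
    def test_township_flagged_between_thresholds(self):
        villages = frame_villages([("V0", 0, 0, 1000, "T0", "C0")])
        table = pd.DataFrame({"village_id": ["V0"], "R": [0.0003]})
        agg, summary = classify_deficiency(table, villages)
        row = agg.iloc[0]
        assert bool(row["deficient_0.0005"]) is True
        assert bool(row["deficient_0.00025"]) is False

    def test_weighted_mean_aggregation(self):
        villages = frame_villages(
            [("V0", 0, 0, 1000, "T0", "C0"), ("V1", 0, 0, 3000, "T0", "C0")]
        )
        table = pd.DataFrame({"village_id": ["V0", "V1"], "R": [0.004, 0.0]})
        agg, _ = classify_deficiency(table, villages)
        assert agg["R_township"].iloc[0] == pytest.approx(0.001)

    def test_all_zero_scores_fully_deficient(self):
        villages, _, _ = random_instance(10, 2, seed=4)
        table = pd.DataFrame({"village_id": villages["village_id"], "R": 0.0})
        _, summary = classify_deficiency(table, villages)
        assert (summary["pct_deficient"] == 100.0).all()

    def test_printed_share_arithmetic(self):
        # 16 deficient of 352 townships reports as 4.5%
        assert percentage(16, 352, decimals=1) == 4.5


class TestQuartiles:
    def test_zero_group_plus_one_per_quartile(self):
        table = pd.DataFrame(
            {"village_id": list("abcde"), "R": [0.0, 1.0, 2.0, 3.0, 4.0]}
        )
        out = quartile_grouping(table)
        groups = out.set_index("village_id")["quartile_group"]
        assert groups["a"] == "zero"
        assert list(groups[list("bcde")]) == ["Q1", "Q2", "Q3", "Q4"]

    def test_degenerate_ties_fall_back_to_stable_order(self, caplog):
        table = pd.DataFrame(
            {"village_id": [f"v{i}" for i in range(8)], "R": [0.5] * 8}
        )
        with caplog.at_level("WARNING"):
            out = quartile_grouping(table)
        counts = out["quartile_group"].value_counts()
        assert set(counts.index) == {"Q1", "Q2", "Q3", "Q4"}
        assert counts.max() - counts.min() <= 1
        assert "degenerate" in caplog.text

    def test_too_few_positive_scores_rejected(self):
        table = pd.DataFrame({"village_id": list("abc"), "R": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 4"):
            quartile_grouping(table)

    def test_thousand_villages_match_quantile_oracle(self):
        rng = np.random.default_rng(21)
        r = np.concatenate([np.zeros(50), rng.lognormal(-4, 1, 950)])
        table = pd.DataFrame(
            {"village_id": [f"v{i}" for i in range(1000)], "R": r}
        )
        out = quartile_grouping(table)
        pos = np.sort(r[r > 0])
        cuts = np.quantile(pos, [0.25, 0.5, 0.75])
        for _, row in out.iterrows():
            if row["R"] == 0:
                assert row["quartile_group"] == "zero"
            elif row["R"] <= cuts[0]:
                assert row["quartile_group"] == "Q1"
            elif row["R"] <= cuts[1]:
                assert row["quartile_group"] == "Q2"
            elif row["R"] <= cuts[2]:
                assert row["quartile_group"] == "Q3"
            else:
                assert row["quartile_group"] == "Q4"
        sizes = out[out["quartile_group"] != "zero"]["quartile_group"].value_counts()
        assert sizes.max() - sizes.min() <= 5  # tie slack only
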