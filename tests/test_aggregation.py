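"""Three-step aggregation: frozen hand-computed values and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import soilscore as ss
from soilscore import (
    AggregationConfig,
    ConfigurationError,
    InputError,
    aggregate_categories,
    aggregate_within_category,
    aggregate_years,
    weight_category,
    weight_distance_to_target,
)
from soilscore.aggregation import CategoryScore
from soilscore.advisory import apply_vsa
from soilscore.types import Category

from conftest import make_record

unit = st.floats(0.0, 1.0)


class TestDistanceToTargetWeight:
    def test_hand_values(self):
        assert weight_distance_to_target(0.2, 0.2) == pytest.approx(2.5)
        assert weight_distance_to_target(1.0, 0.2) == pytest.approx(1 / 1.2)

    @given(c=st.floats(0.01, 5.0))
    def test_strictly_decreasing(self, c):
        assert (
            weight_distance_to_target(0.0, c)
            > weight_distance_to_target(0.5, c)
            > weight_distance_to_target(1.0, c)
        )

    @pytest.mark.parametrize("c", [0.0, -0.2])
    def test_nonpositive_offset_rejected(self, c):
        with pytest.raises(ConfigurationError):
            weight_distance_to_target(0.5, c)


class TestWithinCategory:
    def test_frozen_two_value_example(self):
        # (2.5*0.2 + (1/1.2)*1.0) / (2.5 + 1/1.2) = 0.4 exactly
        assert aggregate_within_category([0.2, 1.0]) == pytest.approx(0.4, abs=1e-12)

    @given(v=unit, n=st.integers(1, 6))
    def test_idempotence(self, v, n):
        assert aggregate_within_category([v] * n) == pytest.approx(v, abs=1e-12)

    def test_missing_excluded_and_all_missing_is_none(self):
        assert aggregate_within_category([None, 0.2, None, 1.0]) == pytest.approx(0.4)
        assert aggregate_within_category([None, None]) is None

    def test_limiting_factor_pulls_below_mean(self, rng):
        """Step-1 aggregate <= arithmetic mean, equality iff constant."""
        for _ in range(1000):
            vals = rng.uniform(0, 1, size=rng.integers(2, 9)).tolist()
            agg = aggregate_within_category(vals)
            mean = float(np.mean(vals))
            assert agg <= mean + 1e-12
            if max(vals) - min(vals) > 1e-9:
                assert agg < mean


class TestAcrossYears:
    def test_frozen_recent_old_example(self):
        # 5 recent years at 1.0 (w=1.0) + 5 old at 0.0 (w=0.5) -> 5/7.5
        scores = {age: (1.0 if age < 5 else 0.0) for age in range(10)}
        assert aggregate_years(scores) == pytest.approx(2 / 3, abs=1e-12)

    @given(v=unit)
    def test_constant_and_single_year(self, v):
        assert aggregate_years({a: v for a in range(10)}) == pytest.approx(v, abs=1e-12)
        assert aggregate_years({3: v}) == pytest.approx(v, abs=1e-12)

    def test_missing_years_renormalize(self):
        """Dropping missing years = aggregating only the present ones."""
        with_missing = aggregate_years({0: 0.8, 3: None, 7: 0.4})
        present_only = aggregate_years({0: 0.8, 7: 0.4})
        assert with_missing == present_only
        assert aggregate_years({}) is None


class TestCategoryWeight:
    def test_values(self):
        assert weight_category(1) == pytest.approx(1.0)
        assert weight_category(0) == 0.0
        assert weight_category(9) == pytest.approx(math.log2(10))

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            weight_category(-1)


class TestAcrossCategories:
    def test_frozen_four_category_example(self):
        scores = {
            Category.CHEMICAL: CategoryScore(0.8, 9),
            Category.PHYSICAL: CategoryScore(0.6, 8),
            Category.BIOLOGICAL: CategoryScore(0.9, 2),
            Category.ENVIRONMENTAL: CategoryScore(0.7, 2),
            Category.MANAGEMENT: CategoryScore(0.9, 1),
        }
        cfg = AggregationConfig(include_management=False)
        w = [math.log2(n + 1) for n in (9, 8, 2, 2)]
        expected = sum(
            wi * s for wi, s in zip(w, (0.8, 0.6, 0.9, 0.7))
        ) / sum(w)
        got = aggregate_categories(scores, cfg)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.7344, abs=5e-5)

    @given(v=unit)
    def test_all_equal_gives_v(self, v):
        scores = {
            cat: CategoryScore(v, n)
            for cat, n in zip(Category, (9, 8, 2, 2, 1))
        }
        assert aggregate_categories(scores) == pytest.approx(v, abs=1e-12)

    def test_bounded_by_inputs(self, rng):
        for _ in range(500):
            vals = rng.uniform(0, 1, 5)
            ns = rng.integers(1, 10, 5)
            scores = {
                cat: CategoryScore(float(v), int(n))
                for cat, v, n in zip(Category, vals, ns)
            }
            final = aggregate_categories(scores)
            assert vals.min() - 1e-12 <= final <= vals.max() + 1e-12

    def test_empty_category_excluded_and_no_categories_errors(self):
        scores = {
            Category.CHEMICAL: CategoryScore(0.8, 2),
            Category.PHYSICAL: CategoryScore(None, 0),
        }
        assert aggregate_categories(scores) == pytest.approx(0.8)
        with pytest.raises(InputError):
            aggregate_categories({Category.PHYSICAL: CategoryScore(None, 0)})


def manual_score(records, battery, cfg):
    """Independent step-by-step composition of the three aggregation
    operations, used as the oracle for score_field."""
    vectors = {
        r.year_age: apply_vsa(ss.evaluate_battery(battery, r), r.vsa)
        for r in records
    }
    per_year = {
        age: {
            cat: aggregate_within_category(
                [iv.value for iv in vec.values() if iv.category is cat], cfg
            )
            for cat in Category
        }
        for age, vec in vectors.items()
    }
    subs = {}
    for cat in Category:
        sub = aggregate_years({a: c[cat] for a, c in per_year.items()}, cfg)
        n = len({
            fid
            for vec in vectors.values()
            for fid, iv in vec.items()
            if iv.category is cat and iv.value is not None
        })
        subs[cat] = CategoryScore(sub, n)
    return aggregate_categories(subs, cfg)


class TestScoreField:
    def test_agronomically_optimal_profile_hits_curve_optima(self, battery):
        # every measured property at/past its sand-arable agronomic
        # optimum; the groundwater lookups keep their drought/wetness
        # trade-off and the environmental curves penalize the high
        # nutrient status -- those are real trade-offs, not defects
        rec = make_record(
            ph=5.8, n_total=2500, p_avail=60, k_avail=200, mg_avail=150,
            cu_avail=5, s_avail=30, zn_avail=8, cec=160, organic_matter=9,
            clay=13, silt=15, sand=72, pmn=120, bulk_density=1.15,
            management=1.0, gw=ss.GroundwaterClass.IV,
        )
        vec = ss.evaluate_battery(battery, rec)
        skip = {"i_p_droughtstress", "i_p_wetnessstress", "i_e_ngw", "i_e_nsw"}
        for fid, iv in vec.items():
            if fid not in skip:
                assert iv.value == 1.0, fid
        assert vec["i_e_ngw"].value < 1.0  # nutrient-status trade-off

    def test_all_indicators_one_gives_final_one(self):
        """A 10-year field whose battery evaluates to 1.0 everywhere
        scores exactly 1.0, class good."""
        curve = {"kind": "two_anchor_increasing", "x_zero": -2, "x_half": -1, "x_opt": 0}
        mk = lambda fid, cat, prop: {
            "function_id": fid, "category": cat,
            "required_properties": [prop], "curves": {"*:*": dict(curve)},
        }
        battery = ss.load_battery({"battery": [
            mk("c1", "chemical", "n_total"), mk("c2", "chemical", "p_avail"),
            mk("p1", "physical", "clay"), mk("p2", "physical", "silt"),
            mk("b1", "biological", "pmn"), mk("b2", "biological", "organic_matter"),
        ]})
        recs = [make_record(year_age=a) for a in range(10)]
        report = ss.score_field(recs, battery)
        assert report.final_score == 1.0
        assert report.score_class is ss.ScoreClass.GOOD

    def test_matches_manual_step_composition(self, battery):
        """score_field equals the hand-chained three aggregation steps."""
        recs = [make_record(year_age=a) for a in range(10)]
        report = ss.score_field(recs, battery)
        assert report.final_score == manual_score(recs, battery, AggregationConfig())

    def test_single_year_step2_is_identity(self, battery, complete_record):
        report = ss.score_field([complete_record], battery)
        for cat in Category:
            assert (
                report.category_scores[cat].score
                == report.per_year[0][cat].score
            )

    def test_final_bounded_by_subscores(self, battery):
        recs = [make_record(year_age=a) for a in range(5)]
        report = ss.score_field(recs, battery)
        subs = [
            cs.score for cs in report.category_scores.values()
            if cs.score is not None
        ]
        assert min(subs) <= report.final_score <= max(subs)

    def test_inconsistent_field_ids_rejected(self, battery):
        recs = [make_record("a", 0), make_record("b", 1)]
        with pytest.raises(InputError, match="multiple field_ids"):
            ss.score_field(recs, battery)

    def test_management_excluded_when_configured(self, battery):
        recs = [make_record(year_age=a, management=0.0) for a in range(3)]
        with_mgmt = ss.score_field(recs, battery)
        without = ss.score_field(
            recs, battery, AggregationConfig(include_management=False)
        )
        assert without.final_score > with_mgmt.final_score
        assert "management" not in without.weights["category_weights"]

    def test_monotone_in_any_single_indicator(self, rng):
        """Increasing one indicator never decreases any sub-score or the
        final score (tested on the aggregation layer directly)."""
        cfg = AggregationConfig()
        for _ in range(300):
            ns = rng.integers(1, 6, size=5)
            years = rng.integers(1, 4)
            data = {
                age: {
                    cat: rng.uniform(0, 1, n).tolist()
                    for cat, n in zip(Category, ns)
                }
                for age in range(years)
            }

            def final(d):
                subs = {}
                for i, cat in enumerate(Category):
                    by_age = {
                        a: aggregate_within_category(d[a][cat], cfg) for a in d
                    }
                    subs[cat] = CategoryScore(
                        aggregate_years(by_age, cfg), int(ns[i])
                    )
                return aggregate_categories(subs, cfg)

            base = final(data)
            age = int(rng.integers(0, years))
            cat = Category(list(Category)[rng.integers(0, 5)])
            idx = int(rng.integers(0, len(data[age][cat])))
            bumped = {
                a: {c: list(v) for c, v in cats.items()}
                for a, cats in data.items()
            }
            old = bumped[age][cat][idx]
            bumped[age][cat][idx] = min(1.0, old + float(rng.uniform(0, 1 - old + 1e-9)))
            assert final(bumped) >= base - 1e-12
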