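import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoassay.assay_scoring import (
    ClassificationThresholds,
    InsufficientDataError,
    LeafCategoryCounts,
    MatureLeafSection,
    PathClass,
    TimeCourse,
    UnscoreableObservationError,
    classify_mature,
    classify_seedling,
    count_above_threshold,
    growth_rate,
    mean_lesion_score,
    read_seedling_table,
    score_mature_table,
    score_seedling_table,
    seedling_regression,
    standardized_di_10day,
    weighted_disease_index,
    IsolateAssayResult,
)


def make_tc(days, dis, total=10):
    """Time course whose weighted index equals each requested DI exactly."""
    obs = []
    for day, di in zip(days, dis):
        lo = min(int(np.floor(di)), 4)
        n_hi = 0 if lo == 4 else int(round((di - lo) * total))
        counts = [0] * 5
        counts[lo] = total - n_hi
        if lo < 4:
            counts[lo + 1] = n_hi
        obs.append((day, LeafCategoryCounts(*counts)))
    return TimeCourse("tc", tuple(obs))


class TestWeightedDiseaseIndex:
    def test_all_healthy(self):
        assert weighted_disease_index(LeafCategoryCounts(5, 0, 0, 0, 0)) == 0.0

    def test_all_dead(self):
        assert weighted_disease_index(LeafCategoryCounts(0, 0, 0, 0, 3)) == 4.0

    def test_hand_formula(self):
        # (0 + 1 + 2) / 4
        assert weighted_disease_index(LeafCategoryCounts(2, 1, 1, 0, 0)) == 0.75

    def test_zero_total_is_explicit_error(self):
        with pytest.raises(UnscoreableObservationError):
            weighted_disease_index(LeafCategoryCounts(0, 0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            LeafCategoryCounts(-1, 0, 0, 0, 0)

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=5, max_size=5).filter(
            lambda c: sum(c) >= 1
        ),
        st.integers(min_value=1, max_value=9),
    )
    def test_scale_invariance_and_bounds(self, counts, k):
        di = weighted_disease_index(LeafCategoryCounts(*counts))
        scaled = weighted_disease_index(LeafCategoryCounts(*(k * c for c in counts)))
        assert 0.0 <= di <= 4.0
        assert scaled == pytest.approx(di)

    @pytest.mark.parametrize("k", range(5))
    def test_pure_category(self, k):
        counts = [0] * 5
        counts[k] = 7
        assert weighted_disease_index(LeafCategoryCounts(*counts)) == float(k)


class TestStandardizedDI:
    def test_points_on_line_through_origin(self):
        tc = make_tc([3, 6, 9], [0.6, 1.2, 1.8])  # DI = 0.2 * day
        assert standardized_di_10day(tc) == pytest.approx(2.0)

    def test_late_day_excluded_oracle(self):
        # day 18 dropped; b = (4*1.0 + 8*1.6 + 12*2.8) / (16 + 64 + 144)
        tc = make_tc([4, 8, 12, 18], [1.0, 1.6, 2.8, 3.9])
        assert standardized_di_10day(tc) == pytest.approx(10 * 50.4 / 224)

    def test_death_rule_and_clipping(self):
        tc = make_tc([2, 4, 6, 8], [4.0, 4.0, 4.0, 4.0])
        # first two dead observations only: b = (2*4 + 4*4) / (4 + 16) = 1.2
        assert standardized_di_10day(tc) == pytest.approx(4.0)
        assert standardized_di_10day(tc, clip=False) == pytest.approx(12.0)

    def test_day_16_retained(self, thresholds):
        tc = make_tc([8, 16], [1.6, 3.2])  # DI = 0.2 * day
        fit = seedling_regression(tc, thresholds)
        assert fit.n_used == 2
        assert fit.standardized == pytest.approx(2.0)

    def test_all_excluded_errors(self):
        tc = make_tc([17, 18], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            standardized_di_10day(tc)

    def test_all_days_zero_errors(self):
        tc = make_tc([0], [1.0])
        with pytest.raises(InsufficientDataError):
            standardized_di_10day(tc)

    def test_exclusion_idempotent(self):
        """Re-scoring already-filtered data gives the same answer."""
        tc = make_tc([2, 4, 6, 8, 18], [4.0, 4.0, 4.0, 4.0, 2.0])
        filtered = make_tc([2, 4], [4.0, 4.0])
        assert standardized_di_10day(tc) == standardized_di_10day(filtered)

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=16),
                st.floats(min_value=0.0, max_value=3.9),
            ),
            min_size=1,
            max_size=6,
            unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=200)
    def test_matches_normal_equation_oracle(self, points):
        points = sorted(points)
        days = [p[0] for p in points]
        dis = [round(p[1] * 10) / 10 for p in points]
        tc = make_tc(days, dis)
        actual_dis = [4.0 if d == 4.0 else d for d in dis]
        beta = sum(d * v for d, v in zip(days, actual_dis)) / sum(d * d for d in days)
        expected = min(4.0, max(0.0, 10 * beta))
        assert standardized_di_10day(tc) == pytest.approx(expected, abs=1e-9)


class TestGrowthRate:
    def test_on_line(self):
        obs = tuple(
            (d, LeafCategoryCounts(int(0.5 * d), 0, 0, 0, 0)) for d in (2, 4, 6)
        )
        tc = TimeCourse("g", obs)
        assert growth_rate(tc) == pytest.approx(0.5)

    def test_constant_leaf_count_oracle(self):
        obs = ((5, LeafCategoryCounts(4, 0, 0, 0, 0)), (10, LeafCategoryCounts(4, 0, 0, 0, 0)))
        tc = TimeCourse("g", obs)
        # (5*4 + 10*4) / (25 + 100) = 0.48
        assert growth_rate(tc) == pytest.approx(0.48)

    def test_ols_alternative_recovers_intercept_model(self):
        obs = tuple((d, LeafCategoryCounts(2 + d, 0, 0, 0, 0)) for d in (2, 4, 6, 8))
        tc = TimeCourse("g", obs)
        assert growth_rate(tc, through_origin=False) == pytest.approx(1.0)

    def test_empty_after_exclusions(self):
        obs = ((17, LeafCategoryCounts(3, 0, 0, 0, 0)),)
        with pytest.raises(InsufficientDataError):
            growth_rate(TimeCourse("g", obs))


class TestMeanLesionScore:
    @pytest.mark.parametrize(
        "scores,expected", [([0, 0, 0], 0.0), ([1, 1, 1], 1.0), ([0, 0.5, 1, 0.5], 0.5)]
    )
    def test_values(self, scores, expected):
        assert mean_lesion_score(scores) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mean_lesion_score([])

    def test_replicate_count_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            mean_lesion_score([0, 1])
        assert "expected 3-7" in caplog.text

    def test_accepts_section_objects(self):
        sections = [MatureLeafSection("i", "australis", True, s) for s in (0, 0.5, 1)]
        assert mean_lesion_score(sections) == pytest.approx(0.5)

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError):
            mean_lesion_score([0.25, 0.5, 1])


class TestClassification:
    @pytest.mark.parametrize(
        "di,expected",
        [
            (6.6, PathClass.STRONG_PATHOGEN),
            (0.0, PathClass.NONPATHOGEN),
            (2.2, PathClass.PATHOGEN),
            (4.1, PathClass.STRONG_PATHOGEN),
            (2.0, PathClass.PATHOGEN),
            (1.95, PathClass.PATHOGEN),  # rounds half-up to 2.0
            (0.1, PathClass.WEAK_PATHOGEN),
            (0.03, PathClass.NONPATHOGEN),
            (0.04, PathClass.NONPATHOGEN),  # rounds to 0.0
        ],
    )
    def test_seedling(self, di, expected):
        assert classify_seedling(di) is expected

    def test_seedling_negative_errors(self):
        with pytest.raises(ValueError):
            classify_seedling(-0.1)

    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.05, PathClass.NONPATHOGEN),
            (1.0, PathClass.STRONG_PATHOGEN),
            (0.2, PathClass.WEAK_PATHOGEN),  # lower bound is inclusive
            (0.5, PathClass.PATHOGEN),
            (0.8, PathClass.STRONG_PATHOGEN),
            (0.19, PathClass.NONPATHOGEN),
        ],
    )
    def test_mature(self, score, expected):
        assert classify_mature(score) is expected

    def test_mature_out_of_range(self):
        with pytest.raises(ValueError):
            classify_mature(1.1)
        with pytest.raises(ValueError):
            classify_mature(-0.01)

    @given(st.floats(min_value=0, max_value=8), st.floats(min_value=0, max_value=8))
    def test_seedling_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert classify_seedling(lo) <= classify_seedling(hi)

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_mature_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert classify_mature(lo) <= classify_mature(hi)

    def test_threshold_invariants_enforced(self):
        with pytest.raises(ValueError):
            ClassificationThresholds(seedling_pathogen_min=5.0)
        with pytest.raises(ValueError):
            ClassificationThresholds(mature_weak_min=0.9)


class TestCountAboveThreshold:
    def results(self, values, lineage="australis"):
        return [
            IsolateAssayResult(isolate_id=f"i{k}", lineage=lineage, standardized_di_10day=v)
            for k, v in enumerate(values)
        ]

    def test_empty(self):
        assert count_above_threshold([], 2.0) == 0

    def test_zero_threshold_counts_all(self):
        res = self.results([0.0, 1.0, 3.0])
        assert count_above_threshold(res, 0.0) == 3

    def test_lineage_filter(self):
        res = self.results([3.0], "australis") + self.results([3.0], "americanus")
        assert count_above_threshold(res, 2.0, lineage="australis") == 1
        assert count_above_threshold(res, 2.0) == 2


class TestTables:
    def make_table(self):
        rows = []
        for rep in (1, 2):
            for day in (2, 4, 6):
                # DI = 0.3 * day exactly with 10 leaves
                di = 0.3 * day
                lo = int(di)
                hi = int(round((di - lo) * 10))
                counts = [0] * 5
                counts[lo], counts[lo + 1] = 10 - hi, hi
                rows.append(
                    dict(
                        isolate_id="A", lineage="australis", replicate=rep, day=day,
                        n0=counts[0], n1=counts[1], n2=counts[2], n3=counts[3], n4=counts[4],
                    )
                )
        return pd.DataFrame(rows)

    def test_read_groups_replicates(self):
        courses = read_seedling_table(self.make_table())
        assert len(courses) == 2
        assert all(len(tc.observations) == 3 for tc in courses)

    def test_score_seedling_table(self):
        scored = score_seedling_table(self.make_table())
        assert len(scored) == 1
        assert scored.loc[0, "standardized_di"] == pytest.approx(3.0)
        assert scored.loc[0, "class"] == "Pathogen"
        assert scored.loc[0, "n_replicates"] == 2

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            read_seedling_table(pd.DataFrame({"isolate_id": ["x"]}))

    def test_score_mature_table(self):
        df = pd.DataFrame(
            {
                "isolate_id": ["A"] * 4 + ["B"] * 3,
                "lineage": ["australis"] * 7,
                "abraded": [1] * 7,
                "section_score": [0, 0.5, 1, 0.5, 0, 0, 0],
            }
        )
        scored = score_mature_table(df)
        by_id = scored.set_index("isolate_id")
        assert by_id.loc["A", "mean_lesion_score"] == pytest.approx(0.5)
        assert by_id.loc["A", "class"] == "Pathogen"
        assert by_id.loc["B", "class"] == "Nonpathogen"


def test_timecourse_requires_increasing_days():
    counts = LeafCategoryCounts(1, 0, 0, 0, 0)
    with pytest.raises(ValueError):
        TimeCourse("x", ((2, counts), (2, counts)))
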