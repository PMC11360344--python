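"""Cut-point classification, vector magnitude, summaries, percent errors."""

import math
from datetime import datetime

import numpy as np
import pytest

from actikit import (
    CATEGORIES,
    ContractError,
    CutPointScheme,
    EpochCounts,
    FREEDSON_ADULT_1998,
    WearMask,
    classify_cpm,
    classify_cpm_vector,
    comparison_table,
    percent_error,
    per_epoch_vector_magnitude_total,
    summarize,
    vector_magnitude_total,
)

from oracles import classify_reference

START = datetime(2021, 6, 1)


class TestClassify:
    @pytest.mark.parametrize(
        "cpm,expected",
        [
            (0, "sedentary"), (99, "sedentary"),
            (100, "light"), (1951, "light"),
            (1952, "moderate"), (5724, "moderate"),
            (5725, "vigorous"), (9498, "vigorous"),
            (9499, "very_vigorous"), (50_000, "very_vigorous"),
        ],
    )
    def test_boundary_lookup(self, cpm, expected):
        assert classify_cpm(cpm) == expected

    def test_agrees_with_linear_scan_everywhere(self):
        cpms = np.arange(0, 20_001)
        vec = classify_cpm_vector(cpms)
        for cpm in range(0, 20_001, 97):  # stride keeps the scan cheap
            assert vec[cpm] == classify_reference(cpm, FREEDSON_ADULT_1998.boundaries)
        # vectorised and scalar paths agree everywhere
        scalar = [classify_cpm(int(c)) for c in cpms[::211]]
        assert list(vec[::211]) == scalar

    def test_negative_cpm_rejected(self):
        with pytest.raises(ContractError):
            classify_cpm(-1)

    def test_scheme_partition_validated(self):
        with pytest.raises(ContractError, match="abut"):
            CutPointScheme("gap", (("a", 0, 10), ("b", 12, None)))
        with pytest.raises(ContractError, match="unbounded"):
            CutPointScheme("capped", (("a", 0, 10),))


class TestVectorMagnitude:
    def test_single_axis_identity(self):
        assert vector_magnitude_total(0, 123.0, 0) == 123.0

    def test_3_4_5(self):
        assert vector_magnitude_total(3, 4, 0) == 5.0

    def test_unit_diagonal(self):
        assert vector_magnitude_total(1, 1, 1) == pytest.approx(math.sqrt(3))

    def test_permutation_invariant_and_homogeneous(self, rng):
        for _ in range(50):
            a, b, c = rng.uniform(0, 1e6, 3)
            base = vector_magnitude_total(a, b, c)
            assert vector_magnitude_total(c, a, b) == pytest.approx(base)
            k = rng.uniform(0.1, 10)
            assert vector_magnitude_total(k * a, k * b, k * c) == pytest.approx(k * base)

    def test_negative_rejected(self):
        with pytest.raises(ContractError):
            vector_magnitude_total(-1, 0, 0)

    def test_per_epoch_variant_differs_from_totals_variant(self):
        ep = EpochCounts(60.0, START, [3, 0], [4, 0], [0, 5])
        per_epoch = per_epoch_vector_magnitude_total(ep)
        assert per_epoch == pytest.approx(5.0 + 5.0)
        totals = vector_magnitude_total(3, 4, 5)
        assert per_epoch != pytest.approx(totals)


class TestSummarize:
    def test_all_sedentary_hour(self):
        ep = EpochCounts(60.0, START, np.zeros(60), np.zeros(60), np.zeros(60))
        s = summarize(ep, WearMask(np.ones(60)))
        assert s.minutes_per_category == {
            "sedentary": 60, "light": 0, "moderate": 0, "vigorous": 0, "very_vigorous": 0}
        assert s.percent_per_category["sedentary"] == 100.0
        assert s.wear_minutes == 60

    def test_empty_wear_time(self):
        ep = EpochCounts(60.0, START, [5], [5], [5])
        s = summarize(ep, WearMask([0]))
        assert s.wear_minutes == 0
        assert s.total_counts_y == 0
        assert all(v == 0 for v in s.percent_per_category.values())

    def test_partition_property_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 300))
            y = rng.integers(0, 12_000, n)
            ep = EpochCounts(60.0, START, rng.integers(0, 5000, n), y, rng.integers(0, 5000, n))
            mask = WearMask(rng.integers(0, 2, n))
            s = summarize(ep, mask)
            assert sum(s.minutes_per_category.values()) == s.wear_minutes
            if s.wear_minutes:
                assert sum(s.percent_per_category.values()) == pytest.approx(100.0, abs=1e-9)

    def test_totals_exclude_nonwear(self):
        ep = EpochCounts(60.0, START, [100, 200], [10, 20], [1, 2])
        s = summarize(ep, WearMask([1, 0]))
        assert (s.total_counts_x, s.total_counts_y, s.total_counts_z) == (100, 10, 1)
        assert s.vector_magnitude_total == pytest.approx(math.hypot(100, math.hypot(10, 1)))


class TestPercentError:
    def test_identity(self):
        assert percent_error(100, 100) == 0.0

    def test_zero_reference_undefined(self):
        assert math.isnan(percent_error(0, 5))

    def test_symmetric_magnitude(self):
        assert percent_error(100, 98) == pytest.approx(2.0)
        assert percent_error(100, 102) == pytest.approx(2.0)


def _summary_dict(y=100, vm=200.0, steps=50, minutes=None):
    minutes = minutes or {c: 10 for c in CATEGORIES}
    wear = sum(minutes.values())
    return {
        "total_counts_x": 0, "total_counts_y": y, "total_counts_z": 0,
        "vector_magnitude_total": vm, "vector_magnitude_per_epoch_total": vm,
        "total_steps": steps, "wear_minutes": wear,
        "minutes_per_category": minutes,
        "percent_per_category": {c: 100.0 * m / wear for c, m in minutes.items()},
    }


class TestComparisonTable:
    def test_identical_summaries_zero_error(self):
        t = comparison_table(_summary_dict(), _summary_dict())
        assert (t["percent_error"] == 0.0).all()

    def test_simple_arithmetic(self):
        t = comparison_table(_summary_dict(y=100), _summary_dict(y=98))
        row = t[t.metric == "total_y_axis_counts"].iloc[0]
        assert row.percent_error == 2.00

    def test_row_order(self):
        t = comparison_table(_summary_dict(), _summary_dict())
        assert t.metric.tolist() == [
            "total_y_axis_counts", "total_vector_magnitude_counts", "total_step_counts",
            "minutes_sedentary", "minutes_light", "minutes_moderate",
            "minutes_vigorous", "minutes_very_vigorous",
        ]

    def test_mean_of_errors_differs_from_error_of_means(self):
        # method B errs +10% on one recording and -10% on another: the mean
        # totals agree (0% error of means) but per-unit errors average 10%
        a = [_summary_dict(y=1000), _summary_dict(y=1000)]
        b = [_summary_dict(y=1100), _summary_dict(y=900)]
        of_means = comparison_table(a, b, mode="error_of_means")
        per_unit = comparison_table(a, b, mode="mean_of_errors")
        y_means = of_means[of_means.metric == "total_y_axis_counts"].iloc[0].percent_error
        y_unit = per_unit[per_unit.metric == "total_y_axis_counts"].iloc[0].percent_error
        assert y_means == 0.00 and y_unit == 10.00

    def test_missing_keys_rejected(self):
        bad = _summary_dict()
        del bad["total_steps"]
        with pytest.raises((ContractError, KeyError)):
            comparison_table(_summary_dict(), bad)
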