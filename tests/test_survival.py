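"""Shifted-cohort estimator: worked example, oracle equivalence, invariants."""

import numpy as np
import pytest

from storeflux import (
    AveragedCurve,
    CohortError,
    SimulationConfig,
    StorefluxError,
    UndefinedIntervalError,
    all_cohort_series,
    average_series,
    cohort_series,
    estimate_half_life,
    half_life,
    removal_interval,
    simulate_marketplace,
)

from conftest import (
    brute_average,
    brute_cohort,
    brute_half_life,
    panel_from_sets,
    random_small_panel,
)


class TestCohortSeries:
    def test_worked_example_start_day_1(self, fixture_f):
        s = cohort_series(fixture_f, "search", 1)
        assert s.baseline == frozenset("abcd")
        assert s.points == {1: 1.0, 2: 0.75, 3: 0.5, 4: 0.5, 5: 0.25, 6: 0.25}

    def test_worked_example_start_day_2(self, fixture_f):
        s = cohort_series(fixture_f, "search", 2)
        assert s.baseline == frozenset("abc")
        expected = {1: 1.0, 2: 2 / 3, 3: 2 / 3, 4: 1 / 3, 5: 1 / 3}
        assert s.points == pytest.approx(expected)

    def test_availability_dominates_search_pointwise(self, fixture_f):
        search = cohort_series(fixture_f, "search", 1)
        avail = cohort_series(fixture_f, "availability", 1)
        for t in search.points:
            assert avail.points[t] >= search.points[t]
        assert all(p == 1.0 for p in avail.points.values())

    def test_all_apps_present_gives_flat_series(self):
        panel = panel_from_sets({d: ["a", "b", "c"] for d in range(1, 8)})
        s = cohort_series(panel, "search", 1)
        assert set(s.points.values()) == {1.0}

    def test_empty_baseline_raises(self):
        panel = panel_from_sets({1: [], 2: ["a"]})
        with pytest.raises(CohortError):
            cohort_series(panel, "search", 1)

    def test_unobserved_start_day_raises(self, fixture_f):
        with pytest.raises(StorefluxError, match="observed"):
            cohort_series(fixture_f, "search", 99)

    def test_missing_days_leave_gaps_not_carried_values(self):
        # day 3 unobserved: offset 3 absent from the day-1 cohort
        panel = panel_from_sets({1: ["a", "b"], 2: ["a"], 4: ["a"]}, span_days=4)
        s = cohort_series(panel, "search", 1)
        assert sorted(s.points) == [1, 2, 4]

    def test_absorbing_mode_is_monotone(self):
        # app b leaves on day 2 and re-enters on day 3
        panel = panel_from_sets({1: ["a", "b"], 2: ["a"], 3: ["a", "b"]})
        free = cohort_series(panel, "search", 1)
        absorbed = cohort_series(panel, "search", 1, absorbing=True)
        assert free.points[3] == 1.0  # re-entry counted
        assert absorbed.points == {1: 1.0, 2: 0.5, 3: 0.5}


class TestAverageSeries:
    def test_worked_example_average(self, fixture_f):
        series = [cohort_series(fixture_f, "search", d) for d in (1, 2)]
        curve = average_series(series, min_series=1)
        expected = {
            1: 1.0,
            2: (0.75 + 2 / 3) / 2,
            3: (0.5 + 2 / 3) / 2,
            4: (0.5 + 1 / 3) / 2,
            5: (0.25 + 1 / 3) / 2,
            6: 0.25,
        }
        assert curve.points == pytest.approx(expected)
        assert curve.support == {1: 2, 2: 2, 3: 2, 4: 2, 5: 2, 6: 1}

    def test_min_series_drops_thin_tail(self, fixture_f):
        series = [cohort_series(fixture_f, "search", d) for d in (1, 2)]
        curve = average_series(series, min_series=2)
        assert sorted(curve.points) == [1, 2, 3, 4, 5]

    def test_identical_series_average_to_themselves(self, fixture_f):
        s = cohort_series(fixture_f, "search", 1)
        curve = average_series([s] * 25, min_series=20)
        assert curve.points == pytest.approx(s.points)

    def test_mixed_modes_rejected(self, fixture_f):
        pair = [
            cohort_series(fixture_f, "search", 1),
            cohort_series(fixture_f, "availability", 1),
        ]
        with pytest.raises(StorefluxError, match="mixed"):
            average_series(pair, min_series=1)

    def test_empty_input_rejected(self):
        with pytest.raises(StorefluxError):
            average_series([], min_series=1)

    def test_average_bounded_by_contributing_series(self):
        rng_seeds = range(6)
        for seed in rng_seeds:
            panel = random_small_panel(seed)
            series = all_cohort_series(panel, "search")
            if not series:
                continue
            curve = average_series(series, min_series=1)
            for t, value in curve.points.items():
                contributing = [s.points[t] for s in series if t in s.points]
                assert min(contributing) - 1e-12 <= value <= max(contributing) + 1e-12


class TestHalfLife:
    def test_worked_example_crossing(self, fixture_f):
        series = [cohort_series(fixture_f, "search", d) for d in (1, 2)]
        result = half_life(average_series(series, min_series=1))
        assert result.half_life_days == 4
        assert not result.censored
        assert result.remaining_at_end == pytest.approx(0.25)
        assert result.last_offset == 6

    def test_flat_curve_is_censored(self):
        curve = AveragedCurve(
            "search",
            {t: 1.0 for t in range(1, 101)},
            {t: 30 for t in range(1, 101)},
            20,
        )
        result = half_life(curve)
        assert result.censored and result.half_life_days is None
        assert result.remaining_at_end == 1.0

    def test_crossing_is_strictly_below_half(self):
        points = {1: 1.0, 2: 0.8, 3: 0.5, 4: 0.49}
        curve = AveragedCurve("search", points, {t: 25 for t in points}, 20)
        assert half_life(curve).half_life_days == 4

    def test_empty_curve_rejected(self):
        with pytest.raises(StorefluxError):
            half_life(AveragedCurve("search", {}, {1: 3}, 20))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("mode", ["search", "availability"])
    def test_matches_brute_force_enumeration(self, seed, mode):
        panel = random_small_panel(seed)
        series = all_cohort_series(panel, mode)
        searched_days = sorted(
            {int(d) for d in panel.frame.loc[panel.frame["in_search"], "date"]}
        )
        assert [s.start_day for s in series] == searched_days
        for s in series:
            assert s.points == pytest.approx(brute_cohort(panel, mode, s.start_day), abs=1e-12)
        if not series:
            return
        for min_series in (1, 2):
            curve = average_series(series, min_series=min_series)
            points, support = brute_average(panel, mode, min_series)
            assert curve.points == pytest.approx(points, abs=1e-12)
            assert curve.support == support
            if curve.points:
                crossing, remaining = brute_half_life(points)
                result = half_life(curve)
                assert result.half_life_days == crossing
                assert result.remaining_at_end == pytest.approx(remaining, abs=1e-12)


class TestDominanceInvariant:
    @pytest.mark.parametrize("seed", range(5))
    def test_search_halflife_never_exceeds_availability(self, seed):
        cfg = SimulationConfig(
            n_initial_apps=40,
            arrival_rate=1.0,
            removal_hazard_relevant=0.02,
            removal_hazard_nonrelevant=0.02,
            search_window_k=25,
            span_days=60,
            n_missing_days=6,
            seed=seed,
        )
        panel, _, _ = simulate_marketplace(cfg)
        _, search = estimate_half_life(panel, "search", min_series=5)
        _, avail = estimate_half_life(panel, "availability", min_series=5)
        if avail.censored:
            assert True  # availability censored dominates any search result
        else:
            assert not search.censored
            assert search.half_life_days <= avail.half_life_days

    def test_no_truncation_makes_modes_identical(self):
        cfg = SimulationConfig(
            n_initial_apps=30,
            arrival_rate=0.5,
            removal_hazard_relevant=0.03,
            removal_hazard_nonrelevant=0.03,
            search_window_k=10_000,
            span_days=50,
            n_missing_days=0,
            seed=4,
        )
        panel, _, _ = simulate_marketplace(cfg)
        search_curve, _ = estimate_half_life(panel, "search", min_series=1)
        avail_curve, _ = estimate_half_life(panel, "availability", min_series=1)
        assert search_curve.points == pytest.approx(avail_curve.points, abs=1e-12)


class TestRemovalInterval:
    def test_android_relevant_interval(self):
        assert removal_interval([(197, 0.659)], 246) == 3.7

    def test_pooled_interval_across_platforms(self):
        assert removal_interval([(197, 0.659), (150, 0.878)], 246) == 2.9

    def test_no_removals_is_undefined(self):
        with pytest.raises(UndefinedIntervalError):
            removal_interval([(100, 1.0)], 246)

    def test_simple_interval(self):
        assert removal_interval([(100, 0.5)], 100) == 2.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StorefluxError):
            removal_interval([(0, 0.5)], 100)
        with pytest.raises(StorefluxError):
            removal_interval([(10, 1.5)], 100)
        with pytest.raises(StorefluxError):
            removal_interval([(10, 0.5)], 0)
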