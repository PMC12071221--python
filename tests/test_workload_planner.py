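"""Workload arithmetic, feasibility classification and staff-hour accounting."""

import math

import numpy as np
import pytest

from cep_planner.core_data import HourlyProfile, flat_profile
from cep_planner.workload_planner import (
    STRATEGY3_GROUPS,
    FeasibilityThresholds,
    ShiftPlan,
    StrategySpec,
    StrategyUnit,
    builtin_strategies,
    classify_feasibility,
    evaluate_strategies,
    group_workload_table,
    slot_workload,
    staff_hours,
    station_workload_table,
)


class TestSlotWorkload:
    def test_peak_slot(self):
        row = slot_workload(0.8877, 1, 60)
        assert row.workload == pytest.approx(88.77)
        assert row.over85 and not row.over100

    def test_zero_rate(self):
        assert slot_workload(0.0, 1, 60).workload == 0.0

    def test_two_servers_halve(self):
        assert slot_workload(1.0, 2, 60).workload == pytest.approx(50.0)

    def test_uncovered_demand_marker(self):
        row = slot_workload(0.5, 0, 60)
        assert row.uncovered
        assert math.isinf(row.workload)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            slot_workload(-0.1, 1)
        with pytest.raises(ValueError):
            slot_workload(0.5, 1, 0)


class TestStationTable:
    def test_wandsbek_reference_table(self, wandsbek_profile):
        table = station_workload_table(wandsbek_profile)
        assert round(table.average_workload, 2) == 55.70
        assert table.n_over85 == 1
        assert table.n_over100 == 0
        assert not table.sufficient
        assert table.rows[10].workload == pytest.approx(88.77)
        assert table.rows[10].demand == pytest.approx(53.26, abs=0.005)

    def test_low_demand_station_average(self):
        table = station_workload_table(flat_profile("Finkenwerder", 383))
        assert round(table.average_workload, 2) == 4.37
        assert table.sufficient

    def test_average_equals_annual_over_8760(self, registry):
        """With one round-the-clock CEP the average workload reduces to
        annual_total / 8760 regardless of the diurnal shape."""
        for name, expected in (
            ("Altona", 44.26),
            ("Veddel", 12.13),
            ("Wilhelmsburg", 15.47),
        ):
            total = registry[name].ops_total
            table = station_workload_table(flat_profile(name, total))
            assert table.average_workload == pytest.approx(total / 8760 * 100)
            assert round(table.average_workload, 2) == pytest.approx(
                expected, abs=0.05
            )

    def test_all_zero_profile(self):
        table = station_workload_table(HourlyProfile("empty", np.zeros(24)))
        assert table.average_workload == 0.0
        assert table.sufficient


class TestGroupTable:
    def test_single_member_group_is_station_table(self, wandsbek_profile):
        solo = station_workload_table(wandsbek_profile)
        grouped = group_workload_table([wandsbek_profile])
        assert grouped.average_workload == pytest.approx(solo.average_workload)

    def test_group_additivity_one_cep(self):
        """With one shared CEP the group average equals the sum of member
        averages (exact additivity)."""
        a = flat_profile("Altona", 3877)
        b = flat_profile("Osdorf", 2982)
        combined = group_workload_table([a, b])
        sep = [station_workload_table(p).average_workload for p in (a, b)]
        assert combined.average_workload == pytest.approx(sum(sep))
        assert round(combined.average_workload, 2) == pytest.approx(78.29, abs=0.05)

    def test_second_shift_halves_day_slots(self, wandsbek_profile):
        plan = ShiftPlan.with_second_shift(7, 19)
        table = group_workload_table([wandsbek_profile], plan)
        solo = station_workload_table(wandsbek_profile)
        for h in range(24):
            factor = 2.0 if 7 <= h < 19 else 1.0
            assert table.rows[h].workload == pytest.approx(
                solo.rows[h].workload / factor
            )
        assert round(table.average_workload, 2) == 37.89

    def test_doubling_ceps_halves_everything(self, wandsbek_profile):
        one = station_workload_table(wandsbek_profile, ShiftPlan.around_the_clock(1))
        two = station_workload_table(wandsbek_profile, ShiftPlan.around_the_clock(2))
        for r1, r2 in zip(one.rows, two.rows):
            assert r2.workload == pytest.approx(r1.workload / 2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_workload_table([])


class TestFeasibility:
    def test_wandsbek_classification(self, wandsbek_profile):
        record = classify_feasibility(station_workload_table(wandsbek_profile))
        assert record.n_over85 == 1
        assert record.n_over100 == 0
        assert "over 85" in record.label

    def test_sufficient_label(self):
        record = classify_feasibility(
            station_workload_table(flat_profile("Altona", 3877))
        )
        assert record.label == "sufficient"

    def test_zero_table_sufficient(self):
        record = classify_feasibility(
            station_workload_table(HourlyProfile("z", np.zeros(24)))
        )
        assert record.label == "sufficient"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            FeasibilityThresholds(realistic_limit=100.0, hard_limit=85.0)


class TestStaffHours:
    @pytest.mark.parametrize(
        "sid,expected",
        [
            ("1a", 148_920),
            ("1b", 52_560),
            ("1c", 35_040),
            ("2a", 166_440),
            ("2b", 70_080),
            ("2c", 52_560),
            ("3a", 87_600),
            ("3b", 122_640),
            ("3b_extended", 126_290),
        ],
    )
    def test_catalogue_annual_hours(self, sid, expected):
        summary = staff_hours(builtin_strategies()[sid])
        assert summary.staff_hours_per_year == expected
        assert summary.staff_hours_per_year == summary.staff_hours_per_day * 365

    def test_coverage_rates(self):
        strategies = builtin_strategies()
        assert staff_hours(strategies["1a"]).area_coverage_rate == pytest.approx(100.0)
        assert staff_hours(strategies["1c"]).area_coverage_rate == pytest.approx(
            4 / 17 * 100
        )
        assert staff_hours(strategies["3a"]).area_coverage_rate == pytest.approx(100.0)

    def test_cep_counts(self):
        strategies = builtin_strategies()
        s2a = staff_hours(strategies["2a"])
        assert (s2a.n_24h_ceps, s2a.n_12h_ceps) == (17, 4)
        s3b = staff_hours(strategies["3b"])
        assert (s3b.n_24h_ceps, s3b.n_12h_ceps) == (10, 8)

    def test_empty_strategy(self):
        summary = staff_hours(StrategySpec("none", []))
        assert summary.staff_hours_per_year == 0
        assert summary.area_coverage_rate == 0.0

    def test_linearity_disjoint_units(self):
        unit = StrategyUnit("solo", ("Barmbek",), ShiftPlan.around_the_clock())
        one = staff_hours(StrategySpec("one", [unit]))
        unit2 = StrategyUnit("solo2", ("Sasel",), ShiftPlan.around_the_clock())
        two = staff_hours(StrategySpec("two", [unit, unit2]))
        assert (
            two.staff_hours_per_year - one.staff_hours_per_year == 24 * 365
        )

    def test_duplicate_station_rejected(self):
        unit = StrategyUnit("a", ("Barmbek",), ShiftPlan.around_the_clock())
        dup = StrategyUnit("b", ("Barmbek",), ShiftPlan.around_the_clock())
        with pytest.raises(ValueError, match="twice"):
            StrategySpec("bad", [unit, dup])


class TestEvaluateStrategies:
    def test_groups_partition_stations(self):
        members = [s for g in STRATEGY3_GROUPS.values() for s in g]
        assert len(members) == 17
        assert len(set(members)) == 17

    def test_comparison_table(self, registry, wandsbek_profile):
        profiles = {
            r.name: (
                wandsbek_profile if r.name == "Wandsbek"
                else flat_profile(r.name, r.ops_total)
            )
            for r in registry
        }
        table = evaluate_strategies(registry, profiles)
        assert len(table) == 9
        by_id = table.set_index("strategy")
        assert by_id.loc["1a", "staff_hours_per_year"] == 148_920
        assert by_id.loc["3b", "staff_hours_per_year"] == 122_640
        # every annual figure divisible by 365
        assert (by_id["staff_hours_per_year"] % 365 == 0).all()

    def test_unknown_strategy_member_profile_missing(self, registry):
        with pytest.raises(ValueError, match="profile"):
            evaluate_strategies(registry, {"Wandsbek": flat_profile("Wandsbek", 1)})
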