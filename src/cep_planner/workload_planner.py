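"""Hourly workload tables and staff-hour accounting for paramedic strategies.

The demand of a clock-hour slot is ``rate * operation_time`` minutes, where
``rate`` is the slot's average number of non-time-critical operations per
day (annual slot count / 365) and the mean operation time defaults to 60
minutes.  Supply is ``n_cep * 60`` minutes for the community emergency
paramedics (CEPs) on duty in the slot, and

    workload [%] = demand / supply * 100.

Slots above 85% are flagged as beyond the sustainable utilisation limit
(time for administration and recovery); slots above 100% carry uncovered
demand.  A station or group is labelled "sufficient" when no slot exceeds
85%.

The built-in strategy catalogue covers:

* #1 [a/b/c]: one 24-h CEP per station — all 17 / the six higher-demand /
  the four high-demand stations;
* #2 [a/b/c]: like #1 plus a second 12-h CEP at the four high-demand
  stations;
* #3 [a/b]: ten neighbourhood groups sharing one 24-h CEP each, with [b]
  adding a second 12-h CEP (07:00-19:00) to the eight higher-demand groups,
  and an extended variant that lengthens the second shift in four groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import DAYS_PER_YEAR, HOURS_PER_DAY, HourlyProfile, StationRegistry

N_STATIONS = 17

HIGH_DEMAND = ("Barmbek", "Sasel", "Stellingen", "Wandsbek")
HIGHER_DEMAND = ("Altona", "Barmbek", "Bergedorf", "Sasel", "Stellingen", "Wandsbek")

#: the ten neighbourhood groups of strategy #3
STRATEGY3_GROUPS: dict[int, tuple[str, ...]] = {
    1: ("Süderelbe", "Finkenwerder"),
    2: ("Harburg", "Veddel", "Wilhelmsburg"),
    3: ("Billstedt", "Bergedorf"),
    4: ("Innenstadt", "Berliner Tor"),
    5: ("Altona", "Osdorf"),
    6: ("Rotherbaum",),
    7: ("Stellingen", "Alsterdorf"),
    8: ("Barmbek",),
    9: ("Sasel",),
    10: ("Wandsbek",),
}

#: groups that receive the second 12-h CEP under strategy #3[b]
STRATEGY3B_SECOND_CEP = (2, 3, 4, 5, 7, 8, 9, 10)

#: extra daily duty hours of the second CEP in the extended #3[b] variant
STRATEGY3B_EXTENSION_HOURS = {3: 1, 4: 1, 5: 3, 7: 5}


@dataclass(frozen=True)
class FeasibilityThresholds:
    realistic_limit: float = 85.0  # sustainable utilisation, percent
    hard_limit: float = 100.0  # capacity ceiling

    def __post_init__(self) -> None:
        if not self.realistic_limit < self.hard_limit:
            raise ValueError("realistic limit must lie below the hard limit")


@dataclass(frozen=True)
class ShiftPlan:
    """CEPs on duty per hour slot (24 non-negative integers)."""

    n_cep: tuple[int, ...]
    daily_hours: int | None = None  # scheduled duty hours per day; defaults to sum

    def __post_init__(self) -> None:
        if len(self.n_cep) != HOURS_PER_DAY:
            raise ValueError("a shift plan covers exactly 24 hour slots")
        if any(n < 0 for n in self.n_cep):
            raise ValueError("CEP counts must be non-negative")
        if self.daily_hours is None:
            object.__setattr__(self, "daily_hours", int(sum(self.n_cep)))

    @classmethod
    def around_the_clock(cls, n: int = 1) -> "ShiftPlan":
        return cls(tuple([n] * HOURS_PER_DAY))

    @classmethod
    def with_second_shift(
        cls, start: int = 7, end: int = 19, extension_hours: int = 0
    ) -> "ShiftPlan":
        """One 24-h CEP plus a second CEP on duty [start, end) o'clock.

        ``extension_hours`` lengthens the second shift past ``end``.
        """
        counts = [1] * HOURS_PER_DAY
        for h in range(start, min(end + extension_hours, HOURS_PER_DAY)):
            counts[h] += 1
        return cls(tuple(counts))


@dataclass(frozen=True)
class WorkloadRow:
    hour_slot: int
    rate: float  # operations per hour slot per day
    operation_time: float  # minutes
    demand: float  # minutes
    n_cep: int
    supply: float  # minutes
    workload: float  # percent; inf when demand meets zero supply
    over85: bool
    over100: bool
    uncovered: bool = False


@dataclass
class WorkloadTable:
    station_or_group: str
    rows: list[WorkloadRow]
    average_workload: float  # mean of the 24 per-slot workloads, percent
    n_over85: int
    n_over100: int
    sufficient: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hour_slot": [r.hour_slot for r in self.rows],
                "rate": [r.rate for r in self.rows],
                "demand_min": [r.demand for r in self.rows],
                "n_cep": [r.n_cep for r in self.rows],
                "supply_min": [r.supply for r in self.rows],
                "workload_pct": [r.workload for r in self.rows],
                "over85": [r.over85 for r in self.rows],
                "over100": [r.over100 for r in self.rows],
            }
        )


def slot_workload(
    rate: float,
    n_cep: int,
    operation_time: float = 60.0,
    thresholds: FeasibilityThresholds = FeasibilityThresholds(),
    hour_slot: int = 0,
) -> WorkloadRow:
    """Workload of one hour slot: rate x operation_time / (n_cep x 60)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if operation_time <= 0:
        raise ValueError("operation_time must be positive")
    demand = rate * operation_time
    supply = n_cep * 60.0
    if n_cep == 0:
        workload = math.inf if demand > 0 else 0.0
        uncovered = demand > 0
    else:
        workload = demand / supply * 100.0
        uncovered = False
    return WorkloadRow(
        hour_slot=hour_slot,
        rate=rate,
        operation_time=operation_time,
        demand=demand,
        n_cep=n_cep,
        supply=supply,
        workload=workload,
        over85=workload > thresholds.realistic_limit,
        over100=workload > thresholds.hard_limit,
        uncovered=uncovered,
    )


def station_workload_table(
    profile: HourlyProfile,
    plan: ShiftPlan = ShiftPlan.around_the_clock(),
    operation_time: float = 60.0,
    thresholds: FeasibilityThresholds = FeasibilityThresholds(),
) -> WorkloadTable:
    """24 workload rows plus the daily average for one station."""
    rows = [
        slot_workload(
            float(profile.rates[h]),
            plan.n_cep[h],
            operation_time,
            thresholds,
            hour_slot=h,
        )
        for h in range(HOURS_PER_DAY)
    ]
    workloads = [r.workload for r in rows]
    return WorkloadTable(
        station_or_group=profile.station_or_group,
        rows=rows,
        average_workload=float(np.mean(workloads)),
        n_over85=sum(r.over85 for r in rows),
        n_over100=sum(r.over100 for r in rows),
        sufficient=not any(r.over85 for r in rows),
    )


def group_workload_table(
    profiles: Sequence[HourlyProfile],
    plan: ShiftPlan = ShiftPlan.around_the_clock(),
    operation_time: float = 60.0,
    thresholds: FeasibilityThresholds = FeasibilityThresholds(),
) -> WorkloadTable:
    """Per-CEP workload of a pooled group of stations.

    The group's slot rate is the element-wise sum of the member rates; the
    per-CEP workload divides the combined demand by the CEPs on duty in the
    slot, so adding a second CEP during its window halves those slots.
    """
    if not profiles:
        raise ValueError("a group needs at least one member profile")
    combined = HourlyProfile(
        "+".join(p.station_or_group for p in profiles),
        np.sum([p.rates for p in profiles], axis=0),
    )
    return station_workload_table(combined, plan, operation_time, thresholds)


@dataclass(frozen=True)
class FeasibilityRecord:
    station_or_group: str
    n_over85: int
    n_over100: int
    label: str  # "sufficient" or "n slots over 85%[, m over 100%]"


def classify_feasibility(
    table: WorkloadTable,
    thresholds: FeasibilityThresholds = FeasibilityThresholds(),
) -> FeasibilityRecord:
    n85 = sum(r.workload > thresholds.realistic_limit for r in table.rows)
    n100 = sum(r.workload > thresholds.hard_limit for r in table.rows)
    if n85 == 0:
        label = "sufficient"
    elif n100 == 0:
        label = f"{n85} time slot(s) over {thresholds.realistic_limit:g}%"
    else:
        label = (
            f"{n85} time slot(s) over {thresholds.realistic_limit:g}% and "
            f"{n100} over {thresholds.hard_limit:g}%"
        )
    return FeasibilityRecord(
        station_or_group=table.station_or_group,
        n_over85=n85,
        n_over100=n100,
        label=label,
    )


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------


@dataclass
class StrategyUnit:
    """One staffed unit: a station or a pooled group with its shift plan."""

    name: str
    members: tuple[str, ...]
    plan: ShiftPlan


@dataclass
class StrategySpec:
    id: str
    units: list[StrategyUnit]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for unit in self.units:
            for station in unit.members:
                if station in seen:
                    raise ValueError(f"station {station!r} assigned twice")
                seen.add(station)

    @property
    def covered_stations(self) -> set[str]:
        return {s for u in self.units for s in u.members}


@dataclass
class StaffingSummary:
    strategy_id: str
    staff_hours_per_day: int
    staff_hours_per_year: int  # per_day * 365 exactly
    n_24h_ceps: int
    n_12h_ceps: int
    area_coverage_rate: float  # covered stations / 17 * 100
    feasibility: list[FeasibilityRecord] = field(default_factory=list)


def staff_hours(
    strategy: StrategySpec, n_stations_total: int = N_STATIONS
) -> StaffingSummary:
    """Daily and annual staff-hour accounting of a strategy.

    Every unit contributes its scheduled daily duty hours (24 for the
    round-the-clock CEP, plus 12 and any extension for a second shift);
    annual hours are daily hours x 365.
    """
    per_day = 0
    n24 = n12 = 0
    for unit in strategy.units:
        per_day += unit.plan.daily_hours
        base = min(unit.plan.n_cep)
        n24 += base
        if max(unit.plan.n_cep) > base:
            n12 += 1
    covered = len(strategy.covered_stations)
    return StaffingSummary(
        strategy_id=strategy.id,
        staff_hours_per_day=per_day,
        staff_hours_per_year=per_day * DAYS_PER_YEAR,
        n_24h_ceps=n24,
        n_12h_ceps=n12,
        area_coverage_rate=covered / n_stations_total * 100.0,
        feasibility=[],
    )


def builtin_strategies(
    second_shift_start: int = 7, second_shift_end: int = 19
) -> dict[str, StrategySpec]:
    """The strategy catalogue: 1a-1c, 2a-2c, 3a, 3b and 3b_extended.

    The second-shift window defaults to 07:00-19:00 (12 h), consistent with
    the 12-hour duty accounting of every strategy.
    """
    one24 = ShiftPlan.around_the_clock()

    def single(stations: Sequence[str], second: Sequence[str] = ()) -> list[StrategyUnit]:
        units = []
        for s in stations:
            plan = (
                ShiftPlan.with_second_shift(second_shift_start, second_shift_end)
                if s in second
                else one24
            )
            units.append(StrategyUnit(name=s, members=(s,), plan=plan))
        return units

    all17 = tuple(sorted(set(sum((list(g) for g in STRATEGY3_GROUPS.values()), []))))

    def groups(
        second: Sequence[int] = (), extensions: Mapping[int, int] | None = None
    ) -> list[StrategyUnit]:
        extensions = extensions or {}
        units = []
        for gid, members in STRATEGY3_GROUPS.items():
            if gid in second:
                plan = ShiftPlan.with_second_shift(
                    second_shift_start,
                    second_shift_end,
                    extension_hours=extensions.get(gid, 0),
                )
            else:
                plan = one24
            units.append(
                StrategyUnit(name=f"group{gid}", members=members, plan=plan)
            )
        return units

    return {
        "1a": StrategySpec("1a", single(all17)),
        "1b": StrategySpec("1b", single(HIGHER_DEMAND)),
        "1c": StrategySpec("1c", single(HIGH_DEMAND)),
        "2a": StrategySpec("2a", single(all17, second=HIGH_DEMAND)),
        "2b": StrategySpec("2b", single(HIGHER_DEMAND, second=HIGH_DEMAND)),
        "2c": StrategySpec("2c", single(HIGH_DEMAND, second=HIGH_DEMAND)),
        "3a": StrategySpec("3a", groups()),
        "3b": StrategySpec("3b", groups(second=STRATEGY3B_SECOND_CEP)),
        "3b_extended": StrategySpec(
            "3b_extended",
            groups(
                second=STRATEGY3B_SECOND_CEP,
                extensions=STRATEGY3B_EXTENSION_HOURS,
            ),
        ),
    }


def evaluate_strategies(
    registry: StationRegistry,
    profiles: Mapping[str, HourlyProfile],
    strategies: Mapping[str, StrategySpec] | None = None,
    operation_time: float = 60.0,
    thresholds: FeasibilityThresholds = FeasibilityThresholds(),
) -> pd.DataFrame:
    """Comparison table: one row per strategy with staff hours, coverage and
    worst-unit feasibility counts.

    ``profiles`` maps station *names* to hourly profiles; group profiles are
    element-wise sums of their members.
    """
    if strategies is None:
        strategies = builtin_strategies()
    rows = []
    for sid, strategy in strategies.items():
        summary = staff_hours(strategy)
        records = []
        for unit in strategy.units:
            missing = [m for m in unit.members if m not in profiles]
            if missing:
                raise ValueError(f"no hourly profile for station(s) {missing}")
            table = group_workload_table(
                [profiles[m] for m in unit.members],
                unit.plan,
                operation_time,
                thresholds,
            )
            records.append(classify_feasibility(table, thresholds))
        summary.feasibility = records
        rows.append(
            {
                "strategy": sid,
                "n_24h_ceps": summary.n_24h_ceps,
                "n_12h_ceps": summary.n_12h_ceps,
                "staff_hours_per_day": summary.staff_hours_per_day,
                "staff_hours_per_year": summary.staff_hours_per_year,
                "area_coverage_pct": round(summary.area_coverage_rate, 1),
                "units_over85": sum(r.n_over85 > 0 for r in records),
                "units_over100": sum(r.n_over100 > 0 for r in records),
                "slots_over85": sum(r.n_over85 for r in records),
                "slots_over100": sum(r.n_over100 for r in records),
            }
        )
    return pd.DataFrame(rows)
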