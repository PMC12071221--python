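"""Domain types, calendar construction and event-count aggregation.

The analysis operates on three layers of data:

* a **station registry** — per-station demography and annual counts of
  non-time-critical ambulance operations for the 17 major Hamburg rescue
  stations, split by whether the patient was transported to hospital;
* a **call-event table** — one row per non-time-critical operation
  (station, date, hour slot, transport outcome);
* **count cubes / hourly profiles** — aggregations of the events by
  station, day of year and clock-hour slot, which feed the statistics,
  the seasonal model and the staffing calculations.

All per-day arithmetic uses a 365-day (non-leap) study year.  Calendar
weeks follow the convention ``week = min(ceil(day_of_year / 7), 52)``:
weeks 1..51 hold exactly 7 days and week 52 absorbs the final 8, so the
annual total divided by 52 is the weekly average.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

AREAS = ("East", "South", "West")

HOURS_PER_DAY = 24
DAYS_PER_YEAR = 365
WEEKS_PER_YEAR = 52

REGISTRY_COLUMNS = (
    "name",
    "abbr",
    "area",
    "population",
    "area_km2",
    "density",
    "ops_total",
    "ops_with",
    "ops_without",
)


# ---------------------------------------------------------------------------
# station registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StationRecord:
    """One rescue station: demography and annual operation counts."""

    name: str
    abbreviation: str
    area: str
    population: int
    area_size: float  # km^2
    density: float  # persons / km^2, stored as printed (not recomputed)
    ops_total: int
    ops_with_transport: int
    ops_without_transport: int

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValueError(
                f"station {self.name!r}: unknown area {self.area!r} "
                f"(expected one of {AREAS})"
            )
        if self.area_size <= 0:
            raise ValueError(f"station {self.name!r}: area_size must be positive")
        for attr in ("ops_total", "ops_with_transport", "ops_without_transport"):
            if getattr(self, attr) < 0:
                raise ValueError(f"station {self.name!r}: {attr} must be >= 0")
        if self.ops_with_transport + self.ops_without_transport != self.ops_total:
            raise ValueError(
                f"station {self.name!r}: with ({self.ops_with_transport}) + "
                f"without ({self.ops_without_transport}) != total ({self.ops_total})"
            )


class StationRegistry:
    """Ordered, validated collection of :class:`StationRecord`.

    Iteration order is alphabetical by station name so every downstream
    computation is deterministic.
    """

    def __init__(self, records: Iterable[StationRecord]):
        self.records: tuple[StationRecord, ...] = tuple(
            sorted(records, key=lambda r: r.name)
        )
        abbrs = [r.abbreviation for r in self.records]
        if len(set(abbrs)) != len(abbrs):
            dupes = sorted({a for a in abbrs if abbrs.count(a) > 1})
            raise ValueError(f"duplicate station abbreviations: {dupes}")
        self._by_abbr = {r.abbreviation: r for r in self.records}
        self._by_name = {r.name: r for r in self.records}

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: str) -> StationRecord:
        if key in self._by_abbr:
            return self._by_abbr[key]
        if key in self._by_name:
            return self._by_name[key]
        raise KeyError(f"unknown station {key!r}")

    def __contains__(self, key: str) -> bool:
        return key in self._by_abbr or key in self._by_name

    @property
    def abbreviations(self) -> list[str]:
        return [r.abbreviation for r in self.records]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def area_of(self, key: str) -> str:
        return self[key].area

    def stations_in_area(self, area: str) -> list[StationRecord]:
        if area not in AREAS:
            raise ValueError(f"unknown area {area!r}")
        return [r for r in self.records if r.area == area]

    def total_operations(self) -> int:
        return sum(r.ops_total for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.records],
                "abbr": [r.abbreviation for r in self.records],
                "area": [r.area for r in self.records],
                "population": [r.population for r in self.records],
                "area_km2": [r.area_size for r in self.records],
                "density": [r.density for r in self.records],
                "ops_total": [r.ops_total for r in self.records],
                "ops_with": [r.ops_with_transport for r in self.records],
                "ops_without": [r.ops_without_transport for r in self.records],
            }
        )


def load_station_table(source) -> StationRegistry:
    """Read a station registry from a CSV file (path or buffer).

    The file needs one row per station with columns
    ``name,abbr,area,population,area_km2,density,ops_total,ops_with,ops_without``.
    A totals row (name == "Total") is ignored but, if present, cross-checked
    against the station sum.
    """
    df = pd.read_csv(source)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"station table missing column(s): {missing}")
    totals_mask = df["name"].astype(str).str.lower().eq("total")
    totals_rows = df[totals_mask]
    df = df[~totals_mask]
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                StationRecord(
                    name=str(row["name"]),
                    abbreviation=str(row["abbr"]),
                    area=str(row["area"]),
                    population=int(row["population"]),
                    area_size=float(row["area_km2"]),
                    density=float(row["density"]),
                    ops_total=int(row["ops_total"]),
                    ops_with_transport=int(row["ops_with"]),
                    ops_without_transport=int(row["ops_without"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"invalid station row {row['name']!r}: {exc}") from exc
    registry = StationRegistry(records)
    if len(totals_rows):
        declared = int(totals_rows.iloc[0]["ops_total"])
        if declared != registry.total_operations():
            raise ValueError(
                f"totals row declares {declared} operations but stations sum to "
                f"{registry.total_operations()}"
            )
    return registry


def load_default_registry() -> StationRegistry:
    """The packaged 17-station Hamburg 2019 registry."""
    ref = resources.files("cep_planner.fixtures") / "stations_2019.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return load_station_table(fh)


def load_wandsbek_profile() -> "HourlyProfile":
    """Packaged 24-slot hourly demand-rate profile of the Wandsbek station."""
    ref = resources.files("cep_planner.fixtures") / "wandsbek_hourly_2019.csv"
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    rates = np.zeros(HOURS_PER_DAY)
    rates[df["hour_slot"].to_numpy()] = df["rate"].to_numpy()
    return HourlyProfile("Wandsbek", rates)


def load_weekday_totals() -> pd.DataFrame:
    """Packaged weekday totals (1=Monday .. 7=Sunday) of the study year."""
    ref = resources.files("cep_planner.fixtures") / "weekday_totals_2019.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# calendar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalendarDay:
    date: dt.date
    day_of_year: int  # 1..365
    week: int  # 1..52; week 52 holds days 358..365
    weekday: int  # 1=Monday .. 7=Sunday
    is_break: bool = False
    is_holiday: bool = False
    is_event: bool = False


def week_of_day(day_of_year: int) -> int:
    """Calendar week index: weeks 1..51 of 7 days, week 52 of 8 days."""
    if not 1 <= day_of_year <= DAYS_PER_YEAR:
        raise ValueError(f"day_of_year {day_of_year} outside 1..{DAYS_PER_YEAR}")
    return min(math.ceil(day_of_year / 7), WEEKS_PER_YEAR)


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _normalize_ranges(entries) -> list[tuple[dt.date, dt.date]]:
    ranges = []
    for entry in entries or []:
        if isinstance(entry, Mapping):
            start = _as_date(entry["start"])
            end = _as_date(entry.get("end", entry["start"]))
        elif isinstance(entry, (tuple, list)):
            start, end = _as_date(entry[0]), _as_date(entry[1])
        else:
            start = end = _as_date(entry)
        if end < start:
            raise ValueError(f"range end {end} before start {start}")
        ranges.append((start, end))
    return ranges


def build_calendar(
    year: int, definitions: Mapping[str, Sequence] | None = None
) -> list[CalendarDay]:
    """Construct the 365 :class:`CalendarDay` entries of a study year.

    ``definitions`` maps the keys ``breaks``, ``holidays`` and ``events`` to
    lists of date ranges (``{start, end}`` mappings, ``(start, end)`` pairs
    or single dates).  Overlapping ranges of the same type collapse silently;
    a range outside the year is an error.  Leap years are rejected because
    every per-day statistic of the model assumes 365 days.
    """
    jan1 = dt.date(year, 1, 1)
    if (dt.date(year + 1, 1, 1) - jan1).days != DAYS_PER_YEAR:
        raise ValueError(f"{year} is a leap year; the model assumes 365 days")
    definitions = definitions or {}
    flag_sets: dict[str, set[dt.date]] = {}
    for kind in ("breaks", "holidays", "events"):
        days: set[dt.date] = set()
        for start, end in _normalize_ranges(definitions.get(kind)):
            if start.year != year or end.year != year:
                raise ValueError(
                    f"{kind} range {start}..{end} falls outside year {year}"
                )
            for offset in range((end - start).days + 1):
                days.add(start + dt.timedelta(days=offset))
        flag_sets[kind] = days
    days_out = []
    for doy in range(1, DAYS_PER_YEAR + 1):
        date = jan1 + dt.timedelta(days=doy - 1)
        days_out.append(
            CalendarDay(
                date=date,
                day_of_year=doy,
                week=week_of_day(doy),
                weekday=date.isoweekday(),
                is_break=date in flag_sets["breaks"],
                is_holiday=date in flag_sets["holidays"],
                is_event=date in flag_sets["events"],
            )
        )
    return days_out


def load_calendar_definitions(source=None) -> dict:
    """Load break/holiday/event definitions from YAML (default: packaged 2019)."""
    if source is None:
        ref = resources.files("cep_planner.fixtures") / "calendar_hamburg_2019.yaml"
        with ref.open("r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    with open(source, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_default_calendar() -> list[CalendarDay]:
    defs = load_calendar_definitions()
    return build_calendar(int(defs["year"]), defs)


def calendar_to_frame(calendar: Sequence[CalendarDay]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": [d.date for d in calendar],
            "day_of_year": [d.day_of_year for d in calendar],
            "week": [d.week for d in calendar],
            "weekday": [d.weekday for d in calendar],
            "is_break": [d.is_break for d in calendar],
            "is_holiday": [d.is_holiday for d in calendar],
            "is_event": [d.is_event for d in calendar],
        }
    )


# ---------------------------------------------------------------------------
# call events and aggregation
# ---------------------------------------------------------------------------


EVENT_COLUMNS = ("station", "date", "hour", "transported")

AGGREGATION_KEYS = ("station", "week", "weekday", "hour_slot", "day_of_year")


@dataclass
class CallEventTable:
    """Event-level table: one row per non-time-critical operation."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"event table missing column(s): {missing}")
        df = self.frame.copy()
        df["date"] = pd.to_datetime(df["date"]).dt.date
        df["hour"] = df["hour"].astype(int)
        df["transported"] = df["transported"].astype(bool)
        if len(df) and not df["hour"].between(0, 23).all():
            raise ValueError("hour slots must lie in 0..23")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def validate(self, registry: StationRegistry, year: int | None = None) -> None:
        unknown = set(self.frame["station"]) - set(registry.abbreviations)
        if unknown:
            raise ValueError(f"events reference unknown station(s): {sorted(unknown)}")
        if year is not None and len(self.frame):
            years = {d.year for d in self.frame["date"]}
            if years != {year}:
                raise ValueError(f"events outside configured year {year}: {years}")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CallEventTable":
        return cls(pd.read_csv(path))


def _event_keys(frame: pd.DataFrame) -> pd.DataFrame:
    """Derive the aggregation key columns from the raw event columns."""
    df = frame.copy()
    doy = np.array([d.timetuple().tm_yday for d in df["date"]])
    df["day_of_year"] = doy
    df["week"] = np.minimum(np.ceil(doy / 7).astype(int), WEEKS_PER_YEAR)
    df["weekday"] = [d.isoweekday() for d in df["date"]]
    df["hour_slot"] = df["hour"]
    return df


_KEY_DOMAINS = {
    "week": lambda reg: range(1, WEEKS_PER_YEAR + 1),
    "weekday": lambda reg: range(1, 8),
    "hour_slot": lambda reg: range(HOURS_PER_DAY),
    "day_of_year": lambda reg: range(1, DAYS_PER_YEAR + 1),
}


def aggregate(
    events: CallEventTable,
    keys: Sequence[str],
    registry: StationRegistry | None = None,
) -> pd.Series:
    """Count events by a subset of {station, week, weekday, hour_slot,
    day_of_year}.  Missing key combinations are reported as zero; counts sum
    to the total event count."""
    keys = list(keys)
    if not keys:
        raise ValueError("at least one aggregation key is required")
    bad = [k for k in keys if k not in AGGREGATION_KEYS]
    if bad:
        raise ValueError(f"unknown aggregation key(s): {bad}")
    df = _event_keys(events.frame)
    counts = df.groupby(keys, sort=True).size()
    # zero-fill the full key domain where it is known
    domains = []
    for k in keys:
        if k == "station":
            domains.append(
                registry.abbreviations
                if registry is not None
                else sorted(df["station"].unique())
            )
        else:
            domains.append(list(_KEY_DOMAINS[k](registry)))
    index = (
        pd.MultiIndex.from_product(domains, names=keys)
        if len(keys) > 1
        else pd.Index(domains[0], name=keys[0])
    )
    counts = counts.reindex(index, fill_value=0).astype(int)
    counts.name = "count"
    return counts


@dataclass
class CountCube:
    """Counts indexed (station, day_of_year, hour_slot)."""

    stations: list[str]
    counts: np.ndarray  # shape (n_stations, 365, 24), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (len(self.stations), DAYS_PER_YEAR, HOURS_PER_DAY)
        if self.counts.shape != expected:
            raise ValueError(f"count cube shape {self.counts.shape} != {expected}")
        if (self.counts < 0).any():
            raise ValueError("count cube entries must be non-negative")

    @classmethod
    def from_events(
        cls, events: CallEventTable, registry: StationRegistry
    ) -> "CountCube":
        events.validate(registry)
        stations = registry.abbreviations
        counts = np.zeros((len(stations), DAYS_PER_YEAR, HOURS_PER_DAY), dtype=int)
        idx = {s: i for i, s in enumerate(stations)}
        df = _event_keys(events.frame)
        for (station, doy, hour), n in df.groupby(
            ["station", "day_of_year", "hour_slot"]
        ).size().items():
            counts[idx[station], doy - 1, hour] = n
        return cls(stations, counts)

    def total(self) -> int:
        return int(self.counts.sum())

    def station_index(self, key: str) -> int:
        try:
            return self.stations.index(key)
        except ValueError:
            raise KeyError(f"unknown station {key!r}") from None


# ---------------------------------------------------------------------------
# hourly profiles
# ---------------------------------------------------------------------------


@dataclass
class HourlyProfile:
    """24 per-slot demand rates (operations per hour slot per day).

    ``rates[h]`` is the annual number of operations in clock-hour slot
    ``[h:00, h+1:00)`` divided by 365.
    """

    station_or_group: str
    rates: np.ndarray = field(default_factory=lambda: np.zeros(HOURS_PER_DAY))

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (HOURS_PER_DAY,):
            raise ValueError("an hourly profile needs exactly 24 rates")
        if (self.rates < 0).any():
            raise ValueError("hourly rates must be non-negative")

    @property
    def annual_total(self) -> float:
        return float(self.rates.sum() * DAYS_PER_YEAR)

    def __add__(self, other: "HourlyProfile") -> "HourlyProfile":
        return HourlyProfile(
            f"{self.station_or_group}+{other.station_or_group}",
            self.rates + other.rates,
        )


def hourly_profile(cube: CountCube, station_or_group) -> HourlyProfile:
    """Per-slot rates of one station or the element-wise sum of a group."""
    if isinstance(station_or_group, str):
        members = [station_or_group]
    else:
        members = list(station_or_group)
    if not members:
        raise ValueError("station_or_group must name at least one station")
    rows = [cube.counts[cube.station_index(m)] for m in members]
    slot_totals = np.sum(rows, axis=0).sum(axis=0)  # sum over days -> 24 slots
    return HourlyProfile("+".join(members), slot_totals / DAYS_PER_YEAR)


def flat_profile(name: str, annual_total: float) -> HourlyProfile:
    """A diurnally flat profile with the given annual volume.

    Used when only a station's annual count is known: every slot gets
    ``annual_total / (365 * 24)`` operations per hour, so the average
    workload with a single round-the-clock paramedic equals
    ``annual_total / 8760``.
    """
    rates = np.full(HOURS_PER_DAY, annual_total / (DAYS_PER_YEAR * HOURS_PER_DAY))
    return HourlyProfile(name, rates)
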