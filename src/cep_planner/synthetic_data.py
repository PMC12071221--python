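"""Synthetic call-event generator with calendar structure.

Emulates one study year of non-time-critical dispatch events: for station
``s``, day ``d`` and hour slot ``h`` the event count is Poisson with

    lambda_sdh = base_s * shape_h * weekly(weekday_d) * yearly(doy_d)
                 * uplift(flags_d)

where ``shape`` is a 24-slot diurnal profile summing to one, ``weekly`` and
``yearly`` are cosine modulations, and ``uplift`` multiplies the intensity
on school-break, legal-holiday and event days.  ``base_s`` is calibrated in
closed form so the expected annual total equals the configured per-station
volume exactly.  Composition is multiplicative so intensities stay
non-negative; the additive seasonal model is fitted to these data anyway,
which doubles as a robustness check of the fitting stage.

One master seed drives everything; each station gets its own deterministic
substream, so the output is bit-identical for a given seed regardless of
how many stations are generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    DAYS_PER_YEAR,
    HOURS_PER_DAY,
    CalendarDay,
    CallEventTable,
    StationRegistry,
    load_wandsbek_profile,
)

DEFAULT_UPLIFTS = {"break": 1.10, "holiday": 1.05, "event": 1.20}

# day-of-year around which the smooth yearly modulation peaks (mid July)
YEARLY_PEAK_DOY = 196


@dataclass
class GeneratorConfig:
    year: int
    annual_volumes: dict[str, float]  # station abbr -> expected annual count
    transport_probabilities: dict[str, float]
    diurnal_shape: np.ndarray  # 24 weights, normalized to sum 1
    weekly_amplitude: float = 0.03
    yearly_amplitude: float = 0.10
    uplifts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UPLIFTS))
    seed: int = 0

    def __post_init__(self) -> None:
        shape = np.asarray(self.diurnal_shape, dtype=float)
        if shape.shape != (HOURS_PER_DAY,):
            raise ValueError("diurnal_shape needs exactly 24 weights")
        if (shape < 0).any() or shape.sum() <= 0:
            raise ValueError("diurnal_shape weights must be non-negative, sum > 0")
        self.diurnal_shape = shape / shape.sum()
        for s, v in self.annual_volumes.items():
            if v < 0:
                raise ValueError(f"negative annual volume for {s!r}")
        for s, p in self.transport_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transport probability for {s!r} outside [0, 1]")
        for k, u in self.uplifts.items():
            if u <= 0:
                raise ValueError(f"uplift {k!r} must be positive")
        if not (0 <= self.weekly_amplitude < 1 and 0 <= self.yearly_amplitude < 1):
            raise ValueError("seasonal amplitudes must lie in [0, 1)")


@dataclass(frozen=True)
class ScenarioMultipliers:
    """Area-level demand scaling, e.g. the observed pandemic-year increases
    of roughly +19% (East), +22% (South) and +14% (West) over the baseline
    year."""

    factors: Mapping[str, float] = field(
        default_factory=lambda: {"East": 1.19, "South": 1.22, "West": 1.14}
    )

    def __post_init__(self) -> None:
        for area, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"multiplier for {area!r} must be positive")


def default_config(
    registry: StationRegistry, year: int = 2019, seed: int = 0, **overrides
) -> GeneratorConfig:
    """Config calibrated to the registry's annual totals and transport
    split, with the packaged Wandsbek diurnal profile as the default shape."""
    shape = load_wandsbek_profile().rates
    return GeneratorConfig(
        year=year,
        annual_volumes={r.abbreviation: float(r.ops_total) for r in registry},
        transport_probabilities={
            r.abbreviation: (
                r.ops_with_transport / r.ops_total if r.ops_total else 0.0
            )
            for r in registry
        },
        diurnal_shape=shape,
        seed=seed,
        **overrides,
    )


def apply_scenario(
    config: GeneratorConfig,
    multipliers: ScenarioMultipliers,
    registry: StationRegistry,
) -> GeneratorConfig:
    """Scale each station's expected volume by its area's factor."""
    volumes = {}
    for abbr, volume in config.annual_volumes.items():
        area = registry[abbr].area
        if area not in multipliers.factors:
            raise ValueError(f"no multiplier for area {area!r}")
        volumes[abbr] = volume * multipliers.factors[area]
    return replace(config, annual_volumes=volumes)


def _day_modulation(
    config: GeneratorConfig, calendar: Sequence[CalendarDay]
) -> np.ndarray:
    """Per-day multiplicative factor (weekly x yearly x uplifts), length 365."""
    if len(calendar) != DAYS_PER_YEAR:
        raise ValueError("calendar must cover the full 365-day year")
    mod = np.empty(DAYS_PER_YEAR)
    for i, day in enumerate(calendar):
        weekly = 1.0 + config.weekly_amplitude * math.cos(
            2 * math.pi * (day.weekday - 1) / 7
        )
        yearly = 1.0 + config.yearly_amplitude * math.cos(
            2 * math.pi * (day.day_of_year - YEARLY_PEAK_DOY) / DAYS_PER_YEAR
        )
        uplift = 1.0
        if day.is_break:
            uplift *= config.uplifts.get("break", 1.0)
        if day.is_holiday:
            uplift *= config.uplifts.get("holiday", 1.0)
        if day.is_event:
            uplift *= config.uplifts.get("event", 1.0)
        mod[i] = weekly * yearly * uplift
    return mod


def expected_intensity(
    config: GeneratorConfig,
    registry: StationRegistry,
    calendar: Sequence[CalendarDay],
) -> dict[str, np.ndarray]:
    """Expected counts lambda_sdh per station, shape (365, 24).

    Each station's grid sums exactly to its configured annual volume: the
    base rate is ``volume / sum_d modulation(d)`` and the diurnal shape
    sums to one.
    """
    mod = _day_modulation(config, calendar)
    out = {}
    for abbr in sorted(config.annual_volumes):
        if abbr not in registry:
            raise ValueError(f"configured station {abbr!r} not in registry")
        volume = config.annual_volumes[abbr]
        base = volume / mod.sum()
        out[abbr] = base * np.outer(mod, config.diurnal_shape)
    return out


def generate_year(
    registry: StationRegistry,
    calendar: Sequence[CalendarDay],
    config: GeneratorConfig,
) -> CallEventTable:
    """Draw one year of events; bit-identical for a given seed."""
    lambdas = expected_intensity(config, registry, calendar)
    dates = [day.date for day in calendar]
    frames = []
    for idx, abbr in enumerate(sorted(lambdas)):
        rng = np.random.default_rng([config.seed, idx])
        counts = rng.poisson(lambdas[abbr])  # (365, 24)
        day_idx, hour_idx = np.nonzero(counts)
        reps = counts[day_idx, hour_idx]
        if reps.sum() == 0:
            continue
        rows_day = np.repeat(day_idx, reps)
        rows_hour = np.repeat(hour_idx, reps)
        transported = rng.random(rows_day.size) < config.transport_probabilities.get(
            abbr, 0.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "station": abbr,
                    "date": [dates[d] for d in rows_day],
                    "hour": rows_hour,
                    "transported": transported,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(
            {
                "station": pd.Series(dtype=str),
                "date": pd.Series(dtype=object),
                "hour": pd.Series(dtype=int),
                "transported": pd.Series(dtype=bool),
            }
        )
    return CallEventTable(df)
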