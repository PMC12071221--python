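import numpy as np
import pytest

from cep_planner.core_data import (
    load_default_calendar,
    load_default_registry,
    load_wandsbek_profile,
    load_weekday_totals,
)


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def calendar():
    return load_default_calendar()


@pytest.fixture(scope="session")
def wandsbek_profile():
    return load_wandsbek_profile()


@pytest.fixture(scope="session")
def weekday_totals():
    return load_weekday_totals()


@pytest.fixture(scope="session")
def density_groups(registry):
    """Population densities grouped by operational area (East, South, West)."""
    return [
        [r.density for r in registry.stations_in_area(area)]
        for area in ("East", "South", "West")
    ]


@pytest.fixture(scope="session")
def small_events(registry, calendar):
    """A small deterministic synthetic year (reduced volumes) for
    aggregation tests."""
    from cep_planner.synthetic_data import default_config, generate_year

    config = default_config(registry, seed=42)
    config.annual_volumes = {
        abbr: vol / 10 for abbr, vol in config.annual_volumes.items()
    }
    return generate_year(registry, calendar, config)
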