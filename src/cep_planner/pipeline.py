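"""End-to-end orchestration: one call reproduces the full station-level
analysis (descriptive statistics, clustering, seasonal model, workload and
strategy comparison) from packaged fixtures, synthetic events or an event
CSV, writing a report bundle plus a hash manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as _clustering
from . import demand_stats as _stats
from . import seasonal_model as _seasonal
from . import synthetic_data as _synth
from . import workload_planner as _wl
from .core_data import (
    CallEventTable,
    CountCube,
    StationRegistry,
    aggregate,
    build_calendar,
    calendar_to_frame,
    flat_profile,
    hourly_profile,
    load_calendar_definitions,
    load_default_registry,
    load_station_table,
    load_wandsbek_profile,
)

INPUT_MODES = ("fixtures", "synthetic", "events")


@dataclass
class RunConfig:
    mode: str = "fixtures"
    seed: int = 0
    output_dir: str | Path = "cep_report"
    registry_path: str | Path | None = None
    calendar_path: str | Path | None = None
    events_path: str | Path | None = None
    strategies: tuple[str, ...] | None = None  # None = full catalogue
    operation_time: float = 60.0
    scenario_2021: bool = False
    seasonal_bootstrap: int = 200

    def __post_init__(self) -> None:
        if self.mode not in INPUT_MODES:
            raise ValueError(f"input mode must be one of {INPUT_MODES}")
        if self.mode == "events" and self.events_path is None:
            raise ValueError("events mode requires events_path")


def _load_registry(config: RunConfig) -> StationRegistry:
    if config.registry_path is None:
        return load_default_registry()
    path = Path(config.registry_path)
    if not path.exists():
        raise FileNotFoundError(f"missing registry file: {path}")
    return load_station_table(path)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def compute_stats(registry: StationRegistry) -> dict:
    """The registry-level statistical battery as a JSON-ready dict."""
    densities = {
        area: [r.density for r in registry.stations_in_area(area)]
        for area in ("East", "South", "West")
    }
    groups = [densities["East"], densities["South"], densities["West"]]
    kw = _stats.kruskal_wallis(groups)
    dunn = _stats.dunn_bonferroni(groups)
    area_names = ["East", "South", "West"]
    totals = [r.ops_total for r in registry]
    without = [r.ops_without_transport for r in registry]
    sp_transport = _stats.spearman(totals, without)
    return {
        "kruskal_wallis_density": {
            "H": round(kw.H, 3),
            "df": kw.df,
            "p": round(kw.p, 3),
        },
        "dunn_density": {
            f"{area_names[d.group_a]}-{area_names[d.group_b]}": {
                "z": round(d.z, 3),
                "p_raw": round(d.p_raw, 3),
                "p_adj": round(d.p_adj, 3),
            }
            for d in dunn
        },
        "spearman_total_vs_without": {
            "rho": round(sp_transport.rho, 2),
            "p": round(sp_transport.p, 3),
        },
        "total_operations": registry.total_operations(),
        "weekly_average": round(registry.total_operations() / 52, 2),
    }


def compute_weekday_stats(weekday_totals: pd.DataFrame) -> dict:
    """Weekday-effect statistics from a (weekday, count) table."""
    x = weekday_totals["weekday"].to_numpy(dtype=float)
    y = weekday_totals["count"].to_numpy(dtype=float)
    sp = _stats.spearman(x, y)
    ols = _stats.ols_with_durbin_watson(x, y)
    return {
        "spearman": {"rho": round(sp.rho, 2), "p": round(sp.p, 3)},
        "ols": {
            "r_squared": round(ols.r_squared, 2),
            "adj_r_squared": round(ols.adj_r_squared, 2),
            "p_slope": round(ols.p_slope, 3),
            "dw_stat": round(ols.dw_stat, 3),
        },
        "daily_average": round(float(y.mean()), 2),
    }


def station_profiles(
    registry: StationRegistry, cube: CountCube | None
) -> dict[str, "object"]:
    """Hourly profiles per station name.

    With an event cube, profiles come from the observed slot counts; without
    one (fixtures mode) the packaged Wandsbek profile is used for Wandsbek
    and diurnally flat profiles, scaled to each station's annual total, for
    the rest.
    """
    profiles = {}
    for record in registry:
        if cube is not None:
            prof = hourly_profile(cube, record.abbreviation)
            prof.station_or_group = record.name
        elif record.name == "Wandsbek":
            prof = load_wandsbek_profile()
        else:
            prof = flat_profile(record.name, record.ops_total)
        profiles[record.name] = prof
    return profiles


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = _load_registry(config)
    cal_defs = load_calendar_definitions(config.calendar_path)
    calendar = build_calendar(int(cal_defs["year"]), cal_defs)
    written: list[Path] = []

    # --- events ------------------------------------------------------------
    events = None
    if config.mode == "synthetic":
        gen_config = _synth.default_config(registry, seed=config.seed)
        if config.scenario_2021:
            gen_config = _synth.apply_scenario(
                gen_config, _synth.ScenarioMultipliers(), registry
            )
        events = _synth.generate_year(registry, calendar, gen_config)
        events_path = outdir / "events.csv"
        events.to_csv(events_path)
        written.append(events_path)
    elif config.mode == "events":
        path = Path(config.events_path)
        if not path.exists():
            raise FileNotFoundError(f"missing events file: {path}")
        events = CallEventTable.read_csv(path)
        events.validate(registry)

    cube = CountCube.from_events(events, registry) if events is not None else None

    # --- statistics ---------------------------------------------------------
    stats_payload = compute_stats(registry)
    if events is not None:
        weekday = aggregate(events, ["weekday"], registry)
        weekday_df = pd.DataFrame(
            {"weekday": weekday.index, "count": weekday.to_numpy()}
        )
    else:
        from .core_data import load_weekday_totals

        weekday_df = load_weekday_totals()
    stats_payload["weekday_effects"] = compute_weekday_stats(weekday_df)
    stats_path = outdir / "stats.json"
    _write_json(stats_path, stats_payload)
    written.append(stats_path)

    # --- clustering ---------------------------------------------------------
    assignment = _clustering.cluster_stations(registry, k=5)
    X, names = _clustering.station_features(registry)
    tree = _clustering.average_linkage(_clustering.distance_matrix(X), names)
    cluster_path = outdir / "clusters.json"
    _write_json(
        cluster_path,
        {
            "k": assignment.k,
            "labels": assignment.labels,
            "clusters": assignment.clusters(),
            "dendrogram_newick": _clustering.to_newick(tree),
        },
    )
    written.append(cluster_path)

    # --- seasonal model (needs an event series) ------------------------------
    if events is not None:
        cal_frame = calendar_to_frame(calendar)
        daily = aggregate(events, ["day_of_year"], registry).to_numpy(dtype=float)
        flags = {
            "is_break": cal_frame["is_break"].to_numpy(dtype=float),
            "is_holiday": cal_frame["is_holiday"].to_numpy(dtype=float),
            "is_event": cal_frame["is_event"].to_numpy(dtype=float),
        }
        fit_daily = _seasonal.fit(
            daily,
            _seasonal.DEFAULT_DAILY_TOTALS_SPEC,
            flags=flags,
            n_boot=config.seasonal_bootstrap,
            seed=config.seed,
        )
        report = _seasonal.component_report(fit_daily)
        hourly = aggregate(events, ["day_of_year", "hour_slot"], registry).to_numpy(
            dtype=float
        )
        fit_hourly = _seasonal.fit(
            hourly,
            _seasonal.DEFAULT_DAILY_SPEC,
            n_boot=min(config.seasonal_bootstrap, 100),
            seed=config.seed,
        )
        hourly_report = _seasonal.component_report(fit_hourly)
        seasonal_path = outdir / "seasonal.json"
        _write_json(
            seasonal_path,
            {
                "daily_totals_model": {
                    "noise_scale": round(fit_daily.noise_scale, 3),
                    "components": report.to_dict(orient="records"),
                },
                "hourly_model": {
                    "noise_scale": round(fit_hourly.noise_scale, 3),
                    "components": hourly_report.to_dict(orient="records"),
                },
            },
        )
        written.append(seasonal_path)

    # --- workload & strategies ----------------------------------------------
    profiles = station_profiles(registry, cube)
    catalogue = _wl.builtin_strategies()
    if config.strategies:
        unknown = [s for s in config.strategies if s not in catalogue]
        if unknown:
            raise ValueError(f"unknown strategy id(s): {unknown}")
        catalogue = {s: catalogue[s] for s in config.strategies}
    comparison = _wl.evaluate_strategies(
        registry, profiles, catalogue, operation_time=config.operation_time
    )
    comparison_path = outdir / "strategy_comparison.csv"
    comparison.to_csv(comparison_path, index=False)
    written.append(comparison_path)
    workload_rows = []
    for name, prof in profiles.items():
        table = _wl.station_workload_table(prof, operation_time=config.operation_time)
        workload_rows.append(
            {
                "station": name,
                "average_workload_pct": round(table.average_workload, 2),
                "n_over85": table.n_over85,
                "n_over100": table.n_over100,
            }
        )
    workload_path = outdir / "station_workloads.csv"
    pd.DataFrame(workload_rows).to_csv(workload_path, index=False)
    written.append(workload_path)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def write_report(bundle: pd.DataFrame, path: str | Path, format: str = "csv") -> Path:
    """Write a comparison table as CSV or JSON; reading it back round-trips."""
    path = Path(path)
    if format == "csv":
        bundle.to_csv(path, index=False)
    elif format == "json":
        path.write_text(
            json.dumps(bundle.to_dict(orient="records"), indent=2, sort_keys=True)
            + "\n",
            encoding="utf-8",
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
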