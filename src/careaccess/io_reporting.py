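"""Readers, writers, validation and the end-to-end pipeline runner.

CSV (UTF-8, RFC 4180, '.' decimal separator) is the single interchange
format: every table the pipeline writes can be re-read by the reader in this
module, and a JSON manifest (seed, epsilon, k, version) makes a run
reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import MODES, PipelineConfig
from .covid_change import change_table, cross_country_change, mode_share_change
from .dp_release import RELEASE_COLUMNS, release_all
from .metrics import country_comparison_table, count_countries, cross_country_summary
from .outcomes import adjusted_association, spearman
from .potential_access import SpeedModelProvider, country_potential_summary
from .synthetic_data import (
    TRIP_COLUMNS,
    generate_outcomes,
    generate_population_grid,
    generate_trips,
    place_facilities,
)

__all__ = [
    "StageError",
    "write_csv",
    "read_trips",
    "read_releases",
    "load_supplementary",
    "run_pipeline",
]

log = logging.getLogger("careaccess")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the offending slice."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_trips(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str, "country": str, "mode": str,
                                  "origin_cell": str, "facility_id": str})
    missing = [c for c in TRIP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trip table missing columns: {missing}")
    return df[TRIP_COLUMNS]


def read_releases(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"country": str, "mode": str})
    missing = [c for c in RELEASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"release table missing columns: {missing}")
    df["suppressed"] = df["suppressed"].astype(bool)
    return df[RELEASE_COLUMNS]


def load_supplementary(path_or_df, column_mapping: dict, unit: str = "minutes"):
    """Load a published-style per-country summary table through a column mapping.

    ``column_mapping`` maps our canonical names (country, p10, p25, p50, p75,
    p90, potential_weighted_mean, pct_change_time, abs_change_time, year,
    quarter, mode, ...) to the columns present in the file. ``unit`` is
    'minutes' or 'hours' for time-valued columns (hours are converted x60).
    Returns (records, report): rows that violate basic invariants (e.g. a
    percentile ladder out of order) are kept but flagged ``valid=False`` and
    listed in the report — never silently dropped.
    """
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [src for src in column_mapping.values() if src not in df.columns]
    if missing:
        raise ValueError(
            f"mapped columns {missing} not present; available headers: {list(df.columns)}"
        )
    out = pd.DataFrame({ours: df[theirs] for ours, theirs in column_mapping.items()})
    if unit not in ("minutes", "hours"):
        raise ValueError(f"unit must be 'minutes' or 'hours', got {unit!r}")
    time_cols = [c for c in out.columns
                 if c.startswith("p") and c[1:].isdigit() or c in ("abs_change_time", "potential_weighted_mean", "potential_weighted_median", "baseline_median_time")]
    if unit == "hours":
        out[time_cols] = out[time_cols].astype(float) * 60.0
    report = []
    valid = np.ones(len(out), dtype=bool)
    ladder = [c for c in ("p10", "p25", "p50", "p75", "p90") if c in out.columns]
    if len(ladder) >= 2:
        vals = out[ladder].astype(float).to_numpy()
        bad = (np.diff(vals, axis=1) < 0).any(axis=1)
        for i in np.flatnonzero(bad):
            report.append({"row": int(i), "problem": "percentile ladder not non-decreasing"})
        valid &= ~bad
    for c in ladder:
        neg = out[c].astype(float) < 0
        for i in np.flatnonzero(neg.to_numpy()):
            report.append({"row": int(i), "problem": f"negative value in {c}"})
        valid &= ~neg.to_numpy()
    out["valid"] = valid
    return out, report


def _country_extent(i: int) -> tuple[float, float, float, float]:
    """Disjoint ~50 km square per country, spread along the equator."""
    lon0 = -170.0 + (i % 68) * 5.0
    lat0 = 5.0 * ((i // 68) % 8)
    return (lat0, lat0 + 0.45, lon0, lon0 + 0.45)


def simulate_world(config: PipelineConfig):
    """Generate cells, facilities and trips for every country in the scenario."""
    scen = config.scenario
    cells_frames, fac_frames = [], []
    for i, country in enumerate(scen.countries):
        cells = generate_population_grid(
            _country_extent(i), config.n_cells_per_country, scen.seed, country=country
        )
        cells_frames.append(cells)
        fac_frames.append(place_facilities(cells, config.n_facilities_per_country, scen.seed))
    cells = pd.concat(cells_frames, ignore_index=True)
    facilities = pd.concat(fac_frames, ignore_index=True)
    trips = generate_trips(scen, cells, facilities)
    return cells, facilities, trips


def _aggregate_2019_revealed(releases: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Year-2019 per-country revealed summary: mean of unsuppressed quarterly percentiles."""
    sel = releases[(releases["year"] == 2019) & (releases["mode"] == mode) & (~releases["suppressed"])]
    if sel.empty:
        return pd.DataFrame(columns=["country", "p10", "p25", "p50", "p75", "p90", "suppressed"])
    agg = sel.groupby("country", as_index=False)[["p10", "p25", "p50", "p75", "p90"]].mean()
    agg["suppressed"] = False
    return agg


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """simulate -> release -> potential -> metrics -> covid -> associate.

    Writes every table as CSV plus a manifest; identical config (including
    seeds) yields byte-identical outputs. Returns a dict of the in-memory
    tables and headline numbers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scen = config.scenario
    bundle: dict = {}

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage context is the point
            raise StageError(name, str(exc)) from exc

    cells, facilities, trips = stage("simulate", lambda: simulate_world(config))
    write_csv(cells, outdir / "cells.csv")
    write_csv(facilities, outdir / "facilities.csv")
    write_csv(trips, outdir / "trips.csv")
    bundle.update(cells=cells, facilities=facilities, trips=trips)

    releases = stage("release", lambda: release_all(trips, config.budget, config.dp))
    write_csv(releases, outdir / "releases.csv")
    bundle["releases"] = releases

    def _potential():
        provider = SpeedModelProvider(dict(scen.mode_speeds), scen.detour_factor)
        frames = []
        for country in scen.countries:
            ccells = cells[cells["country"] == country]
            cfac = facilities[facilities["country"] == country]
            summary = country_potential_summary(
                ccells, cfac, MODES, provider, thresholds=config.time_thresholds_min
            )
            summary.insert(0, "country", country)
            frames.append(summary)
        return pd.concat(frames, ignore_index=True)

    potential = stage("potential", _potential)
    write_csv(potential, outdir / "potential.csv")
    bundle["potential"] = potential

    def _metrics():
        revealed_2019 = _aggregate_2019_revealed(releases, "passenger_vehicle")
        pot_car = potential[potential["mode"] == "passenger_vehicle"]
        table = country_comparison_table(revealed_2019, pot_car)
        stats = {
            "cross_country_median_p50_min": cross_country_summary(table, "p50"),
            "n_countries": int(table["country"].nunique()),
        }
        for th in config.time_thresholds_min:
            stats[f"n_countries_p90_gt_{int(th)}"] = count_countries(
                table, lambda d, th=th: d["p90"] > th
            )
        for f in config.ratio_factors:
            stats[f"n_countries_factor_ge_{int(f)}"] = count_countries(
                table, lambda d, f=f: d["ratio_factor"] >= f
            )
        return table, stats

    country_metrics, metric_stats = stage("metrics", _metrics)
    write_csv(country_metrics, outdir / "country_metrics.csv")
    bundle["country_metrics"] = country_metrics
    bundle["metric_stats"] = metric_stats

    def _covid():
        dist_med = (
            trips.groupby(["country", "mode", "year", "quarter"], as_index=False)["distance_km"]
            .median()
            .rename(columns={"distance_km": "distance_median_km"})
        )
        changes = change_table(releases, dist_med)
        rows = []
        for (year, quarter) in sorted({(y, q) for y, q in zip(changes["year"], changes["quarter"])}):
            for mode in MODES:
                sel = changes[(changes["mode"] == mode) & (changes["year"] == year) & (changes["quarter"] == quarter)]
                if len(sel) == 0:
                    continue
                cc = cross_country_change(changes, mode, (int(year), int(quarter)))
                rows.append({
                    "mode": mode, "year": year, "quarter": quarter,
                    "median_pct_change": cc.median_pct_change,
                    "median_abs_change": cc.median_abs_change,
                    "t_statistic": cc.t_statistic, "p_value": cc.p_value,
                    "n_countries": cc.n_countries,
                })
        counts = (
            trips[trips["year"].isin([2019, 2020])]
            .groupby(["mode", "year"], as_index=False)
            .size()
            .rename(columns={"size": "n_trips"})
        )
        shares = mode_share_change(counts)
        return changes, pd.DataFrame(rows), shares

    changes, cross_changes, shares = stage("covid", _covid)
    write_csv(changes, outdir / "changes.csv")
    write_csv(cross_changes, outdir / "cross_country_changes.csv")
    write_csv(shares, outdir / "mode_shares.csv")
    bundle.update(changes=changes, cross_country_changes=cross_changes, mode_shares=shares)

    def _associate():
        true_median = {
            c: float(np.exp(scen.time_params[c]["passenger_vehicle"][0])) for c in scen.countries
        }
        outcomes_df = generate_outcomes(true_median, scen.seed)
        joined = bundle["country_metrics"].merge(outcomes_df, on="country", how="inner")
        results = []
        if len(joined) >= 3:
            for outcome in ("life_expectancy", "infant_mortality"):
                r = spearman(joined["p90"], joined[outcome], names=("revealed_p90", outcome))
                results.append({
                    "metric": "revealed_p90", "outcome": outcome,
                    "rho": r.rho, "p_value": r.p_value, "n": r.n, "kind": "spearman",
                })
            if len(joined) >= 5:
                adj = adjusted_association(
                    joined.rename(columns={"potential_weighted_mean": "potential_weighted"}),
                    "life_expectancy", "p90", ("potential_weighted", "gdp"),
                )
                results.append({
                    "metric": "revealed_p90", "outcome": "life_expectancy",
                    "rho": np.nan, "p_value": adj.p_value, "n": adj.n,
                    "kind": "ols_adjusted", "estimate": adj.estimate, "stderr": adj.stderr,
                })
        return outcomes_df, pd.DataFrame(results)

    outcomes_df, associations = stage("associate", _associate)
    write_csv(outcomes_df, outdir / "outcomes.csv")
    write_csv(associations, outdir / "associations.csv")
    bundle.update(outcomes=outcomes_df, associations=associations)

    manifest = {
        "package": "careaccess",
        "version": __version__,
        "seed": scen.seed,
        "dp_seed": config.dp.seed,
        "epsilon_total": config.budget.epsilon_total,
        "n_releases": config.budget.n_releases,
        "k_threshold": config.dp.k_threshold,
        "domain_minutes": [config.dp.domain_low, config.dp.domain_high],
        "countries": list(scen.countries),
        "quarters": [list(q) for q in scen.quarters],
        "n_users_per_country": scen.n_users_per_country,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
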