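"""Synthetic trip tables, population grids, facilities and outcome tables.

Every downstream stage (DP release, potential accessibility, metrics, change
analysis, outcome association) is exercisable on the output of this module
without any external download. The generator emulates the statistical
structure the analysis assumes:

* per-country heavy-tailed (lognormal) travel-time laws by transport mode;
* repeated visits per user (Poisson trip counts), so user-level contribution
  bounding has something to do;
* pandemic-quarter effects relative to the 2019 baseline: per-mode travel-time
  multipliers and a mode-share shift toward passenger vehicles;
* distances tied to times through constant mode speeds and a detour factor,
  so a pure time multiplier leaves the distance distribution unchanged —
  the "times changed, distances stable" pattern.

Trip tables are plain pandas DataFrames with columns
``user_id, country, year, quarter, mode, travel_time_min, distance_km,
origin_cell, facility_id``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._rng import substream
from .config import MODES, CovidEffect, ScenarioConfig
from .geo import haversine_km

__all__ = [
    "TRIP_COLUMNS",
    "generate_population_grid",
    "place_facilities",
    "generate_trips",
    "ground_truth_percentiles",
    "generate_outcomes",
    "synthetic_supplementary_tables",
]

TRIP_COLUMNS = [
    "user_id", "country", "year", "quarter", "mode",
    "travel_time_min", "distance_km", "origin_cell", "facility_id",
]

CELL_COLUMNS = ["cell_id", "centroid_lat", "centroid_lon", "population", "country"]


def _grid_shape(n_cells: int) -> tuple[int, int]:
    """Rows x cols tiling with rows*cols == n_cells, as square as possible."""
    nrows = max(1, int(np.sqrt(n_cells)))
    while n_cells % nrows:
        nrows -= 1
    return nrows, n_cells // nrows


def generate_population_grid(
    extent: tuple[float, float, float, float],
    n_cells: int,
    seed: int,
    mean_population: float = 200.0,
    zero_inflation: float = 0.25,
    sigma: float = 1.0,
    country: str = "XX",
) -> pd.DataFrame:
    """Tile ``extent`` = (lat_min, lat_max, lon_min, lon_max) into ``n_cells``
    cells with heavy-tailed populations.

    Populations are zero-inflated lognormal, rounded to integers, with overall
    mean ``mean_population`` (so some cells fall below the downstream
    minimum-population filter). Deterministic for a fixed seed.
    """
    lat_min, lat_max, lon_min, lon_max = extent
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if not lat_max > lat_min:
        raise ValueError(f"degenerate extent: lat_max ({lat_max}) must exceed lat_min ({lat_min})")
    if not lon_max > lon_min:
        raise ValueError(f"degenerate extent: lon_max ({lon_max}) must exceed lon_min ({lon_min})")
    if not (0.0 <= zero_inflation < 1.0):
        raise ValueError("zero_inflation must be in [0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")

    nrows, ncols = _grid_shape(n_cells)
    lat_centers = lat_min + (np.arange(nrows) + 0.5) * (lat_max - lat_min) / nrows
    lon_centers = lon_min + (np.arange(ncols) + 0.5) * (lon_max - lon_min) / ncols
    lat_grid, lon_grid = np.meshgrid(lat_centers, lon_centers, indexing="ij")

    rng = substream(seed, "population-grid", country)
    occupied_mean = mean_population / (1.0 - zero_inflation)
    if sigma == 0.0:
        pops = np.full(n_cells, occupied_mean)
    else:
        mu = np.log(occupied_mean) - sigma**2 / 2.0
        pops = rng.lognormal(mu, sigma, size=n_cells)
    if zero_inflation > 0:
        pops = np.where(rng.random(n_cells) < zero_inflation, 0.0, pops)
    return pd.DataFrame(
        {
            "cell_id": [f"{country}_cell{i:06d}" for i in range(n_cells)],
            "centroid_lat": lat_grid.ravel(),
            "centroid_lon": lon_grid.ravel(),
            "population": np.rint(pops).astype(np.int64),
            "country": country,
        }
    )


def place_facilities(cells: pd.DataFrame, n_facilities: int, seed: int) -> pd.DataFrame:
    """Place facilities at cell centroids, probability proportional to population,
    without replacement."""
    if n_facilities < 1:
        raise ValueError("n_facilities must be >= 1")
    populated = cells[cells["population"] > 0]
    if populated.empty:
        raise ValueError("no populated cells to place facilities in")
    if n_facilities > len(populated):
        raise ValueError(
            f"n_facilities ({n_facilities}) exceeds the number of populated cells ({len(populated)})"
        )
    country = str(populated["country"].iloc[0]) if "country" in populated else "XX"
    rng = substream(seed, "facilities", country)
    probs = populated["population"].to_numpy(dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(populated), size=n_facilities, replace=False, p=probs)
    chosen = populated.iloc[np.sort(idx)]
    return pd.DataFrame(
        {
            "facility_id": [f"{country}_fac{i:04d}" for i in range(n_facilities)],
            "lat": chosen["centroid_lat"].to_numpy(),
            "lon": chosen["centroid_lon"].to_numpy(),
            "country": country,
        }
    )


def _shifted_shares(shares: dict, effect: CovidEffect) -> dict:
    """Shift probability mass toward passenger vehicles."""
    s = effect.mode_shift
    if s == 0.0:
        return dict(shares)
    car = shares["passenger_vehicle"]
    new_car = car + s * (1.0 - car)
    scale = (1.0 - new_car) / (1.0 - car) if car < 1.0 else 0.0
    out = {m: p * scale for m, p in shares.items() if m != "passenger_vehicle"}
    out["passenger_vehicle"] = new_car
    return out


def _nearest_facility_ids(cells: pd.DataFrame, facilities: pd.DataFrame) -> np.ndarray:
    """facility_id of the nearest facility for each cell row (ties: smallest id)."""
    fac = facilities.sort_values("facility_id")
    d = haversine_km(
        cells["centroid_lat"].to_numpy()[:, None],
        cells["centroid_lon"].to_numpy()[:, None],
        fac["lat"].to_numpy()[None, :],
        fac["lon"].to_numpy()[None, :],
    )
    return fac["facility_id"].to_numpy()[np.argmin(d, axis=1)]


def generate_trips(
    config: ScenarioConfig,
    cells: pd.DataFrame | None = None,
    facilities: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate the full synthetic trip table for a scenario.

    Each user has a population-weighted home cell; per quarter their trip
    count is Poisson(trips_per_user_mean); each trip's mode follows the
    (pandemic-shifted) mode shares, its travel time the per-(country, mode)
    lognormal law times the quarter's mode multiplier, and its distance
    ``time/60 * mode_speed / detour_factor``. Deterministic under the
    scenario seed; per-country substreams make countries independent.

    ``cells``/``facilities`` may be omitted, in which case origin cells and
    facility assignments are synthesized from a single unlocated cell per
    country (useful when only the time/mode structure matters).
    """
    frames = []
    for country in config.countries:
        shares = config.mode_shares[country]
        tparams = config.time_params[country]
        for mode in shares:
            if mode not in MODES:
                raise KeyError(f"unknown mode {mode!r} for country {country!r}")
            if mode not in tparams:
                raise KeyError(f"no time parameters for ({country!r}, {mode!r})")
            if mode not in config.mode_speeds:
                raise KeyError(f"no speed configured for mode {mode!r}")

        n_users = config.n_users_per_country
        if cells is not None:
            ccells = cells[(cells["country"] == country) & (cells["population"] > 0)]
            if ccells.empty:
                raise KeyError(f"no populated cells for country {country!r}")
            w = ccells["population"].to_numpy(dtype=float)
            home_rng = substream(config.seed, "homes", country)
            home_idx = home_rng.choice(len(ccells), size=n_users, p=w / w.sum())
            home_cells = ccells["cell_id"].to_numpy()[home_idx]
            if facilities is not None:
                cfac = facilities[facilities["country"] == country]
                if cfac.empty:
                    raise KeyError(f"no facilities for country {country!r}")
                cell_fac = dict(zip(ccells["cell_id"], _nearest_facility_ids(ccells, cfac)))
                home_facility = np.array([cell_fac[c] for c in home_cells])
            else:
                home_facility = np.array([f"{country}_fac0000"] * n_users)
        else:
            home_cells = np.array([f"{country}_cell000000"] * n_users)
            home_facility = np.array([f"{country}_fac0000"] * n_users)
        user_ids = np.array([f"{country}_u{i:06d}" for i in range(n_users)])

        for (year, quarter) in config.quarters:
            effect = config.covid_effects.get((year, quarter), CovidEffect())
            q_shares = _shifted_shares(shares, effect) if year >= 2020 else dict(shares)
            rng = substream(config.seed, "trips", country, year, quarter)
            counts = rng.poisson(config.trips_per_user_mean, size=n_users)
            total = int(counts.sum())
            if total == 0:
                continue
            ridx = np.repeat(np.arange(n_users), counts)
            mode_names = list(q_shares)
            mode_idx = rng.choice(len(mode_names), size=total, p=[q_shares[m] for m in mode_names])
            times = np.empty(total)
            dists = np.empty(total)
            for j, mode in enumerate(mode_names):
                sel = mode_idx == j
                n_sel = int(sel.sum())
                if n_sel == 0:
                    continue
                mu, sd = tparams[mode]
                mult = effect.time_multiplier(mode) if year >= 2020 else 1.0
                t = rng.lognormal(mu, sd, size=n_sel) * mult
                times[sel] = t
                dists[sel] = t / 60.0 * config.mode_speeds[mode] / config.detour_factor
            frames.append(
                pd.DataFrame(
                    {
                        "user_id": user_ids[ridx],
                        "country": country,
                        "year": year,
                        "quarter": quarter,
                        "mode": np.array(mode_names, dtype=object)[mode_idx],
                        "travel_time_min": times,
                        "distance_km": dists,
                        "origin_cell": home_cells[ridx],
                        "facility_id": home_facility[ridx],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=TRIP_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRIP_COLUMNS]


def ground_truth_percentiles(trips: pd.DataFrame, slice_key, quantiles, seed: int):
    """Exact (no-noise) percentiles of the bounded-contribution sample.

    Applies the same one-trip-per-user uniform sampling rule (and seed) as
    the DP release, then evaluates exact empirical quantiles with the linear
    interpolation convention. Serves as the oracle the DP mechanism is
    compared against. Returns None for an empty slice — never zero.
    """
    from .dp_release import bound_contributions  # local import avoids a cycle at import time

    bounded = bound_contributions(trips, slice_key, seed)
    if bounded.empty:
        return None
    values = bounded["travel_time_min"].to_numpy(dtype=float)
    qs = np.atleast_1d(np.asarray(quantiles, dtype=float))
    return dict(zip((float(q) for q in qs), np.percentile(values, qs, method="linear")))


def generate_outcomes(
    country_severity: pd.Series | dict,
    seed: int,
    noise_sd: float = 2.0,
    link_sign: int = -1,
) -> pd.DataFrame:
    """Synthetic country-level outcome table with a planted monotone link.

    ``country_severity`` maps country -> an accessibility burden (e.g. the
    true median or p90 travel time in minutes). Life expectancy decreases
    with severity (sign controlled by ``link_sign``), infant mortality moves
    oppositely, and GDP per capita declines log-linearly with severity.
    """
    sev = pd.Series(country_severity, dtype=float).sort_index()
    rng = substream(seed, "outcomes")
    z = (sev - sev.mean()) / (sev.std(ddof=0) or 1.0)
    life = 72.0 + link_sign * 5.0 * z + rng.normal(0.0, noise_sd, len(sev))
    infant = np.maximum(1.0, 25.0 - link_sign * 12.0 * z + rng.normal(0.0, 2.0 * noise_sd, len(sev)))
    gdp = np.exp(9.5 + link_sign * 0.8 * z + rng.normal(0.0, 0.3, len(sev)))
    return pd.DataFrame(
        {
            "country": sev.index,
            "life_expectancy": np.clip(life, 35.0, 95.0),
            "infant_mortality": infant,
            "gdp": gdp,
        }
    ).reset_index(drop=True)


def synthetic_supplementary_tables(n_countries: int = 120, seed: int = 7):
    """Synthetic stand-in for a published per-country summary bundle.

    The genuine supplementary tables of the study (per-country revealed
    percentiles, aggregated potential times and change-by-quarter records)
    are not redistributable here, so this builds tables with the same schema
    and realistic structure: heavy-tailed per-country percentile ladders,
    potential times below revealed p90 for most countries, and
    pandemic-quarter change records. Returns a dict with keys
    ``revealed`` (country, year, mode, p10..p90, noisy_count, suppressed),
    ``potential`` (country, mode, potential_weighted_mean,
    potential_weighted_median) and ``changes`` (country, mode, year, quarter,
    pct_change_time, abs_change_time, pct_change_distance).
    """
    rng = substream(seed, "synthetic-supplementary")
    countries = [f"S{i:03d}" for i in range(n_countries)]
    med = np.exp(rng.normal(np.log(30.0), 0.55, n_countries))  # country medians, min
    spread = 1.6 + rng.gamma(2.0, 0.5, n_countries)  # p75/p25 style spread
    p25 = med / np.sqrt(spread)
    p75 = med * np.sqrt(spread)
    p10 = p25 * (0.45 + 0.2 * rng.random(n_countries))
    p90 = p75 * (1.6 + rng.gamma(2.0, 0.45, n_countries))
    revealed = pd.DataFrame(
        {
            "country": countries,
            "year": 2019,
            "mode": "passenger_vehicle",
            "noisy_count": rng.integers(2000, 200000, n_countries).astype(float),
            "p10": p10, "p25": p25, "p50": med, "p75": p75, "p90": np.minimum(p90, 480.0),
            "suppressed": False,
        }
    )
    potential = pd.DataFrame(
        {
            "country": countries,
            "mode": "passenger_vehicle",
            "potential_weighted_mean": med * (0.35 + 0.3 * rng.random(n_countries)),
        }
    )
    potential["potential_weighted_median"] = potential["potential_weighted_mean"] * (
        0.85 + 0.1 * rng.random(n_countries)
    )
    rows = []
    for (year, quarter) in ((2020, 2), (2020, 3)):
        for mode, center, scale in (
            ("passenger_vehicle", -11.0, 6.0),
            ("public_transport", 16.0, 9.0),
            ("walking", 25.0, 10.0),
        ):
            pct = rng.normal(center, scale, n_countries)
            base = med * (1.0 if mode == "passenger_vehicle" else 0.8)
            rows.append(
                pd.DataFrame(
                    {
                        "country": countries,
                        "mode": mode,
                        "year": year,
                        "quarter": quarter,
                        "pct_change_time": pct,
                        "abs_change_time": base * pct / 100.0,
                        "pct_change_distance": rng.normal(0.0, 2.0, n_countries),
                        "baseline_median_time": base,
                    }
                )
            )
    return {"revealed": revealed, "potential": potential, "changes": pd.concat(rows, ignore_index=True)}


def _warn_if_empty(df: pd.DataFrame, what: str):
    if df.empty:
        warnings.warn(f"{what} is empty", stacklevel=2)
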