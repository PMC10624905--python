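"""Potential (optimal) accessibility: nearest facility per populated cell and
population-weighted travel-time summaries per country.

The population raster is reduced to ~``target_cell_km`` tiles (default
2.23 km, roughly a five-square-kilometre cell), tiles below the minimum
population (default 50 people) are dropped, and each remaining tile is
represented by its population-weighted centroid. Travel time from a centroid
to its nearest facility comes from a pluggable provider; the default
synthetic provider converts great-circle distance to minutes through a mode
speed and a detour factor standing in for road-network circuity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GridReductionConfig
from .geo import KM_PER_DEG_LAT, haversine_km

__all__ = [
    "TravelTimeProvider",
    "SpeedModelProvider",
    "ConstantTimeProvider",
    "reduce_to_cells",
    "nearest_facility",
    "assign_nearest_facilities",
    "potential_time",
    "population_weighted_summary",
    "country_potential_summary",
]


class TravelTimeProvider:
    """Contract: map (origin, destination, mode) to travel minutes.

    Stands in for a routing service; implementations must be pure functions
    of their inputs so summaries stay reproducible.
    """

    def travel_time(self, origin: tuple[float, float], destination: tuple[float, float], mode: str) -> float:
        raise NotImplementedError


@dataclass
class SpeedModelProvider(TravelTimeProvider):
    """Distance / speed provider: minutes = km * detour / speed * 60."""

    mode_speeds_kmh: dict = field(
        default_factory=lambda: {"passenger_vehicle": 40.0, "public_transport": 20.0, "walking": 4.8}
    )
    detour_factor: float = 1.3

    def travel_time(self, origin, destination, mode):
        if mode not in self.mode_speeds_kmh:
            raise KeyError(f"unknown transport mode {mode!r}")
        d = float(haversine_km(origin[0], origin[1], destination[0], destination[1]))
        return d * self.detour_factor / self.mode_speeds_kmh[mode] * 60.0

    def time_from_distance(self, distance_km, mode):
        if mode not in self.mode_speeds_kmh:
            raise KeyError(f"unknown transport mode {mode!r}")
        return np.asarray(distance_km, dtype=float) * self.detour_factor / self.mode_speeds_kmh[mode] * 60.0


@dataclass
class ConstantTimeProvider(TravelTimeProvider):
    """Returns a fixed number of minutes regardless of geometry (test stub)."""

    minutes: float = 10.0

    def travel_time(self, origin, destination, mode):
        return self.minutes

    def time_from_distance(self, distance_km, mode):
        return np.full(np.shape(distance_km), self.minutes, dtype=float)


def reduce_to_cells(raster: pd.DataFrame, config: GridReductionConfig) -> pd.DataFrame:
    """Aggregate raster pixels (pixel_lat, pixel_lon, population) into
    ~target_cell_km tiles.

    Tiles are latitude-longitude rectangles: the latitude step corresponds to
    target_cell_km everywhere, and each latitude band's longitude step is
    widened by 1/cos(lat) so tiles keep roughly the target width on the
    ground. Pixel populations are summed per tile, the tile centroid is the
    population-weighted mean of pixel centers, and tiles below
    ``min_population`` are dropped.
    """
    if raster.empty:
        raise ValueError("population raster is empty")
    lat = raster["pixel_lat"].to_numpy(dtype=float)
    lon = raster["pixel_lon"].to_numpy(dtype=float)
    pop = raster["population"].to_numpy(dtype=float)
    dlat = config.target_cell_km / KM_PER_DEG_LAT
    lat0, lon0 = lat.min(), lon.min()
    ilat = np.floor((lat - lat0) / dlat).astype(np.int64)
    band_center = lat0 + (ilat + 0.5) * dlat
    dlon = config.target_cell_km / (KM_PER_DEG_LAT * np.maximum(np.cos(np.radians(band_center)), 1e-2))
    ilon = np.floor((lon - lon0) / dlon).astype(np.int64)

    df = pd.DataFrame({"ilat": ilat, "ilon": ilon, "lat": lat, "lon": lon, "pop": pop})
    df["wlat"] = df["lat"] * df["pop"]
    df["wlon"] = df["lon"] * df["pop"]
    g = df.groupby(["ilat", "ilon"], sort=True).agg(
        population=("pop", "sum"),
        wlat=("wlat", "sum"),
        wlon=("wlon", "sum"),
        mlat=("lat", "mean"),
        mlon=("lon", "mean"),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        g["centroid_lat"] = np.where(g["population"] > 0, g["wlat"] / g["population"], g["mlat"])
        g["centroid_lon"] = np.where(g["population"] > 0, g["wlon"] / g["population"], g["mlon"])
    g = g.reset_index()
    g["cell_id"] = [f"r{a}c{b}" for a, b in zip(g["ilat"], g["ilon"])]
    cells = g.loc[g["population"] >= config.min_population,
                  ["cell_id", "centroid_lat", "centroid_lon", "population"]].reset_index(drop=True)
    cells["population"] = np.rint(cells["population"]).astype(np.int64)
    if cells.empty:
        warnings.warn(
            f"all tiles fall below min_population={config.min_population}; no cells retained",
            stacklevel=2,
        )
    return cells


def nearest_facility(cell, facilities: pd.DataFrame):
    """Nearest facility (great-circle) to one cell; ties broken by smallest id.

    ``cell`` is any mapping with centroid_lat / centroid_lon. Returns
    (facility row as Series, distance_km).
    """
    if facilities is None or len(facilities) == 0:
        raise ValueError("facility list is empty")
    fac = facilities.sort_values("facility_id").reset_index(drop=True)
    d = haversine_km(cell["centroid_lat"], cell["centroid_lon"],
                     fac["lat"].to_numpy(), fac["lon"].to_numpy())
    i = int(np.argmin(d))  # argmin returns the first minimum; ids are sorted
    return fac.iloc[i], float(d[i])


def assign_nearest_facilities(cells: pd.DataFrame, facilities: pd.DataFrame) -> pd.DataFrame:
    """Vectorized nearest-facility assignment for every cell.

    Exhaustive scan over all facilities (no pre-filter), so the result is the
    exact argmin. Returns cells plus nearest_facility_id and distance_km.
    """
    if facilities is None or len(facilities) == 0:
        raise ValueError("facility list is empty")
    fac = facilities.sort_values("facility_id").reset_index(drop=True)
    d = haversine_km(
        cells["centroid_lat"].to_numpy()[:, None],
        cells["centroid_lon"].to_numpy()[:, None],
        fac["lat"].to_numpy()[None, :],
        fac["lon"].to_numpy()[None, :],
    )
    idx = np.argmin(d, axis=1)
    out = cells.copy()
    out["nearest_facility_id"] = fac["facility_id"].to_numpy()[idx]
    out["distance_km"] = d[np.arange(len(cells)), idx]
    return out


def potential_time(cell_access, mode: str, provider: TravelTimeProvider) -> float:
    """Travel minutes from a cell's centroid to its nearest facility.

    ``cell_access`` carries centroid_lat/centroid_lon and facility_lat/
    facility_lon (or a distance_km a speed-model provider can use directly).
    """
    if hasattr(provider, "time_from_distance") and "distance_km" in cell_access:
        return float(provider.time_from_distance(cell_access["distance_km"], mode))
    origin = (cell_access["centroid_lat"], cell_access["centroid_lon"])
    dest = (cell_access["facility_lat"], cell_access["facility_lon"])
    return float(provider.travel_time(origin, dest, mode))


def weighted_percentile(times, weights, q):
    """Smallest time t whose cumulative population share reaches q/100.

    Left-continuous weighted empirical CDF convention: the returned value is
    always one of the observed times.
    """
    times = np.asarray(times, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(times, kind="stable")
    t, w = times[order], weights[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("total population weight must be positive")
    share = np.cumsum(w) / total
    qs = np.atleast_1d(np.asarray(q, dtype=float)) / 100.0
    idx = np.searchsorted(share, qs - 1e-12, side="left")
    out = t[np.minimum(idx, t.size - 1)]
    return out if np.ndim(q) else float(out[0])


def population_weighted_summary(
    cell_times,
    populations,
    quantiles=(10, 25, 50, 75, 90),
    thresholds=(30.0, 60.0, 120.0),
) -> dict:
    """Population-weighted percentiles and within-threshold shares.

    fraction_within[theta] is the share of population whose potential time is
    strictly below theta minutes (mirrors statements like "99% of the
    population can reach a facility in under 30 minutes").
    """
    times = np.asarray(cell_times, dtype=float)
    pops = np.asarray(populations, dtype=float)
    total = pops.sum()
    if total <= 0:
        raise ValueError("total population must be positive")
    pcts = {int(q): float(weighted_percentile(times, pops, q)) for q in quantiles}
    fraction_within = {float(th): float(pops[times < th].sum() / total) for th in thresholds}
    return {
        "weighted_percentiles": pcts,
        "fraction_within": fraction_within,
        "weighted_mean": float(np.average(times, weights=pops)),
        "weighted_median": float(weighted_percentile(times, pops, 50)),
        "total_population": float(total),
    }


def country_potential_summary(
    cells: pd.DataFrame,
    facilities: pd.DataFrame,
    modes,
    provider: TravelTimeProvider,
    quantiles=(10, 25, 50, 75, 90),
    thresholds=(30.0, 60.0, 120.0),
) -> pd.DataFrame:
    """Per-mode population-weighted potential summary for one country's cells."""
    assigned = assign_nearest_facilities(cells, facilities)
    fac = facilities.set_index("facility_id")
    rows = []
    for mode in modes:
        if hasattr(provider, "time_from_distance"):
            times = np.asarray(provider.time_from_distance(assigned["distance_km"].to_numpy(), mode))
        else:
            dest = fac.loc[assigned["nearest_facility_id"]]
            times = np.array([
                provider.travel_time((la, lo), (dla, dlo), mode)
                for la, lo, dla, dlo in zip(
                    assigned["centroid_lat"], assigned["centroid_lon"], dest["lat"], dest["lon"]
                )
            ])
        s = population_weighted_summary(times, assigned["population"].to_numpy(), quantiles, thresholds)
        row = {"mode": mode, "potential_weighted_mean": s["weighted_mean"],
               "potential_weighted_median": s["weighted_median"]}
        row.update({f"p{q}": v for q, v in s["weighted_percentiles"].items()})
        row.update({f"frac_lt_{int(th)}": v for th, v in s["fraction_within"].items()})
        rows.append(row)
    return pd.DataFrame(rows)
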