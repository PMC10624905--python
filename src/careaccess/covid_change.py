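"""Pandemic-period change analysis against the matching 2019 quarter.

Every 2020-2021 quarter is compared to the same calendar quarter of 2019 to
control for seasonal fluctuation. Changes are computed on released (DP)
medians by default; an exact-median oracle path exists for testing the
statistical machinery without mechanism noise. Cross-country statistics
treat each country as one observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChangeRecord",
    "CrossCountryChange",
    "baseline_quarter",
    "compute_change",
    "change_table",
    "cross_country_change",
    "mode_share_change",
]

CHANGE_COLUMNS = [
    "country", "mode", "year", "quarter",
    "pct_change_time", "abs_change_time", "pct_change_distance",
    "baseline_median_time", "current_median_time",
]


@dataclass(frozen=True)
class ChangeRecord:
    country: str
    mode: str
    quarter: tuple[int, int]
    pct_change_time: float
    abs_change_time: float
    baseline_median_time: float
    current_median_time: float
    pct_change_distance: float = float("nan")

    def as_row(self) -> dict:
        return {
            "country": self.country, "mode": self.mode,
            "year": self.quarter[0], "quarter": self.quarter[1],
            "pct_change_time": self.pct_change_time,
            "abs_change_time": self.abs_change_time,
            "pct_change_distance": self.pct_change_distance,
            "baseline_median_time": self.baseline_median_time,
            "current_median_time": self.current_median_time,
        }


@dataclass(frozen=True)
class CrossCountryChange:
    mode: str
    quarter: tuple[int, int]
    median_pct_change: float
    median_abs_change: float
    t_statistic: float
    p_value: float
    n_countries: int
    degenerate: bool = False


def baseline_quarter(quarter: tuple[int, int]) -> tuple[int, int]:
    """Same calendar quarter of 2019."""
    year, q = quarter
    if year not in (2020, 2021):
        raise ValueError(f"baseline is defined only for 2020-2021 quarters, got {quarter}")
    if q not in (1, 2, 3, 4):
        raise ValueError(f"invalid quarter number {q}")
    return (2019, q)


def _median(summary):
    if hasattr(summary, "percentile"):
        return summary.percentile(50)
    return summary["p50"]


def _suppressed(summary) -> bool:
    if hasattr(summary, "suppressed"):
        return bool(summary.suppressed)
    return bool(summary.get("suppressed", False))


def compute_change(
    current,
    baseline,
    current_distance_median: float | None = None,
    baseline_distance_median: float | None = None,
) -> ChangeRecord | None:
    """Change of the median travel time versus the 2019 baseline quarter.

    Returns None (missing) when either side is suppressed or the baseline
    median is non-positive. Distance analogues are filled when both distance
    medians are provided.
    """
    if _suppressed(current) or _suppressed(baseline):
        return None
    base = float(_median(baseline))
    cur = float(_median(current))
    if base <= 0:
        return None
    pct_dist = float("nan")
    if current_distance_median is not None and baseline_distance_median is not None:
        if baseline_distance_median > 0:
            pct_dist = (current_distance_median - baseline_distance_median) / baseline_distance_median * 100.0
    cur_slice = current.slice if hasattr(current, "slice") else None
    country = cur_slice.country if cur_slice is not None else current["country"]
    mode = cur_slice.mode if cur_slice is not None else current["mode"]
    quarter = cur_slice.quarter if cur_slice is not None else (int(current["year"]), int(current["quarter"]))
    return ChangeRecord(
        country=country, mode=mode, quarter=quarter,
        pct_change_time=(cur - base) / base * 100.0,
        abs_change_time=cur - base,
        baseline_median_time=base,
        current_median_time=cur,
        pct_change_distance=pct_dist,
    )


def change_table(releases: pd.DataFrame, distance_medians: pd.DataFrame | None = None) -> pd.DataFrame:
    """All pandemic-quarter changes derivable from a released summary table.

    ``releases`` follows the dp_release schema; ``distance_medians`` (optional)
    carries country, year, quarter, mode, distance_median_km for both the
    pandemic quarter and its baseline.
    """
    key = ["country", "mode"]
    base = releases[releases["year"] == 2019]
    rows = []
    dist_lookup = None
    if distance_medians is not None:
        dist_lookup = distance_medians.set_index(["country", "mode", "year", "quarter"])["distance_median_km"]
    for _, cur in releases[releases["year"] >= 2020].iterrows():
        by, bq = baseline_quarter((int(cur["year"]), int(cur["quarter"])))
        match = base[
            (base["country"] == cur["country"]) & (base["mode"] == cur["mode"]) & (base["quarter"] == bq)
        ]
        if match.empty:
            continue
        bl = match.iloc[0]
        cur_d = bl_d = None
        if dist_lookup is not None:
            cur_d = dist_lookup.get((cur["country"], cur["mode"], int(cur["year"]), int(cur["quarter"])))
            bl_d = dist_lookup.get((cur["country"], cur["mode"], by, bq))
        rec = compute_change(cur, bl, cur_d, bl_d)
        if rec is not None:
            rows.append(rec.as_row())
    return pd.DataFrame(rows, columns=CHANGE_COLUMNS)


def cross_country_change(changes: pd.DataFrame, mode: str, quarter: tuple[int, int]) -> CrossCountryChange:
    """Cross-country medians and a two-sided paired t-test for one mode/quarter.

    The paired test compares each country's current median against its
    baseline median. Fewer than 2 countries: medians only, no test (NaN t,
    NaN p). Zero-variance differences (including the all-identical case) are
    degenerate: t is NaN and p = 1 by convention, flagged.
    """
    sel = changes[
        (changes["mode"] == mode)
        & (changes["year"] == quarter[0])
        & (changes["quarter"] == quarter[1])
    ].dropna(subset=["pct_change_time"])
    n = len(sel)
    if n == 0:
        raise ValueError(f"no change records for mode={mode!r}, quarter={quarter}")
    med_pct = float(sel["pct_change_time"].median())
    med_abs = float(sel["abs_change_time"].median())
    if n < 2:
        return CrossCountryChange(mode, quarter, med_pct, med_abs, float("nan"), float("nan"), n)
    cur = sel["current_median_time"].to_numpy(dtype=float)
    base = sel["baseline_median_time"].to_numpy(dtype=float)
    diffs = cur - base
    if np.allclose(diffs.std(ddof=1), 0.0):
        return CrossCountryChange(mode, quarter, med_pct, med_abs, float("nan"), 1.0, n, degenerate=True)
    t, p = stats.ttest_rel(cur, base)
    return CrossCountryChange(mode, quarter, med_pct, med_abs, float(t), float(p), n)


def mode_share_change(trip_counts: pd.DataFrame) -> pd.DataFrame:
    """Mode shares per year and their difference in percentage points.

    ``trip_counts`` carries columns mode, year, n_trips (aggregated counts).
    Returns one row per mode with share_<year> columns (fractions summing to
    1 per year) and pp_change between the two years (later minus earlier).
    """
    if (trip_counts["n_trips"] < 0).any():
        raise ValueError("trip counts must be non-negative")
    years = sorted(trip_counts["year"].unique())
    pivot = trip_counts.pivot_table(index="mode", columns="year", values="n_trips",
                                    aggfunc="sum", fill_value=0.0)
    for y in years:
        total = pivot[y].sum()
        if total <= 0:
            raise ValueError(f"no trips recorded in year {y}")
        pivot[y] = pivot[y] / total
    out = pivot.rename(columns={y: f"share_{y}" for y in years}).reset_index()
    if len(years) == 2:
        y0, y1 = years
        out["pp_change"] = (out[f"share_{y1}"] - out[f"share_{y0}"]) * 100.0
    return out
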