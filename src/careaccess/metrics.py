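"""Accessibility statistics: inequality ratios, revealed-vs-potential
comparisons and cross-country summaries.

All operations treat suppressed DP slices as missing (NaN) — never zero and
never imputed — and cross-country statistics give each country one
observation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "inequality_ratio",
    "inequality_ratio_row",
    "revealed_vs_potential",
    "count_countries",
    "cross_country_summary",
    "country_comparison_table",
]


def _p(summary, q: int):
    """Percentile accessor working for DPPercentileSummary objects and rows."""
    if hasattr(summary, "percentile"):
        return summary.percentile(q)
    return summary[f"p{q}"]


def _is_suppressed(summary) -> bool:
    if hasattr(summary, "suppressed"):
        sup = summary.suppressed
    else:
        sup = summary.get("suppressed", False)
    return bool(sup)


def inequality_ratio(summary) -> float:
    """Within-country inequality of revealed travel times: p75 / p25.

    Analogous in spirit to income-inequality percentile ratios. Returns NaN
    (missing) for suppressed slices or non-positive p25.
    """
    if _is_suppressed(summary):
        return float("nan")
    p25, p75 = _p(summary, 25), _p(summary, 75)
    if not np.isfinite(p25) or p25 <= 0:
        return float("nan")
    return float(p75 / p25)


def inequality_ratio_row(row: pd.Series) -> float:
    return inequality_ratio(row)


def revealed_vs_potential(revealed, potential_weighted: float) -> tuple[float, float]:
    """Gap between what people actually experience and the optimal trip.

    diff_p90 = revealed p90 - aggregated potential time (minutes);
    ratio_factor = revealed p90 / aggregated potential time. Missing (NaN,
    NaN) for suppressed slices or non-positive potential.
    """
    if _is_suppressed(revealed) or not np.isfinite(potential_weighted) or potential_weighted <= 0:
        return (float("nan"), float("nan"))
    p90 = _p(revealed, 90)
    return (float(p90 - potential_weighted), float(p90 / potential_weighted))


def count_countries(records: pd.DataFrame, predicate) -> int:
    """Count countries whose (single, deduplicated) record satisfies the predicate.

    ``predicate`` maps the records frame to a boolean mask; rows with NaN in
    the fields the predicate touches evaluate False and are excluded.
    """
    if records.empty:
        return 0
    if records["country"].duplicated().any():
        raise ValueError("records must be deduplicated by country before counting")
    mask = np.asarray(predicate(records), dtype=bool)
    return int(mask.sum())


def cross_country_summary(records: pd.DataFrame, fieldname: str, statistic="median") -> float:
    """One statistic of a per-country field across countries.

    ``statistic`` is 'median' or a percentile in (0, 100). Suppressed/missing
    countries are dropped; raises when nothing is left.
    """
    values = pd.to_numeric(records[fieldname], errors="coerce").dropna()
    if values.empty:
        raise ValueError(f"no countries with field {fieldname!r} present")
    if statistic == "median":
        return float(values.median())
    q = float(statistic)
    if not (0 < q < 100):
        raise ValueError(f"statistic must be 'median' or a percentile in (0,100), got {statistic!r}")
    return float(np.percentile(values.to_numpy(), q))


def country_comparison_table(
    revealed: pd.DataFrame,
    potential: pd.DataFrame,
    potential_aggregate: str = "potential_weighted_mean",
) -> pd.DataFrame:
    """Join per-country revealed summaries with aggregated potential times.

    ``revealed`` rows carry country, p10..p90, suppressed; ``potential``
    carries country and the aggregate columns. Both the weighted-mean and the
    weighted-median aggregation conventions are preserved when present, and
    diff/factor are computed against ``potential_aggregate``.
    """
    keep = [c for c in ("potential_weighted_mean", "potential_weighted_median") if c in potential.columns]
    merged = revealed.merge(potential[["country", *keep]], on="country", how="left")
    merged["inequality_ratio"] = [inequality_ratio(row) for _, row in merged.iterrows()]
    pairs = [
        revealed_vs_potential(row, row.get(potential_aggregate, float("nan")))
        for _, row in merged.iterrows()
    ]
    merged["diff_p90_minutes"] = [d for d, _ in pairs]
    merged["ratio_factor"] = [f for _, f in pairs]
    return merged
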