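"""Configuration objects for the synthetic scenario, the DP release and the grid.

All knobs that matter scientifically live here, with validated defaults. The
scenario defaults encode the pandemic-period conditions the analysis is meant
to detect: a decrease in passenger-vehicle travel times, increases for public
transport and walking, and a shift of mode share toward passenger vehicles,
each strongest in the second quarter of 2020.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

from ._rng import substream

__all__ = [
    "MODES",
    "STUDY_QUARTERS",
    "CovidEffect",
    "ScenarioConfig",
    "PrivacyBudget",
    "DPReleaseConfig",
    "GridReductionConfig",
    "PipelineConfig",
    "default_scenario",
    "load_scenario_yaml",
]

#: The three transport modes distinguished in the analysis.
MODES = ("passenger_vehicle", "public_transport", "walking")

#: Calendar quarters covered by the study span, Q1 2019 - Q3 2021.
STUDY_QUARTERS = tuple(
    (y, q) for y in (2019, 2020, 2021) for q in (1, 2, 3, 4) if not (y == 2021 and q == 4)
)


@dataclass(frozen=True)
class CovidEffect:
    """Per-quarter pandemic multipliers applied to the 2019 baseline laws.

    ``mode_shift`` moves a fraction of the non-car probability mass toward
    passenger vehicles: car' = car + shift * (1 - car), with the remaining
    modes rescaled proportionally.
    """

    car_time_mult: float = 1.0
    transit_time_mult: float = 1.0
    walk_time_mult: float = 1.0
    mode_shift: float = 0.0

    def __post_init__(self):
        for name in ("car_time_mult", "transit_time_mult", "walk_time_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 <= self.mode_shift < 1.0):
            raise ValueError(f"mode_shift must be in [0, 1), got {self.mode_shift}")

    def time_multiplier(self, mode: str) -> float:
        return {
            "passenger_vehicle": self.car_time_mult,
            "public_transport": self.transit_time_mult,
            "walking": self.walk_time_mult,
        }[mode]


def _as_per_country(mapping: dict, countries: list[str]) -> dict:
    """Broadcast a flat mapping to every country when needed."""
    if not mapping:
        return mapping
    if set(mapping) & set(countries):
        return mapping
    return {c: mapping for c in countries}


@dataclass
class ScenarioConfig:
    """Full description of one synthetic world.

    time_params maps country -> mode -> (log-mean, log-sd) of a lognormal
    travel-time law in minutes; mode_shares maps country -> mode -> share.
    Flat (mode-keyed) dicts are broadcast to every country.
    """

    countries: list[str]
    quarters: list[tuple[int, int]]
    n_users_per_country: int
    trips_per_user_mean: float
    mode_shares: dict
    time_params: dict
    mode_speeds: dict = field(
        default_factory=lambda: {"passenger_vehicle": 40.0, "public_transport": 20.0, "walking": 4.8}
    )
    detour_factor: float = 1.3
    covid_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.quarters = [tuple(q) for q in self.quarters]
        for (y, q) in self.quarters:
            if y not in (2019, 2020, 2021) or q not in (1, 2, 3, 4):
                raise ValueError(f"quarter {(y, q)} outside the supported span")
        if self.n_users_per_country <= 0:
            raise ValueError("n_users_per_country must be positive")
        if self.trips_per_user_mean < 0:
            raise ValueError("trips_per_user_mean must be non-negative")
        if self.detour_factor < 1.0:
            raise ValueError(f"detour_factor must be >= 1, got {self.detour_factor}")
        self.mode_shares = _as_per_country(self.mode_shares, self.countries)
        self.time_params = _as_per_country(self.time_params, self.countries)
        self.covid_effects = {
            tuple(k) if not isinstance(k, str) else _parse_quarter_key(k): (
                v if isinstance(v, CovidEffect) else CovidEffect(**v)
            )
            for k, v in self.covid_effects.items()
        }
        for c in self.countries:
            shares = self.mode_shares.get(c)
            if shares is None:
                raise ValueError(f"no mode shares configured for country {c!r}")
            total = sum(shares.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"mode shares for {c!r} sum to {total}, not 1")
            for mode, (_, sd) in self.time_params.get(c, {}).items():
                if sd <= 0:
                    raise ValueError(f"log-sd for ({c!r}, {mode!r}) must be > 0")
        for v in self.mode_speeds.values():
            if v <= 0:
                raise ValueError("mode speeds must be positive")


def _parse_quarter_key(key: str) -> tuple[int, int]:
    """Parse '2020Q2' or '2020-2' into (2020, 2)."""
    key = key.strip().upper().replace("-", "Q")
    y, q = key.split("Q")
    return int(y), int(q)


@dataclass(frozen=True)
class PrivacyBudget:
    """Total privacy budget and its split across sub-releases per slice.

    The budget is split six ways: five percentile releases plus the noisy
    unique-user count.
    """

    epsilon_total: float = 0.9417
    n_releases: int = 6

    def __post_init__(self):
        if self.epsilon_total <= 0:
            raise ValueError(f"epsilon_total must be > 0, got {self.epsilon_total}")
        if self.n_releases < 1:
            raise ValueError("n_releases must be >= 1")

    @property
    def epsilon_per_release(self) -> float:
        return self.epsilon_total / self.n_releases


@dataclass(frozen=True)
class DPReleaseConfig:
    """Parameters of the anonymized percentile release."""

    k_threshold: int = 1000
    domain_low: float = 0.0
    domain_high: float = 480.0
    quantiles: tuple = (10, 25, 50, 75, 90)
    n_candidate_bins: int = 8192
    seed: int = 0

    def __post_init__(self):
        if self.domain_low >= self.domain_high:
            raise ValueError("domain_low must be < domain_high")
        if self.k_threshold < 1:
            raise ValueError("k_threshold must be >= 1")
        qs = tuple(self.quantiles)
        if list(qs) != sorted(qs) or len(set(qs)) != len(qs) or not all(0 < q < 100 for q in qs):
            raise ValueError("quantiles must be strictly increasing within (0, 100)")
        if self.n_candidate_bins < 2:
            raise ValueError("n_candidate_bins must be >= 2")


@dataclass(frozen=True)
class GridReductionConfig:
    """Population-raster reduction parameters."""

    target_cell_km: float = 2.23
    min_population: int = 50
    tiling: str = "latlon"

    def __post_init__(self):
        if self.target_cell_km <= 0:
            raise ValueError("target_cell_km must be > 0")
        if self.min_population < 0:
            raise ValueError("min_population must be >= 0")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    scenario: ScenarioConfig
    budget: PrivacyBudget = field(default_factory=PrivacyBudget)
    dp: DPReleaseConfig = field(default_factory=DPReleaseConfig)
    grid: GridReductionConfig = field(default_factory=GridReductionConfig)
    time_thresholds_min: tuple = (30.0, 60.0, 120.0)
    ratio_factors: tuple = (2.0, 3.0, 5.0)
    n_cells_per_country: int = 400
    n_facilities_per_country: int = 8
    log_level: str = "INFO"


# Default pandemic-quarter effects. Q2 2020 is the strongest-disruption
# quarter (car times down ~12%, transit up ~18%, walking up ~27%, mode share
# shifting toward passenger vehicles); the surrounding quarters apply the same
# directions attenuated.
# The mode-share shift is constant over 2020 (the share change is a
# whole-year figure: passenger-vehicle share 70.61% -> 77.28%), while the
# travel-time multipliers peak in Q2 2020.
_SHIFT_2020 = 0.22729
_Q2_2020 = CovidEffect(car_time_mult=0.8826, transit_time_mult=1.179,
                       walk_time_mult=1.2689, mode_shift=_SHIFT_2020)
DEFAULT_COVID_EFFECTS = {
    (2020, 1): CovidEffect(0.97, 1.05, 1.06, _SHIFT_2020),
    (2020, 2): _Q2_2020,
    (2020, 3): CovidEffect(0.93, 1.10, 1.15, _SHIFT_2020),
    (2020, 4): CovidEffect(0.93, 1.10, 1.15, _SHIFT_2020),
    (2021, 1): CovidEffect(0.95, 1.08, 1.10, 0.12),
    (2021, 2): CovidEffect(0.95, 1.08, 1.10, 0.12),
    (2021, 3): CovidEffect(0.96, 1.06, 1.08, 0.10),
}

#: 2019 baseline mode shares: passenger vehicles dominate urgent trips.
DEFAULT_MODE_SHARES = {"passenger_vehicle": 0.7061, "public_transport": 0.0959, "walking": 0.1980}


def _country_time_params(country: str) -> dict:
    """Stable per-country lognormal laws, derived by hashing the country code.

    Car medians vary across countries around ~25 min (heavy right tail across
    countries, so some countries have much longer typical trips); transit runs
    slightly faster-scaled than car trips and walking trips are short.
    """
    rng = substream(0, "country-time-params", country)
    mu_car = math.log(25.0) + rng.normal(0.0, 0.5)
    sigma_car = 0.7 + 0.2 * rng.random()
    return {
        "passenger_vehicle": (mu_car, sigma_car),
        "public_transport": (mu_car + math.log(0.88), sigma_car + 0.05),
        "walking": (mu_car + math.log(0.25), max(0.5, sigma_car - 0.1)),
    }


def default_scenario(
    countries: list[str] | None = None,
    quarters: list[tuple[int, int]] | None = None,
    n_users_per_country: int = 5000,
    trips_per_user_mean: float = 1.8,
    seed: int = 0,
    covid_effects: dict | None = None,
) -> ScenarioConfig:
    """A ready-to-run scenario with the default study conditions."""
    if countries is None:
        countries = [f"C{i:02d}" for i in range(20)]
    if quarters is None:
        quarters = list(STUDY_QUARTERS)
    return ScenarioConfig(
        countries=list(countries),
        quarters=list(quarters),
        n_users_per_country=n_users_per_country,
        trips_per_user_mean=trips_per_user_mean,
        mode_shares={c: dict(DEFAULT_MODE_SHARES) for c in countries},
        time_params={c: _country_time_params(c) for c in countries},
        covid_effects=dict(DEFAULT_COVID_EFFECTS if covid_effects is None else covid_effects),
        seed=seed,
    )


def null_scenario(**kwargs) -> ScenarioConfig:
    """Default scenario with every pandemic effect switched off."""
    cfg = default_scenario(**{**kwargs, "covid_effects": {}})
    return cfg


def load_scenario_yaml(path) -> ScenarioConfig:
    """Read a ScenarioConfig from a YAML file keyed exactly as the fields."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return ScenarioConfig(**raw)


def with_seed(cfg: ScenarioConfig, seed: int) -> ScenarioConfig:
    return replace(cfg, seed=seed)
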