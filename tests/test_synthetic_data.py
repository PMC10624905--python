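"""Synthetic world generator: determinism, distributional structure, oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from careaccess.config import CovidEffect, ScenarioConfig, default_scenario
from careaccess.synthetic_data import (
    generate_outcomes,
    generate_population_grid,
    generate_trips,
    ground_truth_percentiles,
    place_facilities,
)

EXTENT = (0.0, 1.0, 10.0, 11.0)


class TestPopulationGrid:
    def test_degenerate_law_single_cell(self):
        cells = generate_population_grid(EXTENT, 1, seed=0, mean_population=100.0,
                                         zero_inflation=0.0, sigma=0.0)
        assert len(cells) == 1
        assert cells["population"].iloc[0] == 100
        # centroid at the extent center
        assert cells["centroid_lat"].iloc[0] == pytest.approx(0.5)
        assert cells["centroid_lon"].iloc[0] == pytest.approx(10.5)

    def test_deterministic_under_seed(self):
        a = generate_population_grid(EXTENT, 64, seed=5)
        b = generate_population_grid(EXTENT, 64, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = generate_population_grid(EXTENT, 64, seed=6)
        assert not a["population"].equals(c["population"])

    def test_grand_total_matches_target_mean(self):
        # law of large numbers: 10,000 cells at mean 200 -> total within 5% of 2e6
        cells = generate_population_grid(EXTENT, 10_000, seed=1, mean_population=200.0)
        assert abs(cells["population"].sum() - 2_000_000) < 0.05 * 2_000_000

    def test_cells_tile_extent(self):
        cells = generate_population_grid(EXTENT, 100, seed=2)
        assert len(cells) == 100
        assert cells["centroid_lat"].between(*EXTENT[:2]).all()
        assert cells["centroid_lon"].between(*EXTENT[2:]).all()
        assert cells["cell_id"].is_unique

    @pytest.mark.parametrize(
        "extent,msg",
        [((1.0, 1.0, 10.0, 11.0), "lat_max"), ((0.0, 1.0, 11.0, 11.0), "lon_max")],
    )
    def test_degenerate_extent_names_failing_bound(self, extent, msg):
        with pytest.raises(ValueError, match=msg):
            generate_population_grid(extent, 4, seed=0)


class TestPlaceFacilities:
    def _cells(self, pops):
        n = len(pops)
        cells = generate_population_grid(EXTENT, n, seed=0, sigma=0.0, zero_inflation=0.0)
        cells["population"] = pops
        return cells

    def test_single_populated_cell_forced(self):
        cells = self._cells([120])
        fac = place_facilities(cells, 1, seed=3)
        assert fac["lat"].iloc[0] == cells["centroid_lat"].iloc[0]
        assert fac["lon"].iloc[0] == cells["centroid_lon"].iloc[0]

    def test_zero_population_cell_never_selected(self):
        cells = self._cells([0, 50])
        for seed in range(25):
            fac = place_facilities(cells, 1, seed=seed)
            assert fac["lon"].iloc[0] == cells["centroid_lon"].iloc[1]

    def test_sampling_frequency_binomial_oracle(self):
        # populations 100/300 -> P(cell1) = 0.75; 10,000 resamplings within 3 sd
        cells = self._cells([100, 300])
        hits = sum(
            place_facilities(cells, 1, seed=s)["lon"].iloc[0] == cells["centroid_lon"].iloc[1]
            for s in range(10_000)
        )
        sd = np.sqrt(10_000 * 0.75 * 0.25)
        assert abs(hits - 7500) < 3 * sd

    def test_too_many_facilities_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            place_facilities(self._cells([10, 0]), 2, seed=0)


def _one_country(seed=0, quarters=((2019, 2), (2020, 2)), n_users=2500,
                 covid_effects=None, trips_mean=4.0):
    return ScenarioConfig(
        countries=["AA"],
        quarters=list(quarters),
        n_users_per_country=n_users,
        trips_per_user_mean=trips_mean,
        mode_shares={"passenger_vehicle": 0.6, "public_transport": 0.25, "walking": 0.15},
        time_params={
            "passenger_vehicle": (3.0, 0.5),
            "public_transport": (3.3, 0.5),
            "walking": (2.2, 0.5),
        },
        covid_effects=covid_effects or {},
        seed=seed,
    )


class TestGenerateTrips:
    def test_null_scenario_2020_equals_2019_in_law(self):
        # all multipliers 1 -> KS cannot distinguish the slices at alpha=0.01
        trips = generate_trips(_one_country(n_users=2600))
        car = trips[trips["mode"] == "passenger_vehicle"]
        a = car[car["year"] == 2019]["travel_time_min"].to_numpy()[:10_000]
        b = car[car["year"] == 2020]["travel_time_min"].to_numpy()[:10_000]
        assert min(a.size, b.size) >= 5000
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_car_multiplier_scales_median(self):
        # lognormal medians scale exactly with the multiplier
        effects = {(2020, 2): CovidEffect(car_time_mult=0.85)}
        trips = generate_trips(_one_country(n_users=8000, covid_effects=effects))
        car = trips[trips["mode"] == "passenger_vehicle"]
        m19 = car[car["year"] == 2019]["travel_time_min"].median()
        m20 = car[car["year"] == 2020]["travel_time_min"].median()
        assert m20 / m19 == pytest.approx(0.85, rel=0.03)

    def test_zero_trip_mean_empty_table(self):
        trips = generate_trips(_one_country(trips_mean=0.0))
        assert trips.empty

    def test_deterministic_and_country_independent(self):
        cfg2 = ScenarioConfig(
            countries=["AA", "BB"],
            quarters=[(2019, 2)],
            n_users_per_country=300,
            trips_per_user_mean=1.5,
            mode_shares={"passenger_vehicle": 1.0},
            time_params={"passenger_vehicle": (3.0, 0.5)},
            seed=9,
        )
        both = generate_trips(cfg2)
        cfg1 = ScenarioConfig(
            countries=["AA"], quarters=[(2019, 2)], n_users_per_country=300,
            trips_per_user_mean=1.5, mode_shares={"passenger_vehicle": 1.0},
            time_params={"passenger_vehicle": (3.0, 0.5)}, seed=9,
        )
        only_aa = generate_trips(cfg1)
        # adding a country does not perturb the first country's substream
        pd.testing.assert_frame_equal(
            both[both["country"] == "AA"].reset_index(drop=True), only_aa
        )
        pd.testing.assert_frame_equal(generate_trips(cfg2), both)

    def test_positivity_and_schema(self, tiny_trips):
        assert (tiny_trips["travel_time_min"] > 0).all()
        assert (tiny_trips["distance_km"] > 0).all()
        assert set(tiny_trips["mode"]) <= {"passenger_vehicle", "public_transport", "walking"}

    def test_mode_share_conservation(self):
        trips = generate_trips(_one_country(n_users=5000))
        q19 = trips[trips["year"] == 2019]
        freq = q19["mode"].value_counts(normalize=True)
        n = len(q19)
        for mode, p in (("passenger_vehicle", 0.6), ("public_transport", 0.25), ("walking", 0.15)):
            assert abs(freq[mode] - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_mode_shift_moves_share_toward_cars(self):
        effects = {(2020, 2): CovidEffect(mode_shift=0.25)}
        trips = generate_trips(_one_country(n_users=5000, covid_effects=effects))
        f20 = trips[trips["year"] == 2020]["mode"].value_counts(normalize=True)
        expected = 0.6 + 0.25 * 0.4
        assert f20["passenger_vehicle"] == pytest.approx(expected, abs=0.02)

    def test_unknown_mode_key_errors(self):
        cfg = _one_country()
        cfg.mode_shares["AA"] = {"teleport": 1.0}
        with pytest.raises(KeyError, match="teleport"):
            generate_trips(cfg)


class TestGroundTruthPercentiles:
    def test_odd_length_median(self, tiny_scenario):
        from conftest import make_trips_df

        trips = make_trips_df([10, 20, 30, 40, 50])
        from careaccess.dp_release import SliceKey

        key = SliceKey("AA", (2019, 2), "passenger_vehicle")
        out = ground_truth_percentiles(trips, key, [50], seed=0)
        assert out[50.0] == 30

    def test_constant_sample_every_percentile(self):
        from conftest import make_trips_df
        from careaccess.dp_release import SliceKey

        trips = make_trips_df([7.5] * 11)
        key = SliceKey("AA", (2019, 2), "passenger_vehicle")
        out = ground_truth_percentiles(trips, key, [10, 25, 50, 75, 90], seed=1)
        assert all(v == 7.5 for v in out.values())

    def test_empty_slice_gives_none_not_zero(self):
        from conftest import make_trips_df
        from careaccess.dp_release import SliceKey

        trips = make_trips_df([])
        key = SliceKey("ZZ", (2019, 2), "walking")
        assert ground_truth_percentiles(trips, key, [50], seed=0) is None

    def test_lognormal_median_closed_form(self):
        # median of lognormal(mu=3, sigma=0.5) is e^3 ~ 20.09 min
        from careaccess.dp_release import SliceKey
        from conftest import make_trips_df

        rng = np.random.default_rng(42)
        trips = make_trips_df(rng.lognormal(3.0, 0.5, 100_000))
        key = SliceKey("AA", (2019, 2), "passenger_vehicle")
        out = ground_truth_percentiles(trips, key, [50], seed=0)
        assert out[50.0] == pytest.approx(np.exp(3.0), rel=0.01)


def test_outcome_generator_plants_monotone_link():
    sev = {f"C{i:02d}": 10 + 3.0 * i for i in range(30)}
    df = generate_outcomes(sev, seed=4, noise_sd=0.5)
    aligned = df.set_index("country").loc[list(sev)]
    rho_life = stats.spearmanr(list(sev.values()), aligned["life_expectancy"]).statistic
    rho_imr = stats.spearmanr(list(sev.values()), aligned["infant_mortality"]).statistic
    assert rho_life < -0.8 and rho_imr > 0.8
    assert df["life_expectancy"].between(30, 100).all()
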