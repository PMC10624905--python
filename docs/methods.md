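# Methods

`careaccess` models the measurement of spatial healthcare accessibility from
two directions: *revealed* accessibility — what travel times people actually
experience when they go to a healthcare facility, estimated from trip-level
mobility tables and released only through a differentially private
mechanism — and *potential* accessibility — the optimal travel time from
every populated place to its nearest facility. Everything downstream
(inequality ratios, revealed-vs-potential gaps, pandemic-period change
analysis, outcome association) consumes only those two summaries.

## The privacy mechanism

The protected unit is one user's presence in a *slice*: all trips in one
(country, calendar quarter, transport mode) cell, over the study span
Q1 2019 – Q3 2021 and the modes {passenger vehicle, public transport,
walking}. The release of a slice is ε-DP with ε = 0.9417 by basic
composition of six (ε/6)-DP sub-queries:

1. **Contribution bounding.** Each user contributes exactly one trip,
   sampled uniformly among their trips in the slice. This caps the
   sensitivity of every subsequent query at 1 and removes the skew of
   disproportionate repeat visitors.
2. **Noisy count and suppression.** The unique-user count gets
   Laplace(1/ε′) noise, ε′ = ε/6. A slice is released only when the *noisy*
   count is strictly above k = 1000; below that, a suppressed summary with
   no percentile values is emitted (slices with no users at all are simply
   excluded). Thresholding is applied after the noise, so it is pure
   post-processing and costs no privacy.
3. **Five percentile releases.** The 10th, 25th, 50th, 75th and 90th
   percentiles of the bounded sample are each released with an (ε/6)-DP
   quantile mechanism, then sorted (isotonic correction — valid
   post-processing; for five unweighted scalars, pool-adjacent-violators
   reduces to sorting).

### The quantile mechanism

Travel times are clamped into a fixed domain [0, 480] minutes (the longest
plausible trips are a few hours; configurable) which is partitioned into
`n_candidate_bins` equal candidate bins (default 8192, i.e. ≈ 0.06 min
resolution). For a bin [e_i, e_{i+1}) the attainable rank interval is
[#{v < e_i}, #{v < e_{i+1}}], and its utility is the negative distance from
the target rank q·n/100 to that interval (zero when the target rank is
attainable inside the bin). Adding or removing one value moves each end of
the interval by at most one, so the utility has sensitivity 1; a bin is
selected with probability ∝ exp(ε′·u/2) and the released value is uniform
within the selected bin. Because the candidate set is data-independent, the
continuous output is ε′-DP, and the interval-valued utility keeps the
mechanism concentrated even when the sample is massively tied (all values
equal to c ⇒ only the bin containing c has utility 0).

A frequently described alternative places candidates on the intervals
between consecutive order statistics with width-weighted exponential
weights. We deliberately use the fixed-grid variant: the order-statistic
form degenerates under heavy ties (with an all-equal sample, the two
non-empty intervals are the domain ends and the output is near-uniform over
the whole domain), while the grid form keeps both the privacy proof and the
tie behaviour simple. The mechanism sits behind a small functional surface
(`dp_quantile` / `dp_quantile_draws`), so a quantile-tree variant can be
plugged in without touching the release logic.

Numerical details: Laplace noise is drawn by inverse-CDF from a seeded
uniform stream (reproducibility over speed); weights are computed in log
space and normalized after subtracting the maximum; enforced monotonicity
is a plain sort; released values are always inside the clamping domain
regardless of the data.

Released summaries carry an explicit budget audit (`epsilon_spent`,
`n_sub_releases`); a full release spends exactly ε, a suppressed one ε/6
(only the count was touched).

The suppression threshold also bounds sampling error: by the normal
approximation, an empirical 90th percentile from 1,000 trips has a 95% CI
of about ±1.9 percentile units (`percentile_ci_halfwidth`).

## Potential accessibility

A population raster is reduced to tiles of roughly 2.23 km side (about five
square kilometres, emulating a level-12 spherical-cell reduction). The
default tiling is latitude–longitude rectangles whose longitude step is
widened by 1/cos φ per latitude band — this avoids a hard spherical-geometry
dependency while keeping tiles near the target ground size; a true S2
adapter can be substituted through the `tiling` field. Tile population is
the sum of pixel populations, the centroid is the population-weighted mean
of pixel centers, and tiles with fewer than 50 people are dropped (50 is
kept, 49 is dropped).

Each retained cell is assigned its nearest facility by exhaustive
great-circle (haversine, R = 6371.0088 km) scan; ties break to the smallest
facility id. Travel time comes from a pluggable provider contract
(origin, destination, mode) → minutes; the default synthetic provider is
`distance × detour_factor / speed × 60`, with the detour factor (default
1.3) standing in for road-network circuity. Real routing engines implement
the same contract.

Country summaries are population-weighted. The weighted q-th percentile is
the smallest observed time whose cumulative population share reaches q/100
(left-continuous weighted empirical CDF; with equal weights this coincides
with the unweighted inverted-CDF percentile), and `fraction_within(θ)` is
the population share with time strictly below θ. Both the weighted mean and
the weighted median are reported as the country-level "aggregated potential
time", and the comparison metrics state which convention they used — the
choice genuinely matters for the revealed-to-potential ratio factors, so
both are kept in every output table.

## Comparison and change metrics

* **Inequality ratio** = released p75 / released p25, per country; invariant
  to rescaling all percentiles, ≥ 1 whenever the ladder is monotone and
  p25 > 0. Suppressed slices propagate as missing, never as zero.
* **Revealed vs. potential**: diff = revealed p90 − aggregated potential;
  factor = revealed p90 / aggregated potential; the two are consistent by
  construction (diff = potential × (factor − 1)). "x times longer" is
  interpreted as factor ≥ x.
* **Pandemic change**: each 2020–2021 quarter is compared to the same
  calendar quarter of 2019 (seasonality control); pct change of the released
  median, absolute change in minutes, and distance analogues when distance
  medians are available. Cross-country statistics give each country one
  observation: medians of the per-country changes plus a two-sided paired
  t-test on (current, baseline) median pairs. A zero-variance set of
  differences is degenerate: t is reported as NaN and p = 1, flagged, so
  NaNs never propagate.
* **Outcome association**: Spearman rank correlation (mid-ranks for ties,
  two-sided t-approximation; exact permutation by full enumeration for
  n ≤ 10), and an OLS adjustment of the outcome on the revealed exposure
  plus potential time and log-GDP. Rank-deficient designs raise with the
  collinear columns named. These are descriptive associations, not causal
  estimates.

## The synthetic world

The generator's defaults are the study conditions the analysis targets:

* **Travel times** are lognormal per (country, mode). Lognormal is positive
  and heavy-tailed, and its closed-form median (e^μ) makes oracle tests
  exact. Per-country car medians are drawn around 25 minutes (log-sd 0.5
  across countries, within-country log-sd 0.7–0.9), public-transport trips
  scale at ×0.88 of car trips and walking trips at ×0.25 — walking trips to
  a facility are short. The cross-country car median then lands in the
  25–30 min range with a long right tail.
* **Mode shares** default to 70.61% passenger vehicle / 9.59% public
  transport / 19.80% walking.
* **Trip counts** are Poisson per user-quarter (default mean 1.8), so some
  users contribute nothing and some many times — exercising contribution
  bounding.
* **Pandemic effects** are per-quarter multipliers on the 2019 laws. The
  strongest quarter, Q2 2020, uses car ×0.8826, transit ×1.179, walking
  ×1.2689; the other 2020 quarters apply the same directions attenuated,
  and a constant 2020 mode shift of 0.22729 moves the passenger-vehicle
  share to 77.28% (shift s reassigns s of the non-car mass to cars, other
  modes rescaled proportionally). Distances are derived from times through
  constant mode speeds (40 / 20 / 4.8 km/h) and the detour factor, so a pure
  time multiplier changes times but leaves the distance law unchanged — the
  "times changed, distances stable" pattern.
* **Population grids** are zero-inflated lognormal per cell (default mean
  200, 25% empty cells) so some tiles fall below the 50-person filter;
  facilities are placed at cell centroids with probability proportional to
  population, without replacement; users' home cells are population-weighted.
* **Outcome tables** plant a monotone link between a country's true travel
  burden and life expectancy (negative), infant mortality (positive) and
  GDP (negative), plus Gaussian noise.

Seeding: a single master seed; per-(country, quarter) substreams are derived
by SHA-256 hashing of the key tuple, so adding a country or quarter never
perturbs the draws of any other.

What the generator does *not* emulate: raw GPS traces, trip segmentation or
stop detection; transit-stop-based mode inference (modes are labels);
road-network routing, traffic or schedules; facility choice beyond
"nearest to home"; within-country urban/rural structure beyond the
population raster; smartphone-ownership selection effects. Passing tests
therefore demonstrate the correctness and calibration of the *methods* under
a controlled data-generating process, not claims about any real country.

## Problem sizes and tolerances

The test suite and the acceptance script size their simulations to be
informative rather than exhaustive: mechanism diagnostics use 10⁵–2×10⁵
draws; the planted-effect recovery uses 50 countries × 20,000 users through
the full DP release (recovering a −12% planted change within ±2 points);
the null calibration uses 200 simulated worlds of 12 countries × 250 users
on exact medians (rejection rate expected in [0.02, 0.10] at α = 0.05); the
end-to-end pipeline run uses 20 countries × 20,000 users over all eleven
study quarters. The near-noiseless consistency checks (ε′ = 100, n = 10⁵,
0.5% tolerance) use 32,768 candidate bins so grid resolution does not
dominate the comparison.

## Known limitations

* The genuine per-country summary tables published with the original study
  are not bundled; recomputation of their headline counts runs against a
  clearly-labelled synthetic stand-in with independently computed expected
  values, and `load_supplementary` accepts the real tables through a
  user-supplied column mapping.
* The per-slice ε applies to each (country, quarter, mode) release
  independently; a user active in many slices is protected per slice, not
  jointly — matching the release design being modelled.
* The default travel-time provider is a speed model, not a router; the
  provider contract is the extension point.
* Facility catchment subtleties (the ~500 m endpoint-matching radius of
  trip extraction, facility choice beyond nearest) are out of scope.
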