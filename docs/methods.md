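# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limitations of the `heatmort` pipeline. It is written for a reader
who wants to know exactly what is computed and what passing tests do and do
not demonstrate.

## Pipeline overview

1. **Synthetic inputs** (`heatmort.synthdata`): counties, demography,
   daily summer temperature series, and station observations.
2. **Calibration** (`heatmort.calibration`): model/observation ratios at
   station counties, spatial interpolation, application by division.
3. **Detection** (`heatmort.heatwaves`): four heat wave definitions over
   calibrated series, against baseline-period thresholds.
4. **Mortality** (`heatmort.mortality`): constant-ratio population
   projection, Latin-hypercube attributable-risk sets, ED = N(RR−1)L.
5. **Uncertainty** (`heatmort.uncertainty`): complete factor grid,
   distribution summaries, first-order variance decomposition.

Everything is driven by one master seed; per-stage seeds are derived as
`(master × 1_000_003 + stage_counter) mod 2^31` with fixed stage counters,
so any stage can be reproduced in isolation.

## Synthetic data: what it emulates, and what it does not

The generator stands in for three real inputs: downscaled gridded
climate-model temperatures, a station observation archive, and census
demography. It emulates the *statistical structure* the downstream stages
rely on, not the physics:

- **Seasonal cycle.** T_avg follows a cosine of day-of-year peaking in
  mid-July, centred so that the May–September mean equals `mean_tavg`
  (default 22.7 °C at the domain reference latitude, matching eastern-US
  summer means). `seasonal_amplitude` (default 11 °C, the annual
  half-range) controls the within-season swing.
- **Geography.** Counties sit on a jittered grid (0.6° × 0.5° spacing, at
  most 17 rows), giving a tall domain spanning up to ~10° of latitude with
  a linear climatological gradient of −0.6 °C per degree latitude. This
  yields the qualitative south–north contrast that matters for the
  definitions: far-south counties are hot and humid enough for heat-index
  events, northern counties sit below the fixed minimum thresholds. States
  are contiguous latitude bands; bands map to the South/Midwest/Northeast
  analysis regions from south to north.
- **Weather.** Daily anomalies are AR(1) with stationary SD `noise_sd`
  (default 3 °C, a typical summer daily-anomaly SD) and lag-1
  autocorrelation 0.6. T_max/T_min are T_avg ± `diurnal_halfrange`
  (default 5.7 °C, splitting the difference between typical
  T_max − T_avg ≈ 6 °C and T_avg − T_min ≈ 5.4 °C offsets) plus a
  day-to-day range perturbation (SD 0.2 × `noise_sd`) so the three
  variables are informative about each other without being collinear. Dew
  point is T_avg minus a fixed spread (default 9 °C, i.e. midday RH
  around 50–60%), floored at the half-range so dew point ≤ T_min.
- **Hot spells.** Additive bumps (default +4 °C) over 2–7 consecutive
  days, Poisson-arriving at `hotspell_rate` per county-season (default
  1.2); every injection is recorded in a truth log so detectors can be
  scored against known events. Tests may also inject an explicit spell
  plan for exact recovery checks.
- **Scenarios.** The future period adds a constant `warming_offset`:
  2.0 °C for the moderate-emission scenario and 3.0 °C for the
  high-emission scenario, reproducing the ~1 °C scenario separation that
  the projection window is expected to show, with fresh weather noise.
- **Stations.** Every `1/station_fraction`-th county in grid order hosts
  one station (default fraction 0.37, the real archive's station-county
  share). Observations are model/`station_bias` (default 1.05) plus
  observation noise (default SD 0.5 °C). Systematic rather than Bernoulli
  sampling guarantees each county support inside the 150-km calibration
  radius at the default fraction — the same coverage property the radius
  was chosen for in the real network.
- **Demography.** Log-normal county populations (median 80k, σ = 0.8),
  baseline non-accidental mortality rates ~N(2.2 × 10⁻⁵, 3 × 10⁻⁶) per
  person-day (≈ 800/100k/year), state 2050 projections as multipliers of
  the 2000 state population: 1.60 / 1.50 / 1.42 / 1.20 for the
  high / constant-medium / low / zero migration assumptions, mirroring the
  tens-of-percent spread of cohort-component projections.

Not emulated: actual synoptic meteorology, urban heat islands, spatially
correlated weather *between* counties (each county's noise is
independent), humidity dynamics (the dew-point spread is constant per
run), coastlines and real geography, age/race/sex structure. Consequently,
passing tests demonstrate that the *methods* are implemented correctly and
behave as the models say they should on data with the assumed structure;
they do not validate the projections against any real population, and the
absolute numbers scale with the synthetic domain (dozens of counties, not
~1,700).

## Calibration

The bias model is multiplicative: station observation = model / bias. The
county ratio is (period mean of model)/(period mean of observations),
computed after (a) averaging multiple stations per county per day and
(b) dropping county-days whose observed value exceeds the 99th percentile
of that county's observations — the screening is by observed temperature,
per county and per variable (a pooled-across-counties variant is
configurable, since either reading is defensible). Ratios are computed
per variable (T_avg, T_max, T_min); dew point is scaled with the T_avg
ratio because no independent humidity reference exists.

Interpolation to all counties uses either the unweighted mean of station
ratios within a fixed 150-km great-circle radius (an empty radius is an
error naming the counties — the radius is meant to guarantee support) or
the mean of the 5 nearest ratios, distance ties broken by ascending county
id. Distances use the haversine formula on a sphere of radius 6,371 km;
at county scale the ellipsoidal correction is irrelevant. Calibration is
applied by division, which maps the model onto the observation scale and
preserves within-county rank order. Future periods are calibrated with
baseline-derived ratios (bias stationarity — no future recalibration data
exist by construction).

## Heat wave definitions

Baseline percentile thresholds are computed per county from all baseline
season days pooled across years, with linear interpolation between order
statistics (the most common percentile convention; fixed for
reproducibility). Minimum thresholds are applied as max(percentile,
floor): 26.7 °C (80 °F) for T_avg, and 21.3 °C / 32.7 °C for T_min/T_max
— the T_avg floor shifted by the 5.4 °C and 6.0 °C mean offsets of T_min
and T_max from T_avg. Choices worth flagging:

- Percentile-threshold comparisons are strict (`>`); the heat-index NWS
  thresholds are inclusive (`≥`), following the definitions' wording
  ("above" vs "no less than").
- The heat-index definition qualifies *days* (low HI ≥ 26.7 °C **and**
  high HI ≥ 40.5 °C); consecutive qualifying days group into one event
  and single days count as events of length 1 (configurable minimum).
  The daily low/high heat index is evaluated from (T_min, dew point) and
  (T_max, dew point) — the inputs are daily, not hourly, which is a
  documented coarsening.
- The heat index uses the NWS operational algorithm: the Rothfusz
  regression with the published low-RH (RH < 13%, 80–112 °F) and high-RH
  (RH > 85%, 80–87 °F) adjustments when the Steadman average reaches
  80 °F, the Steadman average below that, and HI = T at or below 40 °F.
  Relative humidity comes from the Magnus saturation-vapor-pressure
  formula and is clipped at 100% (a single daily dew point can exceed
  T_min).
- The Meehl–Tebaldi T_max definition reports, within each maximal stretch
  of days above T2 (81.5th percentile), the longest window with ≥ 3 days
  above T1 (97.5th percentile) and window-mean T_max above T1, earliest
  start on ties. The 32.7 °C floor applies to T1 only (a single "T_max
  threshold" is floored; applying it to T2 as well is exposed in config),
  and T2 is capped at T1 after flooring so the criteria stay consistent.
  Because one window is reported per warm stretch, the definition's
  event-day total is not monotone under uniform warming (stretches can
  merge), unlike the day-qualification definitions.
- Events never span the season gap (Sep 30 → May 1) or a year boundary.

## Mortality

N is the baseline daily non-accidental mortality rate × (projected)
population, with no exclusion of heat wave days from the person-time
denominator (as the formula is conventionally applied). The baseline rate
is held constant into the future (no adaptation). County projections are
state 2050 projections × the county's 2000 share of its state, held
constant across the projection years (the projections end at 2050;
extrapolating beyond would add an unsupported model). The four population
labels used in reporting (extreme high / high / low / extreme low) map to
the high / constant-medium / low / zero migration assumptions in order.

AR sets: 100 joint Latin-hypercube draws from independent uniforms over
the three regional AR ranges (via `scipy.stats.qmc.LatinHypercube`), of
which 9 are selected uniformly without replacement; all counties of a
region share the region's AR within a set. The South range admits slightly
negative ARs; negative excess-death contributions are retained, not
clamped — the sampled range includes them by construction. A caveat
carried over from the source estimates: the AR CIs were estimated under a
T_avg-based heat wave definition but are applied to all four definitions.

## Uncertainty

The factor grid is complete and balanced by construction (missing cells
are a hard error). On such a grid the first-order index
S_i = V(E[y|x_i])/V(y) is the standard ANOVA main-effect fraction;
population variances are used throughout so that an additive response
decomposes exactly (Σ S_i = 1, residual 0 at machine precision), and all
higher-order terms are pooled into one interaction residual. Confidence
intervals for the pooled estimates are empirical 2.5/97.5 percentiles, not
normal-theory — the pooled distribution is skewed and multimodal across
definitions, so percentiles are the honest summary. Zero total variance
(e.g. a deliberately nulled AR range) yields all-zero indices with a
warning rather than NaNs.

With the default synthetic conditions the decomposition ranks the
attributable risk, the emission scenario, and the heat wave definition
above the calibration method, the population projection, and the year —
the same qualitative ranking the real-data assessments report. The
absolute S_i values depend on the synthetic defaults and the domain size;
only the ranking is asserted by tests (over multiple seeds, since the
pipeline is stochastic).

## Problem sizes and degenerate inputs

Default runs use 40 counties in 6 states (the acceptance script uses 60),
4 baseline years and 3 future years — large enough for stable percentile
thresholds and a populated factor grid, small enough that a full run takes
a few seconds. Degenerate inputs are handled explicitly: empty county
lists, empty year ranges, counties without baseline days, counties without
calibration support, events without demography, and n_select > n_samples
are all errors; a county whose observations are entirely excluded by the
outlier screen is omitted from calibration with a warning; fewer station
ratios than k reduces k with a warning.

## Known limitations

- County weather is spatially independent; real heat waves are regionally
  coherent, so real-world year-to-year variance of domain totals is larger
  than the synthetic analogue suggests.
- The multiplicative station bias is constant; spatially varying bias
  would differentiate the two interpolation rules, which are nearly
  interchangeable here (their S_i is ~0).
- Daily (not hourly) heat-index inputs make the heat-index definition
  more permissive at night and less at midday than the hourly original.
- No exposure-response curve beyond the binary heat-wave AR model, no
  urban/rural effect modification, no demographic change or adaptation.
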