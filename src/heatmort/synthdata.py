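"""Seeded synthetic inputs for the heat wave mortality pipeline.

Generates the three data sets the analysis consumes, with the statistical
structure the downstream stages assume, so every stage runs without any
external download:

* counties and demography — counties on a jittered spatial grid partitioned
  into latitude-band states, each state assigned to one of the three analysis
  regions (South, Midwest, Northeast from south to north); log-normal
  county populations, within-state population shares, and baseline
  non-accidental daily mortality rates;
* daily summer temperature series — a seasonal cosine climatology plus AR(1)
  noise, a north–south temperature gradient, an additive scenario warming
  offset, and injected multi-day hot spells recorded in a truth log;
* station observations — a systematically sampled subset of counties hosts
  one station each; observed values are the model values divided by a
  multiplicative model bias, plus observation noise, so the calibration
  stage has a known ground truth to recover.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

REGIONS = ("South", "Midwest", "Northeast")  # ordered south to north

SERIES_COLUMNS = [
    "county_id",
    "date",
    "year",
    "tavg_c",
    "tmax_c",
    "tmin_c",
    "dewpoint_c",
]

# Grid geometry: county-scale spacing on a tall, narrow rectangle, so the
# domain spans up to ~10 degrees of latitude (a real north-south climate
# contrast) while counties stay dense enough that the 150-km calibration
# search radius always finds support.
_LAT0, _LON0 = 28.0, -82.0
_DLAT, _DLON = 0.6, 0.5
_MAX_ROWS = 17
_JITTER = 0.15
# North-south climatological gradient, °C per degree latitude.
_LAT_GRADIENT = -0.6


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the synthetic summer temperature model.

    ``mean_tavg`` is the season-mean daily average temperature at the domain
    centre; the seasonal cosine is centred so that the May–September mean of
    the climatology equals it. ``diurnal_halfrange`` sets both
    T_max − T_avg and T_avg − T_min. ``warming_offset`` is the additive
    future-minus-baseline shift (°C) of the whole series, emulating the
    scenario separation between moderate and high emission pathways.
    Hot spells are additive bumps of ``hotspell_bump`` °C over consecutive
    days with lengths uniform on {2, …, 7}, occurring at Poisson rate
    ``hotspell_rate`` per county-season. Stations observe
    model / ``station_bias`` + noise.
    """

    season_start: tuple[int, int] = (5, 1)
    season_end: tuple[int, int] = (9, 30)
    mean_tavg: float = 22.7
    seasonal_amplitude: float = 11.0
    diurnal_halfrange: float = 5.7
    dewpoint_spread: float = 9.0
    noise_sd: float = 3.0
    noise_autocorr: float = 0.6
    warming_offset: float = 0.0
    hotspell_rate: float = 1.2
    hotspell_bump: float = 4.0
    station_bias: float = 1.05
    station_fraction: float = 0.37
    obs_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_autocorr < 1.0:
            raise ValueError("noise_autocorr must be in [0, 1)")
        if self.hotspell_rate < 0:
            raise ValueError("hotspell_rate must be >= 0")
        if not 0.0 < self.station_fraction <= 1.0:
            raise ValueError("station_fraction must be in (0, 1]")
        if self.noise_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.station_bias <= 0:
            raise ValueError("station_bias must be positive")

    def replace(self, **kwargs) -> "ClimateParams":
        return dataclasses.replace(self, **kwargs)


def season_dates(year: int, params: ClimateParams) -> pd.DatetimeIndex:
    """Calendar days of the analysis season (default 1 May – 30 Sep) of ``year``."""
    start = pd.Timestamp(year, *params.season_start)
    end = pd.Timestamp(year, *params.season_end)
    if end < start:
        raise ValueError("season_end precedes season_start")
    return pd.date_range(start, end, freq="D")


def generate_counties(
    n_counties: int, n_states: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate county metadata and demography.

    Counties are placed row-major on a jittered grid and split into
    ``n_states`` contiguous latitude bands; bands are assigned to regions
    South/Midwest/Northeast from south to north. Returns
    ``(counties, demography)``: counties with columns ``county_id, state_id,
    region, centroid_lat, centroid_lon`` and demography with ``county_id,
    state_id, region, pop_2000, state_share, mortality_rate`` (non-accidental
    deaths per person per day on non-heat-wave days).
    """
    if n_counties <= 0 or n_states <= 0:
        raise ValueError("n_counties and n_states must be positive")
    if n_counties < n_states:
        raise ValueError("need at least one county per state")
    rng = np.random.default_rng(seed)

    ncols = max(1, int(np.ceil(n_counties / _MAX_ROWS)))
    idx = np.arange(n_counties)
    row, col = idx // ncols, idx % ncols
    lat = _LAT0 + row * _DLAT + rng.uniform(-_JITTER, _JITTER, n_counties)
    lon = _LON0 + col * _DLON + rng.uniform(-_JITTER, _JITTER, n_counties)

    # contiguous latitude bands -> states; rows are already south-to-north
    state_idx = (idx * n_states) // n_counties
    region = [REGIONS[(s * len(REGIONS)) // n_states] for s in state_idx]

    county_id = [f"C{i:04d}" for i in idx]
    state_id = [f"S{s:02d}" for s in state_idx]
    counties = pd.DataFrame(
        {
            "county_id": county_id,
            "state_id": state_id,
            "region": region,
            "centroid_lat": lat,
            "centroid_lon": lon,
        }
    )

    pop = np.round(rng.lognormal(mean=np.log(8e4), sigma=0.8, size=n_counties))
    rate = np.clip(rng.normal(2.2e-5, 3e-6, n_counties), 1.0e-5, None)
    demography = counties[["county_id", "state_id", "region"]].copy()
    demography["pop_2000"] = pop
    demography["state_share"] = pop / demography.groupby("state_id")["pop_2000"].transform("sum")
    demography["mortality_rate"] = rate
    return counties, demography


# State population growth 2000 -> 2050 under the four net-migration
# assumptions (high / constant-medium / low / zero), as multipliers of the
# 2000 state population. Chosen to mirror the spread of national
# cohort-component projections: migration moves the 2050 total by tens of
# percent, not factors.
GROWTH_MULTIPLIERS = {
    "high": 1.60,
    "constant_medium": 1.50,
    "low": 1.42,
    "zero": 1.20,
}


def generate_state_projections(
    demography: pd.DataFrame,
    multipliers: dict[str, float] | None = None,
) -> pd.DataFrame:
    """2050 state population projections per migration scenario.

    Returns a frame with columns ``state_id, scenario, pop_2050`` where each
    state's projection is its 2000 population times the scenario multiplier.
    """
    multipliers = GROWTH_MULTIPLIERS if multipliers is None else multipliers
    state_pop = demography.groupby("state_id", as_index=False)["pop_2000"].sum()
    rows = []
    for scenario, mult in multipliers.items():
        rows.append(
            pd.DataFrame(
                {
                    "state_id": state_pop["state_id"],
                    "scenario": scenario,
                    "pop_2050": state_pop["pop_2000"] * mult,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _climatology(dates: pd.DatetimeIndex, params: ClimateParams) -> np.ndarray:
    """Season-centred cosine climatology of T_avg (domain centre, no noise)."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    phase = np.cos(2.0 * np.pi * (doy - 196.0) / 365.25)  # peak mid-July
    # centre the cosine so the season-window mean equals mean_tavg
    season = season_dates(2001, params)
    sdoy = season.dayofyear.to_numpy(dtype=float)
    centre = np.cos(2.0 * np.pi * (sdoy - 196.0) / 365.25).mean()
    return params.mean_tavg + params.seasonal_amplitude * (phase - centre)


def _draw_spells(
    rng: np.random.Generator, n_days: int, params: ClimateParams
) -> list[tuple[int, int]]:
    """Poisson number of (start_index, length) hot spells for one county-season."""
    n = rng.poisson(params.hotspell_rate)
    out = []
    for _ in range(n):
        length = int(rng.integers(2, 8))  # uniform on {2..7}
        start = int(rng.integers(0, max(n_days - length, 1)))
        out.append((start, length))
    return out


def generate_temperatures(
    counties: pd.DataFrame,
    params: ClimateParams,
    years: tuple[int, ...] | range,
    spells: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate daily county temperature series for the season window of ``years``.

    Returns ``(series, truth_log)``. ``series`` has one row per county-day
    with columns :data:`SERIES_COLUMNS`; T_max/T_min are T_avg ± the diurnal
    half-range plus a day-to-day range perturbation (sd 0.2 × ``noise_sd``,
    never shrinking the range below 0.5 °C) so the three variables are not
    perfectly collinear, and dew point is T_avg minus a spread bounded below
    by the half-range. ``truth_log`` records every injected hot spell
    (``county_id, year, start_date, length_days, bump_c``) for recovery
    tests. If ``spells`` is given (same columns as the truth log, bump
    optional) those spells are injected verbatim instead of Poisson draws.
    """
    if len(counties) == 0:
        raise ValueError("empty county list")
    years = tuple(years)
    if not years:
        raise ValueError("empty year range")
    rng = np.random.default_rng(params.seed)

    frames = []
    truth_rows = []
    for _, county in counties.reset_index(drop=True).iterrows():
        county_lat_effect = _LAT_GRADIENT * (county["centroid_lat"] - (_LAT0 + 5.0))
        for year in years:
            dates = season_dates(year, params)
            n = len(dates)
            clim = _climatology(dates, params)
            # AR(1) noise, stationary sd = noise_sd
            noise = np.zeros(n)
            if params.noise_sd > 0:
                z = rng.standard_normal(n)
                phi = params.noise_autocorr
                noise[0] = params.noise_sd * z[0]
                scale = params.noise_sd * np.sqrt(1.0 - phi**2)
                for t in range(1, n):
                    noise[t] = phi * noise[t - 1] + scale * z[t]
            bump = np.zeros(n)
            if spells is None:
                for start, length in _draw_spells(rng, n, params):
                    bump[start : start + length] += params.hotspell_bump
                    truth_rows.append(
                        (county["county_id"], year, dates[start], length, params.hotspell_bump)
                    )
            tavg = clim + county_lat_effect + params.warming_offset + noise + bump
            frames.append(
                pd.DataFrame(
                    {
                        "county_id": county["county_id"],
                        "date": dates,
                        "year": year,
                        "tavg_c": tavg,
                    }
                )
            )
    series = pd.concat(frames, ignore_index=True)

    if spells is not None:
        for _, sp in spells.iterrows():
            bump_c = float(sp.get("bump_c", params.hotspell_bump))
            start = pd.Timestamp(sp["start_date"])
            mask = (
                (series["county_id"] == sp["county_id"])
                & (series["date"] >= start)
                & (series["date"] < start + pd.Timedelta(days=int(sp["length_days"])))
            )
            series.loc[mask, "tavg_c"] += bump_c
            truth_rows.append(
                (sp["county_id"], start.year, start, int(sp["length_days"]), bump_c)
            )

    range_sd = 0.2 * params.noise_sd
    if range_sd > 0:
        e_hi = rng.normal(0.0, range_sd, len(series))
        e_lo = rng.normal(0.0, range_sd, len(series))
    else:
        e_hi = e_lo = 0.0
    series["tmax_c"] = series["tavg_c"] + np.maximum(0.5, params.diurnal_halfrange + e_hi)
    series["tmin_c"] = series["tavg_c"] - np.maximum(0.5, params.diurnal_halfrange + e_lo)
    spread = max(params.dewpoint_spread, params.diurnal_halfrange)
    series["dewpoint_c"] = series["tavg_c"] - spread
    series = series[SERIES_COLUMNS]

    truth_log = pd.DataFrame(
        truth_rows, columns=["county_id", "year", "start_date", "length_days", "bump_c"]
    )
    return series, truth_log


def generate_stations(
    series: pd.DataFrame,
    counties: pd.DataFrame,
    params: ClimateParams,
) -> pd.DataFrame:
    """Synthetic station observations at a systematic subset of counties.

    Every ``1/station_fraction``-th county in grid order hosts one station
    (systematic spatial sampling, so station coverage is even and every
    county has support within the fixed-radius calibration search).
    Observations are model value / ``station_bias`` + Gaussian noise.
    Returns columns ``station_id, county_id, lat, lon, date, obs_tavg_c,
    obs_tmax_c, obs_tmin_c``.
    """
    rng = np.random.default_rng(params.seed + 1)
    n = len(counties)
    step = 1.0 / params.station_fraction
    n_stations = max(1, round(n * params.station_fraction))
    offset = rng.uniform(0.0, step)
    # wrap-around systematic sample: gaps between hosts never exceed
    # ceil(step) grid positions, so radius coverage is guaranteed at the
    # default station fraction
    host_idx = np.unique(
        np.floor(offset + step * np.arange(n_stations)).astype(int) % n
    )
    hosts = counties.reset_index(drop=True).iloc[host_idx]

    obs = series.merge(
        hosts[["county_id", "centroid_lat", "centroid_lon"]], on="county_id", how="inner"
    )
    out = pd.DataFrame(
        {
            "station_id": "M" + obs["county_id"].str.slice(1),
            "county_id": obs["county_id"],
            "lat": obs["centroid_lat"],
            "lon": obs["centroid_lon"],
            "date": obs["date"],
        }
    )
    for var in ("tavg_c", "tmax_c", "tmin_c"):
        noise = (
            rng.normal(0.0, params.obs_noise_sd, len(obs)) if params.obs_noise_sd > 0 else 0.0
        )
        out["obs_" + var] = obs[var] / params.station_bias + noise
    return out.sort_values(["station_id", "date"]).reset_index(drop=True)
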