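"""Heat wave definitions, event detection, and summaries.

Four operational heat wave definitions (HWDs) over daily summer
(May–September) county series:

``HWD_HI``
    Days whose daily low and high heat index are no less than the National
    Weather Service thresholds of 26.7 °C (80 °F) and 40.5 °C (105 °F);
    consecutive qualifying days form one event (single days count, L = 1).
``HWD_Tavg``
    At least 2 consecutive days with daily mean temperature strictly above
    the baseline 95th percentile of T_avg, with a 26.7 °C minimum threshold.
``HWD_Tmax``
    Meehl–Tebaldi: within a stretch of days all above T2 (the baseline
    81.5th percentile of T_max), the longest window with (a) at least 3 days
    above T1 (97.5th percentile, 32.7 °C minimum) and (b) window-mean T_max
    above T1.
``HWD_Tmin``
    At least 2 consecutive days with daily minimum temperature strictly
    above the baseline 95th percentile of T_min, with a 21.3 °C minimum
    threshold.

Percentile thresholds are computed per county over all baseline season days
pooled across years (linear interpolation between order statistics) and the
minimum thresholds are applied as ``max(percentile, floor)``. Events never
span the gap between seasons. The daily low/high heat index is evaluated
from (T_min, dew point) and (T_max, dew point) respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from heatmort.units import c_to_f, f_to_c

HWD_KINDS = ("HWD_HI", "HWD_Tavg", "HWD_Tmax", "HWD_Tmin")

EVENT_COLUMNS = [
    "county_id",
    "definition",
    "year",
    "start_date",
    "length_days",
    "mean_intensity_c",
]


@dataclass(frozen=True)
class HWDConfig:
    """Thresholds and minimum lengths of the four heat wave definitions."""

    hi_low_threshold: float = 26.7  # °C, 80 °F
    hi_high_threshold: float = 40.5  # °C, 105 °F
    tavg_floor: float = 26.7
    tmin_floor: float = 21.3
    tmax_floor: float = 32.7
    pct_tavg: float = 0.95
    pct_tmin: float = 0.95
    pct_tmax_t1: float = 0.975
    pct_tmax_t2: float = 0.815
    min_len_tavg: int = 2
    min_len_tmin: int = 2
    min_len_tmax: int = 3
    min_len_hi: int = 1
    tmax_floor_scope: str = "t1"  # "t1" or "both"

    def __post_init__(self) -> None:
        for p in (self.pct_tavg, self.pct_tmin, self.pct_tmax_t1, self.pct_tmax_t2):
            if not 0.0 < p < 1.0:
                raise ValueError("percentiles must be in (0, 1)")
        for m in (self.min_len_tavg, self.min_len_tmin, self.min_len_tmax, self.min_len_hi):
            if m < 1:
                raise ValueError("minimum lengths must be >= 1")
        if self.tmax_floor_scope not in ("t1", "both"):
            raise ValueError("tmax_floor_scope must be 't1' or 'both'")


def _saturation_vapor_pressure_hpa(temp_c: np.ndarray) -> np.ndarray:
    # Magnus formula
    return 6.112 * np.exp(17.67 * temp_c / (temp_c + 243.5))


def relative_humidity(temp_c, dewpoint_c) -> np.ndarray:
    """Relative humidity (%) from temperature and dew point via Magnus.

    Clipped to [0, 100]; a dew point above the temperature (possible when a
    single daily dew point is paired with T_min) saturates at 100%.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    dewpoint_c = np.asarray(dewpoint_c, dtype=float)
    rh = 100.0 * _saturation_vapor_pressure_hpa(dewpoint_c) / _saturation_vapor_pressure_hpa(temp_c)
    return np.clip(rh, 0.0, 100.0)


def heat_index(temp_c, dewpoint_c):
    """NWS heat index (°C) from temperature and dew point (°C).

    Uses the Rothfusz regression with the published low-humidity and
    high-humidity adjustments when the simple Steadman average reaches the
    80 °F applicability bound, the Steadman average below it, and the
    convention that the heat index equals the temperature at or below 40 °F.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    if np.any(temp_c < -90.0) or np.any(temp_c > 60.0):
        raise ValueError("temperature outside physical range [-90, 60] °C")
    rh = relative_humidity(temp_c, dewpoint_c)
    t = c_to_f(temp_c)

    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + rh * 0.094)
    hi = -42.379 + 2.04901523 * t + 10.14333127 * rh
    hi += -0.22475541 * t * rh - 6.83783e-3 * t**2 - 5.481717e-2 * rh**2
    hi += 1.22874e-3 * t**2 * rh + 8.5282e-4 * t * rh**2 - 1.99e-6 * t**2 * rh**2
    low_rh = (rh < 13.0) & (t >= 80.0) & (t <= 112.0)
    hi = np.where(
        low_rh,
        hi - ((13.0 - rh) / 4.0) * np.sqrt(np.clip(17.0 - np.abs(t - 95.0), 0.0, None) / 17.0),
        hi,
    )
    high_rh = (rh > 85.0) & (t >= 80.0) & (t <= 87.0)
    hi = np.where(high_rh, hi + ((rh - 85.0) / 10.0) * ((87.0 - t) / 5.0), hi)

    out = np.where(simple >= 80.0, hi, simple)
    out = np.where(t <= 40.0, t, out)
    return f_to_c(out) if out.shape else float(f_to_c(out))


def compute_thresholds(
    baseline_series: pd.DataFrame,
    config: HWDConfig = HWDConfig(),
    counties: list[str] | None = None,
) -> pd.DataFrame:
    """Per-county detection thresholds from pooled baseline season days.

    Returns one row per county with ``thr_tavg, thr_tmin, tmax_t1, tmax_t2``.
    Floors are applied as ``max(percentile, floor)``; T2 is capped at T1 so
    the Meehl–Tebaldi criteria stay consistent after flooring.
    """
    if baseline_series.empty:
        raise ValueError("baseline series is empty")
    if counties is not None:
        missing = set(counties) - set(baseline_series["county_id"].unique())
        if missing:
            raise ValueError(f"no baseline days for counties: {sorted(missing)}")

    grp = baseline_series.groupby("county_id")
    thr = pd.DataFrame(
        {
            "thr_tavg": grp["tavg_c"].quantile(config.pct_tavg, interpolation="linear"),
            "thr_tmin": grp["tmin_c"].quantile(config.pct_tmin, interpolation="linear"),
            "tmax_t1": grp["tmax_c"].quantile(config.pct_tmax_t1, interpolation="linear"),
            "tmax_t2": grp["tmax_c"].quantile(config.pct_tmax_t2, interpolation="linear"),
        }
    ).reset_index()
    thr["thr_tavg"] = thr["thr_tavg"].clip(lower=config.tavg_floor)
    thr["thr_tmin"] = thr["thr_tmin"].clip(lower=config.tmin_floor)
    thr["tmax_t1"] = thr["tmax_t1"].clip(lower=config.tmax_floor)
    if config.tmax_floor_scope == "both":
        thr["tmax_t2"] = thr["tmax_t2"].clip(lower=config.tmax_floor)
    thr["tmax_t2"] = thr[["tmax_t1", "tmax_t2"]].min(axis=1)
    return thr


def _iter_county_years(series: pd.DataFrame):
    for (county_id, year), grp in series.groupby(["county_id", "year"], sort=True):
        yield county_id, int(year), grp.sort_values("date").reset_index(drop=True)


def _maximal_runs(mask: np.ndarray, day_gap: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True over consecutive calendar days.

    ``day_gap[i]`` is True where row i is not the calendar day after row
    i−1, which breaks a run.
    """
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and (start is None or day_gap[i]):
            if start is not None:
                runs.append((start, i - start))
            start = i
        elif not flag and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def _gap_breaks(dates: pd.Series) -> np.ndarray:
    d = pd.to_datetime(dates).to_numpy()
    breaks = np.zeros(len(d), dtype=bool)
    if len(d) > 1:
        breaks[1:] = np.diff(d) != np.timedelta64(1, "D")
    return breaks


def _events_from_runs(
    grp: pd.DataFrame,
    runs: list[tuple[int, int]],
    county_id: str,
    year: int,
    definition: str,
    variable: str,
    min_len: int,
) -> list[dict]:
    events = []
    for start, length in runs:
        if length < min_len:
            continue
        window = grp.iloc[start : start + length]
        events.append(
            {
                "county_id": county_id,
                "definition": definition,
                "year": year,
                "start_date": window["date"].iloc[0],
                "length_days": length,
                "mean_intensity_c": float(window[variable].mean()),
            }
        )
    return events


def detect_runs(
    series: pd.DataFrame,
    thresholds: pd.DataFrame | float,
    variable: str,
    min_len: int,
    definition: str,
    threshold_column: str | None = None,
) -> pd.DataFrame:
    """Threshold-exceedance events: maximal runs of days strictly above threshold.

    ``thresholds`` is either a scalar or a per-county frame; runs shorter
    than ``min_len`` are dropped and runs never cross the seasonal gap or a
    year boundary. Used for the T_avg and T_min definitions.
    """
    if isinstance(thresholds, (int, float)):
        thr_map = None
        scalar = float(thresholds)
    else:
        col = threshold_column or {"tavg_c": "thr_tavg", "tmin_c": "thr_tmin"}[variable]
        thr_map = thresholds.set_index("county_id")[col]
        scalar = np.nan
    events = []
    for county_id, year, grp in _iter_county_years(series):
        thr = scalar if thr_map is None else float(thr_map[county_id])
        mask = grp[variable].to_numpy() > thr
        runs = _maximal_runs(mask, _gap_breaks(grp["date"]))
        events.extend(
            _events_from_runs(grp, runs, county_id, year, definition, variable, min_len)
        )
    return pd.DataFrame(events, columns=EVENT_COLUMNS)


def detect_hi_days(series: pd.DataFrame, config: HWDConfig = HWDConfig()) -> pd.DataFrame:
    """Heat-index definition: days with low HI ≥ 26.7 °C and high HI ≥ 40.5 °C.

    The daily low/high heat index is computed from (T_min, dew point) and
    (T_max, dew point). Consecutive qualifying days are grouped into one
    event; by default single qualifying days are events of length 1.
    """
    if "dewpoint_c" not in series.columns or series["dewpoint_c"].isna().any():
        bad = (
            series.loc[series.get("dewpoint_c", pd.Series(dtype=float)).isna(), "county_id"].unique()
            if "dewpoint_c" in series.columns
            else series["county_id"].unique()
        )
        raise ValueError(f"dew point missing for counties: {sorted(map(str, bad))}")
    work = series.copy()
    work["hi_low"] = heat_index(work["tmin_c"], work["dewpoint_c"])
    work["hi_high"] = heat_index(work["tmax_c"], work["dewpoint_c"])
    events = []
    for county_id, year, grp in _iter_county_years(work):
        mask = (grp["hi_low"].to_numpy() >= config.hi_low_threshold) & (
            grp["hi_high"].to_numpy() >= config.hi_high_threshold
        )
        runs = _maximal_runs(mask, _gap_breaks(grp["date"]))
        events.extend(
            _events_from_runs(grp, runs, county_id, year, "HWD_HI", "hi_high", config.min_len_hi)
        )
    return pd.DataFrame(events, columns=EVENT_COLUMNS)


def _best_window(tmax: np.ndarray, t1: float, min_hot: int) -> tuple[int, int] | None:
    """Longest window with ≥ min_hot days > t1 and mean > t1; earliest on ties."""
    n = len(tmax)
    best = None
    for length in range(n, min_hot - 1, -1):
        for start in range(0, n - length + 1):
            w = tmax[start : start + length]
            if int((w > t1).sum()) >= min_hot and w.mean() > t1:
                best = (start, length)
                break
        if best is not None:
            break
    return best


def detect_meehl_tebaldi(
    series: pd.DataFrame,
    thresholds: pd.DataFrame,
    config: HWDConfig = HWDConfig(),
) -> pd.DataFrame:
    """Meehl–Tebaldi T_max definition.

    Within each maximal stretch of days with T_max > T2, the event is the
    longest window containing at least ``min_len_tmax`` days with T_max > T1
    and with window-mean T_max > T1 (earliest start on length ties). Events
    from distinct stretches never overlap.
    """
    thr = thresholds.set_index("county_id")[["tmax_t1", "tmax_t2"]]
    events = []
    for county_id, year, grp in _iter_county_years(series):
        t1, t2 = float(thr.loc[county_id, "tmax_t1"]), float(thr.loc[county_id, "tmax_t2"])
        if t2 > t1:
            raise ValueError(f"tmax_t2 > tmax_t1 for county {county_id}")
        tmax = grp["tmax_c"].to_numpy()
        runs = _maximal_runs(tmax > t2, _gap_breaks(grp["date"]))
        for start, length in runs:
            found = _best_window(tmax[start : start + length], t1, config.min_len_tmax)
            if found is None:
                continue
            off, wlen = found
            events.extend(
                _events_from_runs(
                    grp, [(start + off, wlen)], county_id, year, "HWD_Tmax", "tmax_c", 1
                )
            )
    return pd.DataFrame(events, columns=EVENT_COLUMNS)


def detect(
    series: pd.DataFrame,
    thresholds: pd.DataFrame,
    config: HWDConfig = HWDConfig(),
    kind: str = "HWD_Tavg",
) -> pd.DataFrame:
    """Dispatch detection for one heat wave definition."""
    if kind == "HWD_HI":
        return detect_hi_days(series, config)
    if kind == "HWD_Tavg":
        return detect_runs(series, thresholds, "tavg_c", config.min_len_tavg, "HWD_Tavg")
    if kind == "HWD_Tmin":
        return detect_runs(series, thresholds, "tmin_c", config.min_len_tmin, "HWD_Tmin")
    if kind == "HWD_Tmax":
        return detect_meehl_tebaldi(series, thresholds, config)
    raise ValueError(f"unknown heat wave definition: {kind}")


def summarize(events: pd.DataFrame, n_years: int, n_counties: int) -> pd.DataFrame:
    """Frequency and duration summary per definition.

    Frequency is episodes / (years × counties); duration is the mean ± SD of
    event lengths (absent when there are no events). Definitions with zero
    events still get a row with frequency 0.
    """
    if n_years < 1 or n_counties < 1:
        raise ValueError("n_years and n_counties must be >= 1")
    rows = []
    present = events["definition"].unique().tolist() if not events.empty else []
    for kind in HWD_KINDS:
        sub = events[events["definition"] == kind] if kind in present else events.iloc[0:0]
        row = {
            "definition": kind,
            "n_events": len(sub),
            "frequency": len(sub) / (n_years * n_counties),
            "duration_mean": float(sub["length_days"].mean()) if len(sub) else np.nan,
            "duration_sd": float(sub["length_days"].std(ddof=1)) if len(sub) > 1 else np.nan,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_by_county(events: pd.DataFrame, n_years: int) -> pd.DataFrame:
    """Per-county event counts per year and mean duration, per definition."""
    if events.empty:
        return pd.DataFrame(columns=["county_id", "definition", "frequency", "duration_mean"])
    g = events.groupby(["county_id", "definition"])
    out = g.agg(n_events=("length_days", "size"), duration_mean=("length_days", "mean"))
    out["frequency"] = out["n_events"] / n_years
    return out.reset_index()[["county_id", "definition", "frequency", "duration_mean"]]
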