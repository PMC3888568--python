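"""Model-to-observation temperature calibration.

Gridded-model output carries a systematic bias relative to station
observations. Calibration proceeds in three steps:

1. at each station county, take the ratio of the period-mean model value to
   the period-mean observed value (after excluding county-days whose
   observed temperature exceeds the 99th percentile of that county's
   observations, and after averaging multiple stations per county per day);
2. interpolate the station-county ratios to every county, either as the
   unweighted mean of all ratios within a fixed 150-km great-circle radius
   of the county centroid, or as the mean of the five nearest ratios;
3. divide each county's model series by its ratio (ratio = model/obs, so
   division maps the model onto the observation scale).

Ratios are computed per variable (T_avg, T_max, T_min). Dew point is scaled
with the T_avg ratio, since the bias model applies to the whole thermal
profile and no independent humidity reference exists.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
VARIABLES = ("tavg_c", "tmax_c", "tmin_c")
RATIO_COLUMNS = ["ratio_tavg", "ratio_tmax", "ratio_tmin"]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def compute_county_ratios(
    model_series: pd.DataFrame,
    station_obs: pd.DataFrame,
    exclusion_quantile: float = 0.99,
    exclusion_scope: str = "county",
) -> pd.DataFrame:
    """Calibration ratios (model mean / observation mean) at station counties.

    Multiple stations within a county are averaged per day before the ratio.
    For each variable, county-days whose observed value exceeds the
    ``exclusion_quantile`` of the observations (per county by default, or
    pooled over all counties with ``exclusion_scope='pooled'``) are dropped
    before taking period means. Counties with no surviving days are omitted
    with a warning.

    Returns one row per station county: ``county_id``, per-variable ratio
    columns, ``n_support`` (=1) and ``method`` (='station').
    """
    if not 0.0 < exclusion_quantile <= 1.0:
        raise ValueError("exclusion_quantile must be in (0, 1]")
    if exclusion_scope not in ("county", "pooled"):
        raise ValueError("exclusion_scope must be 'county' or 'pooled'")

    obs_cols = {v: "obs_" + v for v in VARIABLES}
    daily = (
        station_obs.groupby(["county_id", "date"], as_index=False)[list(obs_cols.values())]
        .mean()
    )
    merged = daily.merge(model_series[["county_id", "date", *VARIABLES]], on=["county_id", "date"], how="inner")
    if merged.empty:
        raise ValueError("model and observation series do not overlap on any county-day")

    rows = []
    dropped = []
    for county_id, grp in merged.groupby("county_id", sort=True):
        ratios = {}
        ok = True
        for var in VARIABLES:
            obs = grp[obs_cols[var]]
            pool = merged[obs_cols[var]] if exclusion_scope == "pooled" else obs
            cut = pool.quantile(exclusion_quantile, interpolation="linear")
            keep = obs <= cut
            if not keep.any():
                ok = False
                break
            ratios["ratio_" + var.split("_")[0]] = (
                grp.loc[keep, var].mean() / obs[keep].mean()
            )
        if ok:
            rows.append({"county_id": county_id, **ratios, "n_support": 1, "method": "station"})
        else:
            dropped.append(county_id)
    if dropped:
        warnings.warn(
            f"counties omitted from calibration (no surviving days): {dropped}", stacklevel=2
        )
    return pd.DataFrame(rows, columns=["county_id", *RATIO_COLUMNS, "n_support", "method"])


def _station_geometry(ratios: pd.DataFrame, counties: pd.DataFrame) -> pd.DataFrame:
    geo = ratios.merge(
        counties[["county_id", "centroid_lat", "centroid_lon"]], on="county_id", how="left"
    )
    if geo["centroid_lat"].isna().any():
        missing = geo.loc[geo["centroid_lat"].isna(), "county_id"].tolist()
        raise ValueError(f"no centroid for station counties: {missing}")
    return geo.sort_values("county_id").reset_index(drop=True)


def interpolate_fixed_radius(
    ratios: pd.DataFrame, counties: pd.DataFrame, radius_km: float = 150.0
) -> pd.DataFrame:
    """County ratios as the unweighted mean of station ratios within ``radius_km``.

    Raises if any county has no station ratio inside its search radius,
    naming the offending counties (the radius is meant to be chosen so this
    cannot happen).
    """
    if ratios.empty:
        raise ValueError("no station-county ratios available")
    geo = _station_geometry(ratios, counties)
    out_rows = []
    empty = []
    for _, county in counties.iterrows():
        d = haversine_km(
            county["centroid_lat"], county["centroid_lon"], geo["centroid_lat"], geo["centroid_lon"]
        )
        within = d <= radius_km
        if not within.any():
            empty.append(county["county_id"])
            continue
        row = {"county_id": county["county_id"]}
        for col in RATIO_COLUMNS:
            row[col] = geo.loc[within, col].mean()
        row["n_support"] = int(within.sum())
        row["method"] = "fixed_radius"
        out_rows.append(row)
    if empty:
        raise ValueError(
            f"no calibration ratio within {radius_km} km for counties: {empty}"
        )
    return pd.DataFrame(out_rows)


def interpolate_nearest_k(
    ratios: pd.DataFrame, counties: pd.DataFrame, k: int = 5
) -> pd.DataFrame:
    """County ratios as the mean of the ``k`` nearest station ratios.

    Distance ties for the k-th slot are broken by ascending county id. If
    fewer than ``k`` station ratios exist, ``k`` is reduced with a warning.
    """
    if ratios.empty:
        raise ValueError("no station-county ratios available")
    if k < 1:
        raise ValueError("k must be >= 1")
    geo = _station_geometry(ratios, counties)
    if len(geo) < k:
        warnings.warn(
            f"only {len(geo)} station ratios available; reducing k from {k}", stacklevel=2
        )
        k = len(geo)
    out_rows = []
    for _, county in counties.iterrows():
        d = haversine_km(
            county["centroid_lat"], county["centroid_lon"], geo["centroid_lat"], geo["centroid_lon"]
        )
        # stable mergesort on distance over the county_id-sorted frame
        # implements the ascending-county-id tie rule
        order = np.argsort(d, kind="mergesort")[:k]
        row = {"county_id": county["county_id"]}
        for col in RATIO_COLUMNS:
            row[col] = geo[col].iloc[order].mean()
        row["n_support"] = k
        row["method"] = "nearest_k"
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def apply_calibration(series: pd.DataFrame, ratios: pd.DataFrame) -> pd.DataFrame:
    """Divide each temperature variable by its county ratio.

    Division maps model values toward the observation scale (ratio =
    model/obs). Dew point is divided by the T_avg ratio. Day ordering is
    preserved; a county in the series without a ratio is an error.
    """
    missing = set(series["county_id"].unique()) - set(ratios["county_id"])
    if missing:
        raise ValueError(f"no calibration ratio for counties: {sorted(missing)}")
    merged = series.merge(ratios[["county_id", *RATIO_COLUMNS]], on="county_id", how="left")
    out = series.copy()
    out["tavg_c"] = merged["tavg_c"].to_numpy() / merged["ratio_tavg"].to_numpy()
    out["tmax_c"] = merged["tmax_c"].to_numpy() / merged["ratio_tmax"].to_numpy()
    out["tmin_c"] = merged["tmin_c"].to_numpy() / merged["ratio_tmin"].to_numpy()
    if "dewpoint_c" in out.columns:
        out["dewpoint_c"] = merged["dewpoint_c"].to_numpy() / merged["ratio_tavg"].to_numpy()
    return out
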