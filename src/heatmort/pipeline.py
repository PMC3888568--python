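"""End-to-end pipeline: generate → calibrate → detect → estimate → decompose.

A single :class:`RunConfig` (optionally loaded from YAML) drives a fully
seeded run. One master seed derives per-stage seeds by a fixed counter
scheme, ``stage_seed = (master × 1_000_003 + stage) mod 2^31`` with stage
numbers 0 counties, 1 baseline climate, 2/3 future climate per emission
scenario, 4 stations, 5 attributable-risk sampling — so any stage can be
re-run reproducibly on its own.

The factor grid evaluated for the uncertainty analysis crosses emission
scenario × calibration method × heat wave definition × population
projection × AR set × projection year (2×2×4×4×9×3 = 1,728 cells at the
defaults). A parallel baseline grid (baseline years, 2000 populations)
supports future/baseline ratio reporting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from heatmort import calibration as cal
from heatmort import heatwaves as hw
from heatmort import mortality as mort
from heatmort import synthdata as synth
from heatmort import uncertainty as unc

RCP_SCENARIOS = ("rcp45", "rcp85")
STAGE_COUNTERS = {"counties": 0, "baseline": 1, "rcp45": 2, "rcp85": 3, "stations": 4, "ar": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed by a fixed counter scheme."""
    return (master_seed * 1_000_003 + STAGE_COUNTERS[stage]) % 2**31


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    n_counties: int = 40
    n_states: int = 6
    baseline_years: tuple[int, ...] = (2001, 2002, 2003, 2004)
    future_years: tuple[int, ...] = (2057, 2058, 2059)
    master_seed: int = 0
    climate: dict = field(default_factory=dict)  # ClimateParams overrides
    warming_offsets: dict = field(default_factory=lambda: {"rcp45": 2.0, "rcp85": 3.0})
    hwd: dict = field(default_factory=dict)  # HWDConfig overrides
    hwd_kinds: tuple[str, ...] = hw.HWD_KINDS
    calibration_methods: tuple[str, ...] = ("fixed_radius", "nearest_k")
    radius_km: float = 150.0
    k_nearest: int = 5
    exclusion_quantile: float = 0.99
    ar_ranges: dict | None = None
    ar_n_samples: int = 100
    ar_n_select: int = 9
    growth_multipliers: dict | None = None
    cumulative_thresholds: tuple[float, ...] = (1000.0, 2000.0, 5000.0)
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("baseline_years", "future_years", "hwd_kinds", "calibration_methods",
                    "cumulative_thresholds"):
            d[key] = list(d[key])
        if d["ar_ranges"] is not None:
            d["ar_ranges"] = {k: list(v) for k, v in d["ar_ranges"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("baseline_years", "future_years", "hwd_kinds", "calibration_methods",
                    "cumulative_thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("ar_ranges"):
            d["ar_ranges"] = {k: tuple(v) for k, v in d["ar_ranges"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle of every artifact one run produces."""

    config: RunConfig
    counties: pd.DataFrame
    demography: pd.DataFrame
    state_projections: pd.DataFrame
    station_ratios: pd.DataFrame
    ratios: dict[str, pd.DataFrame]
    ar_sets: pd.DataFrame
    events: pd.DataFrame  # future events, tagged with rcp and calibration
    baseline_events: pd.DataFrame  # tagged with calibration
    grid: pd.DataFrame
    baseline_grid: pd.DataFrame
    hw_summary: pd.DataFrame
    climate_summary: pd.DataFrame
    distribution: pd.DataFrame
    sensitivity: pd.DataFrame
    manifest: dict


def _cell_totals(
    events: pd.DataFrame,
    demography: pd.DataFrame,
    populations: dict[str, pd.Series],
    ar_sets: pd.DataFrame,
    years: tuple[int, ...],
    regions: list[str],
) -> list[dict]:
    """Totals for (year × pop scenario × AR set), vectorized over events.

    Exploits the linearity of ED = Σ rate × pop × AR × L: events are
    aggregated to per-(year, region) weights once per population scenario,
    then each AR set is a dot product.
    """
    rows = []
    if events.empty:
        weights = {sc: pd.DataFrame() for sc in populations}
    else:
        demo = demography.set_index("county_id")
        ev = events.copy()
        ev["rate"] = demo.loc[ev["county_id"], "mortality_rate"].to_numpy()
        ev["region"] = demo.loc[ev["county_id"], "region"].to_numpy()
        weights = {}
        for sc, pop in populations.items():
            ev["w"] = ev["rate"] * pop.loc[ev["county_id"]].to_numpy() * ev["length_days"]
            weights[sc] = ev.groupby(["year", "region"])["w"].sum().unstack(fill_value=0.0)
    for year in years:
        for sc in populations:
            w = weights[sc]
            for _, ar_row in ar_sets.iterrows():
                total = 0.0
                if len(w) and year in w.index:
                    for region in regions:
                        if region in w.columns:
                            total += w.loc[year, region] * float(ar_row[region])
                rows.append(
                    {
                        "year": year,
                        "pop_scenario": sc,
                        "ar_set": int(ar_row["set_index"]),
                        "total_excess_deaths": total,
                    }
                )
    return rows


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Run every stage from a single config; deterministic given the master seed."""
    config = config or RunConfig()
    ms = config.master_seed

    counties, demography = synth.generate_counties(
        config.n_counties, config.n_states, stage_seed(ms, "counties")
    )
    state_projections = synth.generate_state_projections(demography, config.growth_multipliers)
    regions = sorted(demography["region"].unique().tolist())

    base_params = synth.ClimateParams(
        **{**config.climate, "warming_offset": 0.0, "seed": stage_seed(ms, "baseline")}
    )
    baseline_series, _ = synth.generate_temperatures(counties, base_params, config.baseline_years)
    stations = synth.generate_stations(
        baseline_series, counties, base_params.replace(seed=stage_seed(ms, "stations"))
    )
    station_ratios = cal.compute_county_ratios(
        baseline_series, stations, config.exclusion_quantile
    )
    ratios = {}
    for method in config.calibration_methods:
        if method == "fixed_radius":
            ratios[method] = cal.interpolate_fixed_radius(
                station_ratios, counties, config.radius_km
            )
        elif method == "nearest_k":
            ratios[method] = cal.interpolate_nearest_k(station_ratios, counties, config.k_nearest)
        else:
            raise ValueError(f"unknown calibration method: {method}")

    future_series = {}
    for rcp in RCP_SCENARIOS:
        params = base_params.replace(
            warming_offset=float(config.warming_offsets[rcp]), seed=stage_seed(ms, rcp)
        )
        future_series[rcp], _ = synth.generate_temperatures(counties, params, config.future_years)

    ar_ranges = config.ar_ranges or {
        r: mort.REGION_AR_RANGES[r] for r in regions if r in mort.REGION_AR_RANGES
    }
    ar_sets = mort.sample_ar_sets(
        ar_ranges, config.ar_n_samples, config.ar_n_select, stage_seed(ms, "ar")
    )
    populations = {
        sc: mort.project_population(demography, state_projections, sc)
        for sc in mort.MIGRATION_SCENARIOS
    }
    baseline_pop = {
        "pop_2000": demography.set_index("county_id")["pop_2000"].rename("population")
    }

    hwd_config = hw.HWDConfig(**config.hwd)
    all_events, all_baseline_events = [], []
    grid_rows, baseline_rows, climate_rows = [], [], []
    for method in config.calibration_methods:
        cal_baseline = cal.apply_calibration(baseline_series, ratios[method])
        thresholds = hw.compute_thresholds(cal_baseline, hwd_config)
        climate_rows.append(
            {
                "period": "baseline",
                "rcp": "none",
                "calibration": method,
                "tavg_mean": float(cal_baseline["tavg_c"].mean()),
                "tavg_sd": float(cal_baseline["tavg_c"].std(ddof=1)),
            }
        )
        for kind in config.hwd_kinds:
            base_events = hw.detect(cal_baseline, thresholds, hwd_config, kind)
            base_events["calibration"] = method
            all_baseline_events.append(base_events)
            for row in _cell_totals(
                base_events, demography, baseline_pop, ar_sets, config.baseline_years, regions
            ):
                baseline_rows.append({"calibration": method, "hwd": kind, **row})
        for rcp in RCP_SCENARIOS:
            cal_future = cal.apply_calibration(future_series[rcp], ratios[method])
            climate_rows.append(
                {
                    "period": "future",
                    "rcp": rcp,
                    "calibration": method,
                    "tavg_mean": float(cal_future["tavg_c"].mean()),
                    "tavg_sd": float(cal_future["tavg_c"].std(ddof=1)),
                }
            )
            for kind in config.hwd_kinds:
                events = hw.detect(cal_future, thresholds, hwd_config, kind)
                events["rcp"] = rcp
                events["calibration"] = method
                all_events.append(events)
                for row in _cell_totals(
                    events, demography, populations, ar_sets, config.future_years, regions
                ):
                    grid_rows.append({"rcp": rcp, "calibration": method, "hwd": kind, **row})

    events = pd.concat(all_events, ignore_index=True)
    baseline_events = pd.concat(all_baseline_events, ignore_index=True)
    grid = unc.build_grid(
        pd.DataFrame(grid_rows),
        {
            "rcp": list(RCP_SCENARIOS),
            "calibration": list(config.calibration_methods),
            "hwd": list(config.hwd_kinds),
            "pop_scenario": list(mort.MIGRATION_SCENARIOS),
            "ar_set": ar_sets["set_index"].tolist(),
            "year": list(config.future_years),
        },
    )
    baseline_grid = pd.DataFrame(baseline_rows)

    # frequency/duration summaries per definition, integrated over the
    # calibration methods (and emission scenarios for the future period)
    n_meth = len(config.calibration_methods)
    hw_rows = []
    for kind in config.hwd_kinds:
        b = baseline_events[baseline_events["definition"] == kind]
        hw_rows.append(
            {
                "definition": kind,
                "period": "baseline",
                "rcp": "all",
                "frequency": len(b)
                / (len(config.baseline_years) * config.n_counties * n_meth),
                "duration_mean": float(b["length_days"].mean()) if len(b) else float("nan"),
                "duration_sd": float(b["length_days"].std(ddof=1)) if len(b) > 1 else float("nan"),
            }
        )
        for rcp_label, sel in [
            ("all", events["definition"] == kind),
            *[
                (rcp, (events["definition"] == kind) & (events["rcp"] == rcp))
                for rcp in RCP_SCENARIOS
            ],
        ]:
            f = events[sel]
            denom = len(config.future_years) * config.n_counties * n_meth
            if rcp_label == "all":
                denom *= len(RCP_SCENARIOS)
            hw_rows.append(
                {
                    "definition": kind,
                    "period": "future",
                    "rcp": rcp_label,
                    "frequency": len(f) / denom,
                    "duration_mean": float(f["length_days"].mean()) if len(f) else float("nan"),
                    "duration_sd": float(f["length_days"].std(ddof=1))
                    if len(f) > 1
                    else float("nan"),
                }
            )
    hw_summary = pd.DataFrame(hw_rows)
    climate_summary = pd.DataFrame(climate_rows)

    dist_rows = []
    for label, values in [
        ("future_all", grid["total_excess_deaths"]),
        ("future_rcp45", grid.loc[grid["rcp"] == "rcp45", "total_excess_deaths"]),
        ("future_rcp85", grid.loc[grid["rcp"] == "rcp85", "total_excess_deaths"]),
        ("baseline", baseline_grid["total_excess_deaths"]),
    ]:
        s = unc.summarize_distribution(
            values, thresholds=tuple(config.cumulative_thresholds)
        )
        row = {"subset": label, **{k: s[k] for k in ("mean", "sd", "ci_lo", "ci_hi")}}
        for t, p in s["cumulative"].items():
            row[f"p_below_{int(t)}"] = p
        dist_rows.append(row)
    distribution = pd.DataFrame(dist_rows)

    sensitivity = unc.variance_decomposition(grid)

    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": ms,
        "stage_seeds": {k: stage_seed(ms, k) for k in STAGE_COUNTERS},
        "rows": {
            "counties": len(counties),
            "events": len(events),
            "baseline_events": len(baseline_events),
            "grid": len(grid),
        },
        "config": config.to_dict(),
    }

    result = PipelineResult(
        config=config,
        counties=counties,
        demography=demography,
        state_projections=state_projections,
        station_ratios=station_ratios,
        ratios=ratios,
        ar_sets=ar_sets,
        events=events,
        baseline_events=baseline_events,
        grid=grid,
        baseline_grid=baseline_grid,
        hw_summary=hw_summary,
        climate_summary=climate_summary,
        distribution=distribution,
        sensitivity=sensitivity,
        manifest=manifest,
    )
    if config.outdir:
        write_outputs(result, config.outdir)
    return result


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write every pipeline artifact as CSV plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.counties.to_csv(out / "counties.csv", index=False)
    result.demography.to_csv(out / "demography.csv", index=False)
    result.state_projections.to_csv(out / "state_projections.csv", index=False)
    result.ar_sets.to_csv(out / "ar_sets.csv", index=False)
    pd.concat(result.ratios.values(), ignore_index=True).to_csv(
        out / "calibration_ratios.csv", index=False
    )
    result.events.to_csv(out / "events.csv", index=False)
    result.baseline_events.to_csv(out / "baseline_events.csv", index=False)
    result.grid.to_csv(out / "grid.csv", index=False)
    result.baseline_grid.to_csv(out / "baseline_grid.csv", index=False)
    result.hw_summary.to_csv(out / "hw_summary.csv", index=False)
    result.climate_summary.to_csv(out / "climate_summary.csv", index=False)
    result.distribution.to_csv(out / "distribution.csv", index=False)
    result.sensitivity.to_csv(out / "sensitivity.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))


def validate_inputs(
    series: pd.DataFrame | None = None,
    demography: pd.DataFrame | None = None,
    season: tuple[tuple[int, int], tuple[int, int]] = ((5, 1), (9, 30)),
) -> list[dict]:
    """Schema and invariant checks with row-level diagnostics.

    Returns a list of issue dicts (empty when everything passes): daily
    ordering T_min ≤ T_avg ≤ T_max, dates inside the season window,
    state-share conservation, non-negative rates, known region labels.
    """
    issues: list[dict] = []
    if series is not None:
        for col in synth.SERIES_COLUMNS:
            if col not in series.columns:
                issues.append({"check": "schema", "message": f"series missing column {col}"})
        if not issues:
            bad = series[
                (series["tmin_c"] > series["tavg_c"]) | (series["tavg_c"] > series["tmax_c"])
            ]
            for _, row in bad.iterrows():
                issues.append(
                    {
                        "check": "ordering",
                        "county_id": row["county_id"],
                        "date": str(pd.Timestamp(row["date"]).date()),
                        "message": "requires T_min <= T_avg <= T_max",
                    }
                )
            dates = pd.to_datetime(series["date"])
            (m0, d0), (m1, d1) = season
            inside = (
                (dates.dt.month * 100 + dates.dt.day >= m0 * 100 + d0)
                & (dates.dt.month * 100 + dates.dt.day <= m1 * 100 + d1)
            )
            for _, row in series[~inside].iterrows():
                issues.append(
                    {
                        "check": "season_window",
                        "county_id": row["county_id"],
                        "date": str(pd.Timestamp(row["date"]).date()),
                        "message": "date outside the season window",
                    }
                )
    if demography is not None:
        sums = demography.groupby("state_id")["state_share"].sum()
        for state, s in sums.items():
            if abs(s - 1.0) > 1e-6:
                issues.append(
                    {
                        "check": "share_conservation",
                        "state_id": state,
                        "message": f"state shares sum to {s:.6f}, expected 1",
                    }
                )
        if (demography["mortality_rate"] < 0).any():
            issues.append({"check": "rate_sign", "message": "negative mortality rate"})
        unknown = set(demography["region"].unique()) - set(synth.REGIONS)
        if unknown:
            issues.append(
                {"check": "region_labels", "message": f"unknown regions: {sorted(unknown)}"}
            )
    return issues
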