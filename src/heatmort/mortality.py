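"""Excess mortality attributable to heat waves.

The attributable-risk model: for one heat wave of length L days in a county
whose expected number of non-accidental deaths on non-heat-wave days is N,

    ED_hw = N × (RR − 1) × L,

where RR is the relative risk of death on heat wave versus non-heat-wave
days and AR = RR − 1 the attributable risk. N is the county's baseline
daily non-accidental mortality rate times its (projected) population.

Regional AR values are drawn from published 95% confidence intervals for
the percent increase in non-accidental mortality on heat wave days in
multi-community US epidemiology: Northeast 1.79–11.98%, Midwest 3.36–7.93%,
South −0.11–3.84%. One hundred joint samples are generated by Latin
hypercube sampling from independent uniforms over the three ranges, and
nine of them are selected at random for the factor grid; all counties of a
region share the region's AR value within a set. Negative ARs (the South
lower bound) are retained and propagate to negative excess deaths.

Future county populations come from state 2050 projections by the constant
ratio method: county = state projection × the county's 2000 share of the
state population, held constant through the projection window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import qmc

REGION_AR_RANGES: dict[str, tuple[float, float]] = {
    "Northeast": (0.0179, 0.1198),
    "Midwest": (0.0336, 0.0793),
    "South": (-0.0011, 0.0384),
}

MIGRATION_SCENARIOS = ("high", "constant_medium", "low", "zero")

# Reporting labels for the four population projections, highest to lowest.
POPULATION_LABELS = {
    "high": "extreme_high",
    "constant_medium": "high",
    "low": "low",
    "zero": "extreme_low",
}


def project_population(
    demography: pd.DataFrame,
    state_projections: pd.DataFrame,
    scenario: str,
) -> pd.Series:
    """County populations under one migration scenario (constant ratio method).

    Returns a Series indexed by ``county_id``: the state 2050 projection
    times the county's 2000 share of the state population.
    """
    proj = state_projections[state_projections["scenario"] == scenario]
    missing = set(demography["state_id"].unique()) - set(proj["state_id"])
    if missing:
        raise ValueError(
            f"no population projection for scenario {scenario!r} in states: {sorted(missing)}"
        )
    merged = demography.merge(proj[["state_id", "pop_2050"]], on="state_id", how="left")
    pop = merged["state_share"] * merged["pop_2050"]
    pop.index = merged["county_id"]
    return pop.rename("population")


def lhs_uniform(
    ranges: dict[str, tuple[float, float]], n_samples: int, seed: int
) -> pd.DataFrame:
    """Latin hypercube sample of independent uniforms, one column per range.

    Each column's ``n_samples`` draws occupy the ``n_samples``
    equal-probability strata of its uniform exactly once.
    """
    names = list(ranges)
    for name in names:
        lo, hi = ranges[name]
        if not np.isfinite([lo, hi]).all() or lo > hi:
            raise ValueError(f"invalid range for {name}: {(lo, hi)}")
    sampler = qmc.LatinHypercube(d=len(names), seed=np.random.default_rng(seed))
    unit = sampler.random(n_samples)
    out = {}
    for j, name in enumerate(names):
        lo, hi = ranges[name]
        out[name] = lo + (hi - lo) * unit[:, j]
    return pd.DataFrame(out)


def sample_ar_sets(
    ranges: dict[str, tuple[float, float]] | None = None,
    n_samples: int = 100,
    n_select: int = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """LHS attributable-risk sets: ``n_samples`` joint draws, ``n_select`` kept.

    Returns ``n_select`` rows with ``set_index`` 1..n_select and one AR
    column per region (fractions, e.g. 0.0336 for 3.36%). Deterministic
    given the seed.
    """
    ranges = REGION_AR_RANGES if ranges is None else ranges
    if n_select > n_samples:
        raise ValueError("n_select must be <= n_samples")
    samples = lhs_uniform(ranges, n_samples, seed)
    rng = np.random.default_rng(seed + 1)
    chosen = np.sort(rng.choice(n_samples, size=n_select, replace=False))
    out = samples.iloc[chosen].reset_index(drop=True)
    out.insert(0, "set_index", np.arange(1, n_select + 1))
    return out


def excess_deaths(n_deaths_per_day: float, rr: float, length_days: float) -> float:
    """ED = N × (RR − 1) × L for one heat wave; negative RR−1 propagates."""
    n_deaths_per_day = np.asarray(n_deaths_per_day, dtype=float)
    length_days = np.asarray(length_days, dtype=float)
    if np.any(n_deaths_per_day < 0):
        raise ValueError("N must be >= 0")
    if np.any(length_days < 1):
        raise ValueError("heat wave length must be >= 1 day")
    result = n_deaths_per_day * (np.asarray(rr, dtype=float) - 1.0) * length_days
    return float(result) if result.ndim == 0 else result


def estimate_scenario(
    events: pd.DataFrame,
    demography: pd.DataFrame,
    ar_set: dict[str, float] | pd.Series,
    population: pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Excess deaths for one cell of the factor grid.

    ``events`` holds the heat waves of one definition/scenario slice,
    ``ar_set`` maps region → AR, ``population`` maps county_id → persons.
    Returns ``(per_county, total)`` where per_county has one row per county
    with events (``county_id, n_events, excess_deaths``).
    """
    if events.empty:
        return (
            pd.DataFrame(columns=["county_id", "n_events", "excess_deaths"]),
            0.0,
        )
    demo = demography.set_index("county_id")
    missing = set(events["county_id"].unique()) - set(demo.index)
    if missing:
        raise ValueError(f"events in counties without demography: {sorted(missing)}")
    missing_pop = set(events["county_id"].unique()) - set(population.index)
    if missing_pop:
        raise ValueError(f"events in counties without population: {sorted(missing_pop)}")

    ev = events.copy()
    ev["rate"] = demo.loc[ev["county_id"], "mortality_rate"].to_numpy()
    ev["region"] = demo.loc[ev["county_id"], "region"].to_numpy()
    ev["population"] = population.loc[ev["county_id"]].to_numpy()
    ev["ar"] = ev["region"].map(dict(ar_set)).astype(float)
    if ev["ar"].isna().any():
        bad = sorted(ev.loc[ev["ar"].isna(), "region"].unique())
        raise ValueError(f"no AR value for regions: {bad}")
    ev["excess_deaths"] = ev["rate"] * ev["population"] * ev["ar"] * ev["length_days"]
    per_county = (
        ev.groupby("county_id")
        .agg(n_events=("excess_deaths", "size"), excess_deaths=("excess_deaths", "sum"))
        .reset_index()
    )
    return per_county, float(ev["excess_deaths"].sum())
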