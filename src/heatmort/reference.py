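"""Literature reference values for eastern-US heat wave mortality projections.

These are published summary estimates for the ~1,700-county eastern United
States study area: the 2002–2004 observational baseline and the 2057–2059
projection window under the RCP4.5 and RCP8.5 emission scenarios. They serve
two purposes: (a) fixed comparison baselines for scenario-ratio arithmetic
(how many times more frequent/deadly future heat waves are than the
baseline), and (b) the provenance of the modified minimum thresholds used by
the temperature-percentile heat wave definitions.

The threshold chain: the T_avg heat wave floor is 26.7 °C (80 °F); the T_min
and T_max floors follow from the reported mean offsets of T_min and T_max
from T_avg over May–September (5.4 °C below and 6.0 °C above), giving
21.3 °C and 32.7 °C.
"""

from __future__ import annotations

from heatmort.units import f_to_c

# Mean summer (May–Sep) statistics per period: daily average temperature (°C),
# heat wave frequency (episodes/year/county), duration (days), and total
# excess deaths/year, integrated over definitions and population projections.
BASELINE_2002_2004 = {
    "tavg_c": 22.74,
    "frequency": 0.38,
    "duration_days": 3.44,
    "excess_deaths_per_year": 187.0,
}
FUTURE_2057_2059 = {
    "tavg_c": 24.75,
    "frequency": 1.88,
    "duration_days": 4.53,
    "excess_deaths_per_year": 2379.0,
}
FUTURE_RCP45 = {
    "tavg_c": 24.11,
    "frequency": 1.31,
    "duration_days": 4.06,
    "excess_deaths_per_year": 1403.0,
}
FUTURE_RCP85 = {
    "tavg_c": 25.39,
    "frequency": 2.44,
    "duration_days": 4.85,
    "excess_deaths_per_year": 3556.0,
}

# Modified minimum thresholds for the percentile-based definitions.
TAVG_FLOOR_F = 80.0
TAVG_FLOOR_C = 26.7  # = 80 °F to one decimal
TMIN_OFFSET_C = 5.4  # mean May–Sep T_avg − T_min in the reference data set
TMAX_OFFSET_C = 6.0  # mean May–Sep T_max − T_avg in the reference data set


def derive_tmin_floor(tavg_floor_c: float = TAVG_FLOOR_C) -> float:
    """T_min heat wave floor implied by the T_avg floor and the 5.4 °C offset."""
    return tavg_floor_c - TMIN_OFFSET_C


def derive_tmax_floor(tavg_floor_c: float = TAVG_FLOOR_C) -> float:
    """T_max heat wave floor implied by the T_avg floor and the 6.0 °C offset."""
    return tavg_floor_c + TMAX_OFFSET_C


def tavg_floor_from_fahrenheit() -> float:
    """The 80 °F T_avg floor expressed in °C."""
    return float(f_to_c(TAVG_FLOOR_F))


def mortality_ratio(scenario: dict, baseline: dict = BASELINE_2002_2004) -> float:
    """Future/baseline ratio of annual excess deaths."""
    return scenario["excess_deaths_per_year"] / baseline["excess_deaths_per_year"]


def frequency_ratio(scenario: dict, baseline: dict = BASELINE_2002_2004) -> float:
    """Future/baseline ratio of heat wave frequency (episodes/year/county)."""
    return scenario["frequency"] / baseline["frequency"]
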