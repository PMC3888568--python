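# heatmort

County-level projection of heat-wave-attributable excess mortality, with a
variance-based accounting of where the uncertainty comes from.

Climate-health assessments of this kind chain several stages, each with its
own assumptions: downscaled climate-model temperatures are calibrated
against station observations, heat waves are detected under one of several
operational definitions, an attributable-risk model converts heat wave
exposure into excess deaths, and the spread of estimates across all the
modelling choices is summarized and decomposed. `heatmort` implements that
chain as a tested, seeded pipeline for epidemiologists and climate-impact
modellers, with a synthetic-data module that emulates the statistical
structure of the real inputs (gridded model output with a multiplicative
bias relative to "truth" stations, seasonal cycles with autocorrelated
noise and injected multi-day hot spells, scenario-dependent warming) so
every stage runs and is testable without any external download.

## The model

Excess deaths attributable to one heat wave of length *L* days in a county
with expected daily non-heat-wave deaths *N* (baseline non-accidental
mortality rate × population):

> ED_hw = *N* × (*RR* − 1) × *L*

where *RR* is the relative risk of death on heat wave versus non-heat-wave
days and *RR* − 1 = AR the attributable risk. Regional AR values are drawn
by Latin hypercube sampling from published 95% CIs (Northeast 1.79–11.98%,
Midwest 3.36–7.93%, South −0.11–3.84%); future county populations follow
from state projections by the constant-ratio method.

Heat waves are detected under four definitions: daily low/high heat index
≥ 26.7 °C / 40.5 °C (NWS thresholds); ≥ 2 consecutive days with T_avg or
T_min above its baseline 95th percentile (with 26.7 °C and 21.3 °C minimum
thresholds); and the Meehl–Tebaldi T_max criteria (97.5th/81.5th
percentiles, 32.7 °C minimum). Thresholds come from pooled baseline-season
days per county; model temperatures are first calibrated by county-level
model/observation ratios interpolated from station counties (fixed 150-km
radius or 5 nearest neighbours).

Total annual excess deaths *y* are evaluated on the complete factor grid —
2 emission scenarios × 2 calibration methods × 4 definitions ×
4 population projections × 9 AR sets × 3 years = 1,728 cells — and the
uncertainty is apportioned by first-order sensitivity indices

> *S_i* = V(E[*y* | *x_i*]) / V(*y*),

with all higher-order terms pooled into an interaction residual.

## Worked example

The analysis is organized as numbered drivers over the library:

```sh
python analysis/01_simulate.py            --seed 0   # synthetic inputs
python analysis/02_calibrate.py           --seed 0   # bias calibration
python analysis/03_detect_heatwaves.py    --seed 0   # four definitions
python analysis/04_estimate_mortality.py  --seed 0   # factor grid of ED
python analysis/05_decompose_uncertainty.py --seed 0 # S_i decomposition
```

`03_detect_heatwaves.py` prints, for the default 40-county domain:

```
frequency (episodes/year/county) and duration (days), by definition:
definition base freq   rcp45   rcp85 base dur   rcp45   rcp85
HWD_HI          1.23    3.77    5.62     1.40    1.59    1.84
HWD_Tavg        1.60    4.78    6.65     2.77    3.45    3.89
HWD_Tmax        0.39    1.62    2.26     6.15    9.00   11.65
HWD_Tmin        1.58    4.73    6.68     2.75    3.39    3.79

integrated frequency: baseline 1.20, rcp85 5.30 -> ratio 4.4x
```

Heat waves become several times more frequent in the warmed future period,
the high-emission scenario produces markedly more and longer events than
the moderate one, and the definitions disagree strongly — the T_max
definition finds few long events while the percentile definitions find
many short ones. `05_decompose_uncertainty.py` then reports:

```
first-order sensitivity indices:
  hwd           S_i = 0.408
  ar_set        S_i = 0.215
  rcp           S_i = 0.201
  interactions  S_i = 0.134
  pop_scenario  S_i = 0.030
  year          S_i = 0.011
  calibration   S_i = 0.000
```

i.e. the heat wave definition, the attributable-risk estimate, and the
emission scenario dominate the uncertainty in projected mortality, while
the calibration method, the migration assumption behind the population
projection, and interannual variability are minor — the same ranking the
real-data assessments report.

A single config drives end-to-end runs too: `heatmort all --seed 0
--outdir out/` (subcommands `synth`, `calibrate`, `detect`, `mortality`,
`uncertainty`, `validate`).

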