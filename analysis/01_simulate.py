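"""Generate the synthetic study inputs: counties, demography, temperatures,
and station observations.

Writes the raw inputs the rest of the analysis consumes to
results/synthetic/ and reports what was generated: the county grid, the
regional split, the baseline/future temperature contrast, and the injected
hot-spell truth log.
"""

import argparse
from pathlib import Path

from heatmort import synthdata as sd
from heatmort.pipeline import RunConfig, stage_seed

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
args = parser.parse_args()

cfg = RunConfig(master_seed=args.seed)
counties, demography = sd.generate_counties(
    cfg.n_counties, cfg.n_states, stage_seed(args.seed, "counties")
)
projections = sd.generate_state_projections(demography)
params = sd.ClimateParams(seed=stage_seed(args.seed, "baseline"))
baseline, truth = sd.generate_temperatures(counties, params, cfg.baseline_years)
futures = {}
for rcp, offset in cfg.warming_offsets.items():
    futures[rcp], _ = sd.generate_temperatures(
        counties, params.replace(warming_offset=offset, seed=stage_seed(args.seed, rcp)),
        cfg.future_years,
    )
stations = sd.generate_stations(
    baseline, counties, params.replace(seed=stage_seed(args.seed, "stations"))
)

args.outdir.mkdir(parents=True, exist_ok=True)
counties.to_csv(args.outdir / "counties.csv", index=False)
demography.to_csv(args.outdir / "demography.csv", index=False)
projections.to_csv(args.outdir / "state_projections.csv", index=False)
baseline.to_csv(args.outdir / "baseline_series.csv", index=False)
truth.to_csv(args.outdir / "spell_truth_log.csv", index=False)
stations.to_csv(args.outdir / "stations.csv", index=False)
for rcp, series in futures.items():
    series.to_csv(args.outdir / f"future_series_{rcp}.csv", index=False)

print(f"counties: {len(counties)} in {cfg.n_states} states; "
      f"regions: {counties['region'].value_counts().to_dict()}")
print(f"latitude span: {counties['centroid_lat'].min():.2f}-"
      f"{counties['centroid_lat'].max():.2f} deg")
print(f"baseline {cfg.baseline_years}: mean T_avg {baseline['tavg_c'].mean():.2f} C "
      f"over {len(baseline)} county-days; {len(truth)} hot spells injected")
for rcp, series in futures.items():
    print(f"future {rcp}: mean T_avg {series['tavg_c'].mean():.2f} C "
          f"(+{series['tavg_c'].mean() - baseline['tavg_c'].mean():.2f} C vs baseline)")
print(f"stations: {stations['station_id'].nunique()} "
      f"({stations['station_id'].nunique() / len(counties):.0%} of counties), "
      f"model/obs bias {params.station_bias}")
print(f"wrote inputs to {args.outdir}")
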