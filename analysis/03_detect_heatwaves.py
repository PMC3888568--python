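"""Detect heat waves under the four definitions, baseline vs future.

Reports per-definition frequency (episodes/year/county) and duration for
the baseline period and the two emission scenarios — the synthetic analogue
of the projected-heat-wave tables — and writes the event lists.
"""

import argparse
from pathlib import Path

from heatmort.pipeline import RunConfig, run_pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

result = run_pipeline(RunConfig(master_seed=args.seed))
args.outdir.mkdir(parents=True, exist_ok=True)
result.events.to_csv(args.outdir / "events.csv", index=False)
result.baseline_events.to_csv(args.outdir / "baseline_events.csv", index=False)
result.hw_summary.to_csv(args.outdir / "hw_summary.csv", index=False)

s = result.hw_summary
print("frequency (episodes/year/county) and duration (days), by definition:")
print(f"{'definition':10s} {'base freq':>9s} {'rcp45':>7s} {'rcp85':>7s} "
      f"{'base dur':>8s} {'rcp45':>7s} {'rcp85':>7s}")
for kind in s["definition"].unique():
    row = {}
    for period, rcp in (("baseline", "all"), ("future", "rcp45"), ("future", "rcp85")):
        sel = s[(s.definition == kind) & (s.period == period) & (s.rcp == rcp)].iloc[0]
        row[rcp if period == "future" else "base"] = sel
    print(f"{kind:10s} {row['base']['frequency']:9.2f} {row['rcp45']['frequency']:7.2f} "
          f"{row['rcp85']['frequency']:7.2f} {row['base']['duration_mean']:8.2f} "
          f"{row['rcp45']['duration_mean']:7.2f} {row['rcp85']['duration_mean']:7.2f}")

base_f = s[(s.period == "baseline")]["frequency"].mean()
r85_f = s[(s.period == "future") & (s.rcp == "rcp85")]["frequency"].mean()
print(f"\nintegrated frequency: baseline {base_f:.2f}, rcp85 {r85_f:.2f} "
      f"-> ratio {r85_f / base_f:.1f}x")
print("note the ordering: the T_max definition yields the fewest but longest "
      "events; the heat-index definition produces many short (often single-day) "
      "episodes concentrated in the hottest far-south counties; the T_avg and "
      "T_min percentile definitions behave similarly and dominate event counts.")
print(f"wrote events to {args.outdir}")
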