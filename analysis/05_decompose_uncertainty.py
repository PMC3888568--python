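"""Summarize the estimate distribution and apportion its variance.

Pools the factor grid into probability distributions of annual excess
deaths (overall and per emission scenario, with cumulative probabilities at
round thresholds) and decomposes the total variance into first-order
sensitivity indices S_i = V(E[y|x_i])/V(y) per factor, reporting which
factors dominate the uncertainty.
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
result.distribution.to_csv(args.outdir / "distribution.csv", index=False)
result.sensitivity.to_csv(args.outdir / "sensitivity.csv", index=False)

print("distribution of annual excess deaths:")
for _, row in result.distribution.iterrows():
    print(f"  {row['subset']:13s} mean {row['mean']:7.1f}  sd {row['sd']:6.1f}  "
          f"95% CI ({row['ci_lo']:.0f}, {row['ci_hi']:.0f})")

print("\nfirst-order sensitivity indices:")
sens = result.sensitivity.sort_values("s_i", ascending=False)
for _, row in sens.iterrows():
    print(f"  {row['factor']:13s} S_i = {row['s_i']:.3f}")
major = {"ar_set", "rcp", "hwd"}
top3 = set(sens[sens["factor"] != "interactions"]["factor"].head(3))
print(f"\ndominant factors: {sorted(top3)} "
      f"({'as expected' if top3 == major else 'UNEXPECTED ordering'}: attributable "
      "risk, emission scenario, and heat wave definition drive the uncertainty; "
      "calibration method, population projection, and year are minor)")
print(f"wrote distribution and sensitivity tables to {args.outdir}")
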