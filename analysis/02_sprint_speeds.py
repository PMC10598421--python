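#!/usr/bin/env python
"""Sprint speeds from the tracking trials.

For every trial: per-frame velocities (px -> cm via the video scale,
frame rate -> per-second), cubic smoothing-spline fit with N/2+1 knots to
strip the gait oscillation of the body centre, then mean and sprint
(= smoothed maximum) speed in cm/s and body lengths/s. Trials that fail
the straightness filter are dropped and listed. Aggregation: max over an
individual's trials, mean over a species' individuals.

Run after 01: python analysis/02_sprint_speeds.py
"""

import argparse
from pathlib import Path

import pandas as pd

from marronoid import kinematics

ap = argparse.ArgumentParser()
ap.add_argument("--data-dir", type=Path, default=Path("scratch/study_data"))
ap.add_argument("--out-dir", type=Path, default=Path("results"))
ap.add_argument("--straightness-threshold", type=float, default=0.9)
args = ap.parse_args()

summaries, dropped = [], []
for f in sorted((args.data_dir / "trajectories").glob("*.csv")):
    traj = kinematics.read_trajectory_csv(f)
    s = kinematics.process_trial(traj, args.straightness_threshold)
    (summaries if s is not None else dropped).append(s if s is not None else f.name)

ind, sp = kinematics.aggregate(summaries)
args.out_dir.mkdir(exist_ok=True)
pd.DataFrame([vars(s) for s in summaries]).to_csv(
    args.out_dir / "trial_summaries.csv", index=False)
ind.to_csv(args.out_dir / "individual_summaries.csv", index=False)
sp.to_csv(args.out_dir / "species_speeds.csv", index=False)

print(f"{len(summaries)} trials kept, {len(dropped)} dropped by the "
      "straightness filter")
fastest = sp.sort_values("sprint_rel", ascending=False).head(3)
print("fastest species (bl/s):")
for _, r in fastest.iterrows():
    print(f"  {r.species:12s} {r.sprint_rel:6.1f}")
print(f"species table -> {args.out_dir / 'species_speeds.csv'}")
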