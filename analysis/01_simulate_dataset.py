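#!/usr/bin/env python
"""Generate the synthetic milk-storage study and summarize its design.

Writes the 130-sample dataset (13 twice-daily time points x 10 milk types
over 6 days of refrigerated storage) in the wide-CSV dialect, plus the
acidity trajectory and the class/split composition tables.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lacto2d.dataio import write_spectra
from lacto2d.synthetic import SynthConfig, acidity_trajectory, generate_dataset

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

cfg = SynthConfig(seed=args.seed)
ds = generate_dataset(cfg)
write_spectra(ds, args.outdir / "milk_synth.csv")

composition = (
    ds.metadata.groupby(["split", "label"]).size().unstack(fill_value=0)
)
composition.to_csv(args.outdir / "design_composition.csv")

days = np.round(cfg.time_points_days, 2)
traj = pd.DataFrame(
    {"storage_day": days, "mean_acidity_degT": acidity_trajectory(days, cfg)}
)
traj.to_csv(args.outdir / "acidity_trajectory.csv", index=False)

print(f"wrote {len(ds)} spectra on a {ds.wavelengths.size}-point grid")
print("\ncalibration/validation composition by freshness class:")
print(composition)
print("\nacidity trajectory (degT):")
print(traj.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(
    "\nFinding: acidity rises slowly through day 4 and steeply afterwards, "
    "and sub-fresh milk (B) is the largest class, as in the storage study "
    "the generator emulates."
)
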