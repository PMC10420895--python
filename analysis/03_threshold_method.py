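#!/usr/bin/env python
"""The threshold-value freshness rule and peak-vs-time regressions.

Fits mean + 3*SD thresholds on the three monitored synchronous-map peaks
from fresh calibration milk, scores the binary fresh/non-fresh decision on
both splits, and regresses each peak intensity on storage time.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from lacto2d import corr2d, evaluation, threshold
from lacto2d.synthetic import SynthConfig, generate_dataset

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

ds = generate_dataset(SynthConfig(seed=args.seed))
cal, val = ds.calibration, ds.validation
ref = corr2d.reference_spectrum(cal.where_label("A"))
model = threshold.fit_thresholds(cal.where_label("A"), ref, k_sd=3.0)

report = {"thresholds": dict(zip(["auto_1450", "auto_1940", "cross_1450_1940"],
                                 model.thresholds.tolist()))}
for name, part in (("calibration", cal), ("validation", val)):
    pred = [threshold.classify_threshold(s, ref, model) for s in part]
    truth = [threshold.FRESH if l == "A" else threshold.NON_FRESH
             for l in part.labels]
    rep = evaluation.evaluate(truth, pred,
                              classes=(threshold.FRESH, threshold.NON_FRESH))
    report[name] = rep.to_dict()

regressions = {}
for label, loc in [("auto_1940", (1940, 1940)), ("cross_1450_1940", (1450, 1940))]:
    pts = [
        (s.storage_time, corr2d.peak_value(corr2d.synchronous_single(s, ref), *loc))
        for s in ds
    ]
    slope, intercept, r2 = threshold.peak_time_regression(pts)
    regressions[label] = {"slope_per_hour": slope, "intercept": intercept, "r2": r2}
report["peak_time_regressions"] = regressions

(args.outdir / "threshold_report.json").write_text(json.dumps(report, indent=1))

print(json.dumps(report, indent=1))
cal_fresh = report["calibration"]["accuracy_per_class"]["fresh"]
print(
    f"\nFinding: fresh-class sensitivity is {cal_fresh:.1f}% on calibration "
    f"data; peak intensities track storage time with R^2 "
    f"{regressions['auto_1940']['r2']:.2f} (1940 nm), but the rule is binary "
    f"and cannot separate sub-fresh from spoiled milk."
)
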