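#!/usr/bin/env python
"""Discriminant analysis across pretreatments and feature spaces.

Runs the full pipeline with LDA for every pretreatment (raw, SNV, MSC,
first derivative) on both feature spaces (raw Vis/NIR spectra and the
2D-correlation autocorrelation spectra) and tabulates per-class and total
validation accuracy — the model-comparison design of the study.
"""

import argparse
from pathlib import Path

import pandas as pd

from lacto2d.pipeline import RunConfig, run_pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

rows = []
for space in ("visnir", "corr2d_auto"):
    for method in ("raw", "snv", "msc", "deriv1"):
        rep = run_pipeline(
            RunConfig(seed=args.seed, model="lda", preprocess_method=method,
                      feature_space=space)
        )
        row = {"features": space, "preprocess": method,
               "accuracy_total": round(rep.accuracy_total, 1)}
        row.update({f"accuracy_{k}": round(v, 1)
                    for k, v in rep.accuracy_per_class.items()})
        rows.append(row)

table = pd.DataFrame(rows)
table.to_csv(args.outdir / "lda_comparison.csv", index=False)
print(table.to_string(index=False))
best = table.loc[table["accuracy_total"].idxmax()]
worst_is_deriv = all(
    table[table["features"] == sp].set_index("preprocess")["accuracy_total"].idxmin()
    == "deriv1"
    for sp in table["features"].unique()
)
print(
    f"\nFinding: the best LDA model is {best['features']} + {best['preprocess']} "
    f"at {best['accuracy_total']:.1f}% validation accuracy."
    + (" The first derivative is the weakest pretreatment in both feature "
       "spaces, consistent with derivative noise amplification."
       if worst_is_deriv else "")
)
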