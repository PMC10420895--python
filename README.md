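# lacto2d

Milk freshness discrimination from synchronous two-dimensional Vis/NIR
correlation spectra, with chemometric classifiers.

## The problem

Refrigerated raw milk spoils over days: lactose ferments to lactic acid,
titratable acidity climbs, and eventually the milk coagulates. Titratable
acidity (°T) is the standard freshness criterion — **fresh A** (13–15 °T),
**sub-fresh B** (15–18 °T), **spoiled C** (> 18 °T) — but titration is slow
and destructive. Visible/near-infrared (Vis/NIR) diffuse-reflectance
spectroscopy (400–2500 nm, 2 nm steps) is fast and non-destructive, yet milk
scatters strongly and its broad overlapping bands hide the small
storage-related changes.

This package implements a pipeline that sharpens those changes with
generalized two-dimensional correlation spectroscopy and classifies
freshness from the result. For a sample spectrum *s* and the mean fresh-milk
reference *r*, the *dynamic spectrum* is ỹ = s − r and the per-sample
synchronous correlation map is the outer product

    Φ(ν₁, ν₂) = ỹ(ν₁) · ỹ(ν₂)

Its diagonal Φ(ν, ν) = ỹ(ν)² is the **autocorrelation spectrum** — zero for
fresh milk, growing quadratically as water (1450, 1940 nm), lactose/lactic
acid (1194 nm) and fat (1790 nm) bands change with spoilage. For a group of
m spectra the classical ensemble estimator Φ = Ỹᵀ Ỹ / (m−1) (and its
asynchronous Hilbert–Noda counterpart) is also provided.

Three classifiers operate on these features:

* **Threshold rule** — fresh iff the peaks at (1450, 1450), (1940, 1940) and
  (1450, 1940) nm all stay below mean + 3·SD of the fresh calibration peaks;
* **Linear discriminant analysis** — maximizes the scatter trace ratio
  tr(Vᵀ S_B V) / tr(Vᵀ S_W V) with S_B, S_W the between/within-class scatter
  matrices (solved by the globally optimal trace-ratio iteration), then
  assigns the nearest projected class mean;
* **Kernel SVM** — linear / polynomial / rbf / sigmoid kernels, one-vs-one
  multiclass, with the cost–kernel-scale pair [C, G] tuned in log₂ space by
  an exhaustive coarse grid followed by particle-swarm optimization, scored
  by stratified k-fold cross-validated accuracy.

Because the original 130-sample dataset is not public, a first-class
synthetic generator (`lacto2d.synthetic`) reproduces the study design:
13 twice-daily time points × 10 milk types over 6 days, Gaussian band
structure with spoilage-coupled growth, multiplicative/additive scatter
artifacts, an acidity trajectory from 14.1 °T (day 0) to 21.0 °T (day 6),
and a stratified 97/33 calibration/validation split.

## Worked example

```python
from lacto2d import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=7, model="svm", svm_kernel="rbf",
                                feature_space="corr2d_auto", optimize="grid"))
print("validation confusion (rows true A,B,C):", report.confusion.counts.tolist())
print("total accuracy: %.1f%%" % report.accuracy_total)
print("tuned [C, G]:", report.metadata["grid_best"])
```

prints

```
validation confusion (rows true A,B,C): [[7, 0, 0], [0, 18, 0], [0, 0, 8]]
total accuracy: 100.0%
tuned [C, G]: {'C': 512.0, 'G': 2.0, 'cv_accuracy': 0.9689...}
```

i.e. the pipeline simulated a 130-sample study, split it 97/33, built
autocorrelation features against the fresh calibration reference, tuned an
rbf SVM to [C, G] = [512, 2] at 96.9 % cross-validated calibration
accuracy, and classified all 33 validation samples (7 fresh, 18 sub-fresh,
8 spoiled) correctly.

The numbered scripts under `analysis/` walk the full study: `01` simulates
and summarizes the design, `02` tabulates the synchronous-map peaks day by
day, `03` runs the threshold rule and peak-vs-time regressions, `04`
compares LDA across pretreatments (raw/SNV/MSC/1st derivative) and feature
spaces, `05` compares the four SVM kernels with grid + swarm tuning and
ends with the three-way model shoot-out. Each writes its tables under
`results/`.

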