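# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `lacto2d`.

## Freshness classes and acidity

Titratable acidity in Thörner degrees (mL of 0.1 M NaOH per 100 mL milk)
defines the classes: A for 13 ≤ a < 15, B for 15 ≤ a ≤ 18, C for a > 18.
The published intervals overlap at 15 °T and leave 18 °T ambiguous; we
resolve them half-open as above — the spoiled class is stated strictly as
"> 18", which forces 18 into B, and 15 is assigned to B for symmetry of
one-sided lower bounds. Acidity below 13 °T is outside the scheme and
raises an error rather than silently extrapolating.

## Two-dimensional correlation spectra

The perturbation variable is storage. The reference is the pointwise mean
of the fresh (label-A) calibration spectra; a sample's dynamic spectrum is
ỹ = s − r. Two synchronous estimators are implemented:

* **per-sample**: Φ = ỹ ỹᵀ, an exact rank-one outer product. This is the
  default feature source for classification because each sample needs its
  own feature vector; the classifier consumes the diagonal (the
  autocorrelation spectrum, 1051 values of squared dynamic absorbance).
  The full upper triangle is available but quadratically larger and not
  used by default.
* **ensemble**: Φ = Ỹᵀ Ỹ/(m−1) over a group of m ≥ 2 spectra, the
  conventional normalization; used for per-storage-day maps. On m identical
  copies of one sample it equals m/(m−1) times the per-sample map — the two
  agree up to that factor, which is tested.

The asynchronous map Ψ = Ỹᵀ N Ỹ/(m−1), with N the Hilbert–Noda matrix
(N_jk = 0 if j = k, else 1/(π(k−j))), is provided for completeness
(antisymmetric, zero diagonal) but plays no role in classification.

Peak lookup snaps a requested wavelength to the nearest grid point, ties
toward the lower wavelength — deterministic on the regular 2 nm grid.

Because the reference lies *inside* the fresh window (the mean fresh
spectrum corresponds to roughly half a day of storage), the day-0 map is
small but not zero, and autocorrelation intensity is strictly monotone in
storage day only from day 1 onward; the tests assert exactly that, plus a
day-6/day-0 enhancement of more than two orders of magnitude.

## Pretreatments

SNV standardizes each spectrum across wavelengths (sample SD, ddof = 1);
MSC regresses each spectrum on a reference and removes the fitted
slope/offset, with the reference frozen to the calibration mean so
validation samples never influence it; the first derivative is
Savitzky–Golay (window 11 points, polynomial order 2, absorbance per nm,
same-length output via polynomial edge fits). The derivative settings are a
choice — standard chemometrics practice — since no algorithm or window is
canonical; any reasonable derivative amplifies noise at this
signal-to-noise ratio, which the comparison scripts reproduce.
Pretreatments are applied to the 1-D spectra before the correlation
transform.

## Threshold rule

Fresh-milk synchronous peaks at (1450, 1450), (1940, 1940) and
(1450, 1940) nm scatter tightly around zero, so each threshold is the
fresh-calibration mean plus k·SD (k = 3 by default, configurable). How the
original dashed-line thresholds were set from fresh peaks is not stated;
mean + 3·SD is the natural reading of the emphasis on tiny fresh-peak
standard deviations. The rule is deliberately binary (fresh vs non-fresh):
it is demonstrably poor at separating sub-fresh from spoiled milk and the
package does not pretend otherwise. Raising k can only widen the fresh
region (tested monotonicity).

## Linear discriminant analysis

With class counts N_i, class means x̄_i and grand mean x̄,

    S_B = (1/N) Σ_i N_i (x̄_i − x̄)(x̄_i − x̄)ᵀ
    S_W = (1/N) Σ_i Σ_j (x_ij − x̄_i)(x_ij − x̄_i)ᵀ

and the projection maximizes tr(Vᵀ S_B V)/tr(Vᵀ S_W V). Note the classic
closed form — the top-m generalized eigenvectors of
(S_W + ridge·I)⁻¹ S_B — solves the *ratio-trace* problem and can be
strictly suboptimal for the trace ratio when m > 1 (we observed random
projections beating it by ~2 % on toy data). We therefore use it only to
initialize the standard trace-ratio iteration (re-solve the symmetric
eigenproblem of S_B − λ·S_W at the current ratio λ until convergence),
which is globally optimal; the property "fitted ratio ≥ any random
projection" then holds by theory and is tested against 1000 random
projections.

Numerics: with 1051 wavelengths and 97 samples S_W is singular, so a ridge
(default 10⁻⁶·trace(S_W)/n) is added; the solve is reduced to the span of
the total scatter first (outside it the numerator vanishes while the ridge
still penalizes), which makes the high-dimensional fit cheap and
well-conditioned. m defaults to C − 1 = 2. Eigenvector columns are unit
norm with the largest-magnitude entry positive, so artifacts reproduce
bit-for-bit. Classification is nearest projected class mean, ties broken
A < B < C (the discriminant function is linear; nearest-centroid in the
discriminant subspace is the canonical deterministic reading).

A caveat the comparison scripts expose: squared-dynamic features are
strongly heteroscedastic (the spoiled class spreads far more than the
fresh class), which violates the pooled-covariance geometry behind
nearest-centroid LDA. LDA on autocorrelation features therefore
generalizes worse than LDA on raw spectra on synthetic data, while the
kernel SVM is unaffected.

## Kernel SVM and hyperparameter search

Kernels: linear x·y; polynomial (G·x·y + coef0)^d; rbf exp(−G‖x−y‖²);
sigmoid tanh(G·x·y + coef0). The soft-margin quadratic program is
delegated to scikit-learn's SVC (one-vs-one multiclass voting is its
native scheme); the package owns the kernel contracts, the scaling
bookkeeping, the tuning loops and the support-vector reporting.

Feature scaling defaults to per-feature mean centering, learned on the
calibration data and frozen into the model. Full unit-variance
standardization is available but not the default: re-scaling every
wavelength to unit variance re-inflates the static-wavelength noise that
the squared 2D features suppress quadratically, defeating the transform's
magnification of spoilage-linked bands. Centering is exactly neutral for
the rbf kernel and keeps the other kernels well scaled.

Search: log₂C ∈ [−5, 15], log₂G ∈ [−15, 3] (community-standard box),
coarse grid step 2, ties toward smaller C then smaller G; then an
inertia-weight global-best particle swarm (swarm 20, 50 iterations,
inertia 0.9 → 0.4, c₁ = c₂ = 2, positions clamped to the box, velocities
to the box size), deterministic under a fixed seed, fitness = stratified
5-fold cross-validated accuracy. The global-best trace is non-decreasing
by construction. Cross-validation surfaces plateau near the optimum, so
the swarm routinely lands off-grid at a score equal to the dense-grid
optimum; the tests accept either location-within-one-step or
score-at-least-as-good.

## Synthetic data generator

The generator emulates: 10 milk "types" scanned every 12 h for 6 days
(130 samples); Gaussian absorption bands at the assigned wavelengths
(water 1450/1940, fat 1210/1790/2300, protein 2050/2180, lactose/lactic
acid 1194/1650/2094, carotenoids 460, plus a long-wavelength band at
2498 nm) on a gently sloping baseline; per-sample scatter a·x + b with
a ~ N(1, 0.02²), b ~ N(0, 0.01²); white noise (SD 0.002 absorbance); and
per-sample acidity = trajectory(t) + N(0, 0.12²) °T, from which the label
follows.

**Acidity trajectory.** A smooth monotone linear-plus-exponential curve
a(t) = 14.1 + αt + β(e^{γt} − 1) anchored exactly at (0 d, 14.1 °T) and
(6 d, 21.0 °T), with α = 0.68 °T/day and γ = 1/day. Its mean slope over
days 0–4 (≈ 0.77 °T/day) is well below the day-5–6 slope (≈ 2.5 °T/day) —
gradual, then rapid. A logistic with inflection at day 5 was considered
and rejected: any such logistic crosses 15 °T only near day 3.5, making
the fresh class ~60 % of samples and sub-fresh the smallest class, the
opposite of the study composition (sub-fresh largest, roughly 28/44/28 %);
the chosen curve crosses 15 °T near day 1.3 and 18 °T near day 4.7,
giving a ~31/69/30 sample mix.

**Band growth.** Spoilage-linked band amplitudes grow with the *acidity
excess* Δa(t) = a(t) − 14.1 (the spoilage coordinate), not linearly with
time: amplitude = base·(1 + rate·Δa), rate in °T⁻¹ (0.30 at 1450 nm, 0.35
at 1940 nm, 0.22 at 1194 nm, 0.17 at 1790 nm, 0.26 at 2498 nm; static or
near-static elsewhere). Two reasons. First, realism: spectral change
during the fresh window is negligible and accelerates late, matching
spoilage kinetics. Second, geometry: with growth linear in time, the
squared dynamic spectrum depends on time only through (t − t̄_fresh)², so
day-0 samples fold exactly onto the fresh/sub-fresh boundary region — an
artifact the real data cannot have had. Growth in the convex spoilage
coordinate keeps the fold image deep inside the fresh class.

Band widths (σ 25–50 nm) and base amplitudes (water dominant) are free
parameters with documented defaults; only the qualitative structure —
which peaks grow — is claimed.

**What the generator does not model**: wavelength shifts from hydrogen-
bonding or temperature changes, detector nonlinearity/saturation,
wavelength-dependent scatter, per-type static composition offsets, and
non-Gaussian lineshapes. Consequently, passing tests demonstrate that the
pipeline recovers the structure the generator encodes, not that it attains
any particular accuracy on real milk.

**An honest structural finding.** After reference subtraction and
centering, the autocorrelation features differ from the raw-spectrum
features only by per-feature squaring, and any per-sample affine scatter
nuisance enters both identically; for a separately tuned rbf SVM the two
routes are therefore information-equivalent on this generator, and
measured accuracies tie to within a fraction of a percent (~98 % 5-fold
CV at the default conditions), with the raw route occasionally ahead.
Strengthening the scatter artifacts *hurts* the squared features more,
because squaring bends the low-rank affine nuisance into curved manifolds.
The directional claim that 2D features outperform raw spectra by a wide
margin is thus a property of the real dataset (where the published raw-
spectrum models used 18–24 support vectors against 6–10 for the 2D
models, suggesting nuisance structure beyond an affine model) and is not
reproducible from this generator; the acceptance suite implements the
strict comparison anyway and documents the near-tie.

## Pipeline and reproducibility

`run_pipeline` chains simulate → split → pretreat → reference → features →
train → evaluate. One global seed fans out to per-stage seeds through
`numpy.random.SeedSequence`; reruns are bit-identical, and artifacts
(dataset CSV, model JSON, report JSON) carry sha256 hashes in the report
metadata. No fitting step sees validation data: the MSC reference, the
fresh reference spectrum, feature scaling and all classifier parameters
are learned from the calibration split alone (tested by perturbing
validation spectra and asserting unchanged models).

Problem sizes in the test and acceptance runs — 130-sample studies, 5
recovery seeds, coarse grids of 110 points, dense oracle grids of ~200
points, swarms of 10–20 particles — were chosen so the full suite
completes in a few minutes while leaving every statistical conclusion
stable under seed changes.
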