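# Methods

This note records the models the package implements, the parameters that
matter, what the synthetic generator does and does not emulate, the
numerical choices, and the known limitations.

## Data model

A dataset is an N×p matrix **X** of Raman intensities (arbitrary counts)
on a shared, strictly increasing wavenumber axis (cm⁻¹), with binary
labels W (1 = first sample, 0 = second). On disk the format is wide
delimited text: header = wavenumbers, one reserved `label` column,
one row per spectrum. Analyses run on closed-interval spectral windows;
the two standard windows are LW = [125.25, 549.27] and
HW = [2303.16, 3399.83] cm⁻¹. Region bounds are inclusive on both ends —
on the default 1700-point grid (125.25–3399.83 cm⁻¹, spacing ≈ 1.9274 cm⁻¹,
reconstructed from the LW window's endpoints and its 221-point count)
this convention makes LW select exactly 221 columns and HW exactly 570.

## Synthetic generator

The study's spectra are not public, so the generator emulates their
structure: a smooth fluorescence baseline (polynomial in the normalized
axis coordinate, coefficients in counts), Lorentzian bands (Gaussian
selectable) at the characteristic positions — Ag–N ≈ 234 cm⁻¹, Si ≈ 514
cm⁻¹, DNA base/backbone bands at 730/785/1090 cm⁻¹, CH/CH₃ ≈ 2934 cm⁻¹ —
additive noise, and a small fraction (default 0.5%) of gross single-point
spikes (30 × noise SD) that violate the outlier decision surface by
construction. A class effect multiplies one band's amplitude in class 1
(`class_delta`); `two_class_config("hw"|"lw"|"both"|None, delta=…)`
builds the standard scenarios. The study-scale default is 2000 spectra
per class.

Defaults that are calibration choices, not claims about the instrument:

* **Intensity scale** O(1–10) counts (baseline ≈ 2–4, amplitudes 0.6–3,
  noise SD 0.08). Counts are in arbitrary units, so the scale is free.
* **Noise distribution**: uniform with SD = `noise_sd` (bounded at
  √3·SD), with plain and truncated Gaussian selectable. The bound is
  deliberate: with ~1700 points per spectrum, unbounded Gaussian noise
  puts several points of nearly every spectrum outside the pointwise
  ±3 SD decision surface, so the outlier filter would discard essentially
  all spectra rather than the few gross outliers it is meant to catch.
  Real SERS maps evidently do not behave like i.i.d. Gaussian noise in
  this respect; bounded noise reproduces the intended regime ("most
  spectra share similar features, a few are grossly different").

What the generator does **not** emulate: spatial drop geometry
(coffee-ring structure, per-position enhancement), correlated/structured
noise, cosmic-ray artifacts, wavenumber miscalibration, class effects on
band position or width. Passing tests therefore show the pipeline behaves
correctly on data with this idealized structure; they cannot certify
performance on real instrument output.

## Preprocessing

Stage order is fixed and recorded in run metadata: background → outlier
removal → smoothing.

* **Background**: order-3 polynomial per spectrum, fitted by iterated
  clipped least squares (after each fit, points above the current
  baseline are replaced by it, so peaks stop dragging the fit). A plain
  single fit is selectable. The stage is optional — data that arrive
  already background-corrected skip it.
* **Outlier filter**: per label group, pointwise mean ± k·SD (k = 3,
  population SD); a spectrum with ≥ 1 point strictly outside is
  discarded; boundary points count as inside. A pooled-group mode exists.
* **Savitzky–Golay**: window 91, polynomial order 3, convolutional
  interior with polynomial fits on truncated edge windows. The
  conventional 90-point window is even, which a symmetric SG filter
  cannot realize; 91 is the nearest valid width. The polynomial order is
  unstated upstream; 3 matches the background order and is configurable.

## Classifiers

All five are scored by ten-fold label-stratified cross-validated ROC–AUC
(Mann–Whitney convention, ties ½), reported as mean ± SEM over folds.
Stratification guarantees both labels in every fold so the AUC is
defined.

* **LRA**: logistic regression on the window's global mean intensity,
  L² penalty with shrinkage weight 1 (intercept unpenalized; features
  standardized internally so the penalty acts on a comparable scale).
* **L2D**: class-mean spectra h¹, h² from the training fold; squared ℓ²
  distances (no square root); predict 1 iff τ·d¹ ≤ (1−τ)·d². τ is chosen
  on a 51-point grid over [0,1] by inner ten-fold CV of the margin score
  (1−τ)d² − τd¹, ties broken toward τ = 0.5 (the nearest-centroid rule).
* **LRP**: average pooling over non-overlapping sub-domains —
  LW: cuts at 125.25 / 234 / 360 / 480 / 549.27; HW: 2303.16 / 2700 /
  3200 / 3399.83 — then the same penalized logistic regression.
  Permutation importance of a fitted model on held-out data: AUC minus
  the mean AUC over 30 independent shuffles of each feature column.
* **PCA**: columns centered with training means; components from the SVD
  of the centered matrix (equivalently the eigendecomposition of the
  covariance), eigenvector signs fixed by making each component's
  largest-magnitude loading positive; m = smallest number of components
  reaching 99.9% cumulative variance, capped at 5. The decision
  threshold λ ∈ [0,1] is selected on a grid by the same CV objective;
  since AUC is threshold-invariant every λ ties and the tie-break keeps
  0.5 — λ only matters for hard classifications, which the AUC reporting
  does not use.

## The 1-D CNN

Architecture (fixed): three blocks of [valid convolution, 64 filters,
kernel width 3, softplus φ(x)=log(1+eˣ) → max-pool 2 → dropout 0.25],
flatten, dense 16 (softplus), dense 1 (sigmoid) → score o ∈ (0,1).
Valid padding is used: the shrinking stack with an explicit flatten is
the natural reading of a purely convolutional design, and padding is
configurable in principle via the layer arithmetic. For a 221-point
input the per-stage lengths are 221→219→109→107→53→51→25 and the
trainable parameter count is 50 593.

Training: ADAM (lr 0.001, β₁ 0.9, β₂ 0.999), batch 64, binary
cross-entropy in the numerically stable logit form; dropout active in
training only; default schedule 50 epochs with early stopping on a 10%
validation split (patience 10), both configurable. Spectra enter raw —
no rescaling or transformation.

Implementation notes (the network and its backward pass are written
directly on numpy arrays):

* im2col convolutions as single large GEMMs, float32 by default
  (float64 available; the gradient tests use it).
* **Initialization**: Glorot-uniform weights, with the dense softplus
  biases at +0.5 and the output layer at exactly zero, so the initial
  prediction is 0.5. This matters: raw spectra are all-positive and
  strongly correlated, and a confidently-wrong initial logit pushes the
  hidden layer's common mode into negative softplus saturation, where
  gradients vanish and the network freezes at constant output
  (loss = ln 2). Zero-initializing the output removes that pressure.
* **Restarts**: if a fitted network's hidden layer is constant across
  inputs (the dead state), training restarts from a fresh seeded
  initialization, up to 5 times — the same non-convex-objective restart
  strategy k-means uses. With the initialization above this is a rarely
  triggered backstop.
* Determinism: all weight init, shuffling and dropout streams derive
  from one model seed; identical seed + data ⇒ bit-identical weights.

Saliency: vanilla gradients ∂o/∂Xᵢ of the sigmoid output at each test
spectrum (dropout off), computed by the same backward pass. The raw
derivatives are mapped through the empirical CDF of the pooled
N_test × p derivative set (ties averaged, so a constant field maps to
0.5); a per-wavenumber CDF variant is available behind a flag. The
summary curve is the per-wavenumber mean of the CDF values with a
mean ± 1.96·SEM band across test spectra.

## Unsupervised analysis

Each spectrum standardized to mean 0 and unit population SD; pairwise
cosine affinity (on standardized rows this equals the Pearson correlation
of the raw spectra); negative affinities clipped to 0 (normalized
spectral clustering assumes non-negative weights); symmetric normalized
Laplacian; embedding by the two eigenvectors of smallest eigenvalue;
seeded k-means with 10 restarts. Degenerate structure (no eigengap, or
more components than clusters) triggers a warning but still returns a
partition. Agreement with the labels: because cluster indices carry no
class meaning, both orientations are scored and the larger MCC reported,
with the confusion matrix in density form. MCC returns 0 by convention
when a marginal factor vanishes.

## Pipeline and reproducibility

`run_comparison` executes data → preprocess → per-window: ten-fold CV of
all five methods, permutation importance, CNN saliency, clustering → a
report with the 5×2 AUC grid (mean, SEM, folds), per-window MCC and
confusion densities, importance/saliency summaries and run metadata
(stage order, removed-outlier rows, per-stage seeds). One master seed
fans out to named per-stage seeds through `numpy.random.SeedSequence`
spawning; identical config + seed gives a byte-identical report, CNN
included.

CLI YAML schemas — generator config (`ramanclass simulate`): the fields
of `SyntheticConfig` (`axis_start`, `axis_stop`, `axis_points`, `peaks`
as a list of `{center, width, amplitude, class_delta}`, `baseline_coeffs`,
`noise_sd`, `noise_dist`, `outlier_rate`, `outlier_magnitude`,
`n_per_class`, `seed`, `peak_profile`), or the shortcut `{effect, delta}`
for the standard scenarios. Comparison config (`ramanclass run`): the
fields of `ComparisonConfig`, with `synthetic` holding a generator
mapping and `preprocess` the fields of `PreprocessConfig`.

## Experiment problem sizes

The calibration and recovery experiments (`ramanclass.experiments`,
exercised by the acceptance tests and `scripts/acceptance.py`) run on
scaled-down designs chosen to keep a full run in the minutes range on a
single CPU while leaving the conclusions unambiguous:

* null calibration — 400 spectra per class, LW window, 5 seeds, CNN at
  20 epochs with patience 3 (on null data the validation loss stalls
  immediately, so the short patience trims a schedule whose outcome is
  chance level either way);
* signal recovery — 150 per class, effect size 1.5, ten-fold CV, CNN
  at 35 epochs without early stopping (the ADAM step size bounds how far
  weights move per update, so the small sample needs its whole
  schedule); all five methods in the window carrying the effect, the two
  global methods in the untouched window (the recovery pattern being
  "local separation, global blindness");
* localization — 20 seeded runs for permutation importance, 10 for
  saliency (CNN at 30 epochs); clustering separation — 150 per class,
  5 seeds.

These experiments skip the baseline-subtraction stage: the injected
baseline is identical in both classes, so it carries no class signal,
and the questions the experiments answer do not involve it.

## Known limitations

* Sub-domain cut points for LRP inside LW are partly interpolated; only
  the named sub-bands (480–548, 2701–3200, 3200–3399 cm⁻¹) are pinned,
  so the defaults are one consistent choice among several. They are
  fully configurable.
* The CNN is CPU-only and sized for spectra of a few hundred to a few
  thousand points; no GPU path, no architecture search, no attribution
  methods beyond vanilla gradients.
* Clustering supports k = 2 with the cosine kernel only.
* Standardization makes the cosine kernel amplitude-invariant, so the
  unsupervised analysis cannot see a pure band-amplitude class effect
  once the baseline has been subtracted — the effect survives only as a
  shape change relative to retained common structure. The clustering
  experiments therefore run on data with the (class-symmetric) baseline
  retained; on real spectra, class differences that alter band shape or
  several bands at once would not need this.
* The generator's idealizations (see above) mean synthetic AUCs are not
  predictions of real-data AUCs; they validate mechanics and qualitative
  patterns, not instrument-level performance.
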