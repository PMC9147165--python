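# Methods

## Data model

A dataset pairs spectra blocks with a reference table.  Each
`SpectraMatrix` holds absorbance rows on one strictly increasing,
uniformly spaced wavenumber axis, with a single acquisition technique
(ATR, 500–4000 cm⁻¹, or transmission, 600–4000 cm⁻¹) and nominal
resolution (2, 4 or 8 cm⁻¹) per block and up to three replicate spectra
per sample.  Point spacing is taken as resolution/2, the usual FT-IR
convention; `validate_resolution` also accepts whole-resolution spacing
(within 50% relative tolerance) since exported tables vary.  Descending
axes are normalised to ascending on read so that window selection has a
single convention to reason about.

The `SampleTable` carries one row per physical sample: oil type, the 13
reference values (six fatty-acid percentages, unsaponifiable matter, and
the six pharmacopoeial indices), and the calibration/validation split.

### Calibration/validation split

The split is oil-type-aware: a type with one or two samples contributes
them all to calibration; a type with three or more keeps two in
calibration and sends the rest to validation.  Validation members are
drawn uniformly with a seeded generator from the type's samples that do
not hold the global minimum or maximum of *any* of the 13 responses —
extreme samples must stay in calibration so that validation predictions
interpolate rather than extrapolate — falling back to an unrestricted
draw when too few non-extreme samples exist.  The seed is a required
argument: the draw is random by design, but reproducibility demands it
be pinned.  All replicate spectra of a sample inherit its split.

## Preprocessing

Fifteen spectral variants = {raw, unit-Euclidean-norm normalisation,
SNV, Haar approximation, Haar detail} × {no derivative, 1st, 2nd},
plus a random-data control; the base transform is applied first, the
derivative second.

Choices made where the conventional definitions fork:

* **Normalisation** is scaling to unit Euclidean norm.  Unit-area
  normalisation is an equally common chemometric choice; unit-norm was
  picked because it is the natural companion of the inner-product
  geometry PLS works in, and it is exposed as its own transformer rather
  than hidden in the pipeline.
* **SNV** uses the sample (n−1) standard deviation.
* **Derivatives** are plain first differences Δx/h on the uniform grid,
  applied once or twice, with the effective axis moving to pairwise
  midpoints (then interior points).  No Savitzky–Golay smoothing is
  applied: derivatives here are the minimal definition, and smoothing
  would couple the preprocessing variants.
* **Haar transform** is single-level: aᵢ = (x₂ᵢ+x₂ᵢ₊₁)/√2,
  dᵢ = (x₂ᵢ−x₂ᵢ₊₁)/√2 (computed via PyWavelets), keeping either the
  approximation (WA) or detail (WD) half.  Odd-length rows are extended
  by repeating the last point.  The effective axis of the coefficients
  is the pairwise midpoints; the one synthetic pair created by padding
  is placed at `last + h/2` so the coefficient axis stays uniformly
  spaced (2h) — otherwise derivatives of wavelet features would be
  undefined on the padded grid.  Working FT-IR axes
  (range/spacing + 1 points) are generically odd-length, so this matters
  in practice, not just at corner cases.
* **Random control**: the feature matrix is replaced by seeded i.i.d.
  standard-normal draws of the same shape, keeping the wavenumber axis
  so that window selection still operates.  One random matrix is
  generated per (technique, resolution, replicate-mode) cell and shared
  across selections and responses — the control is treated exactly like
  a preprocessing variant.

## Variable selection

STD and CORR keep `round(0.4·q)` columns (half-away-from-zero rounding,
floor one column) ranked by across-sample standard deviation and
absolute Pearson correlation with the response respectively, ties broken
toward the lower wavenumber.  CHEM keeps every feature inside the closed
windows 600–1500 (fingerprint), 1600–1800 (C=O / C=C), 2850–3050 (C–H
stretch) and 3400–3500 cm⁻¹ (O–H stretch), evaluated on the *effective*
axis so it stays meaningful after derivatives or wavelet compression.

Selection statistics are computed on calibration rows only.  Computing
CORR on all samples would leak the validation responses into the model;
the scope is exposed (`selection_scope`-style argument in the grid
helpers default to calibration) but not the default.  Selection runs on
the preprocessed feature matrix, i.e. after the variant transform.

## PLS1 calibration

NIPALS PLS1 on mean-centred features and response (no autoscaling:
absorbance channels share units and autoscaling would inflate noise
channels).  Per factor: w = X'y/‖X'y‖, t = Xw, c = t'y/t't, p = X't/t't,
deflate X ← X − tp', y ← y − ct; regression vector b = W(P'W)⁻¹c;
early stop when ‖X'y‖ < 1e−12 with the factor count truncated and
recorded.

The factor count k ∈ 1..min(20, n_samples−2, q) is chosen by
leave-one-sample-out cross-validation: all replicate rows of a sample
leave together (row-wise LOO would place two copies of a held-out
spectrum's sibling replicates in the training set and is measurably
optimistic — the test suite demonstrates the gap).  `best_k` is the
global RMSECV minimiser, smallest k on ties; a one-standard-error rule
was considered and rejected in favour of the plain minimiser.

For speed the CV loop runs in the Gram (sample-space) formulation:
with K = XcXc' the factor iteration needs only O(n²) work per factor
after one O(n²q) kernel computation per model, instead of O(nq) per
factor per fold in the primal — decisive for spectra with q ≈ 1400
retained variables.  The fold kernels are double-centred submatrices of
one precomputed Gram matrix.  The formulation is algebraically exact
(not an approximation); the test suite pins it against the primal NIPALS
fold-by-fold to 1e−9.

Metrics: R² = 1 − SSres/SStot on calibration (R²c) and validation (R²v)
rows — the coefficient-of-determination form, which can go negative on
validation when a model is worse than predicting the mean; RMSEC,
RMSECV (at the chosen k), and RMSEP on the validation set.  RMSEV and
RMSEP name the same quantity here.  In all-spectra mode every replicate
row contributes one prediction to the validation metrics; in averaged
mode, one row per sample.

## The model grid

2 techniques × 3 resolutions × 2 replicate modes × 3 selections × 16
preprocessing variants × 13 responses = 7488 configurations, enumerated
in that fixed order.  Per cell: optional replicate averaging →
preprocessing → selection (fitted on calibration rows) → grouped-LOO
factor choice → final fit → metrics.  Degenerate cells (constant
response in a fold-free sense, empty selection, all-zero spectra)
produce a flagged `degenerate` record with NaN metrics and are excluded
from summary denominators; they never abort a run.  Preprocessed
feature matrices are memoised per (technique, resolution, mode, variant)
— 192 at most — and runs are resumable from a partial records file.

Report tables: (1) percentage of models with R² ≥ each of
{0.99, 0.95, 0.90, 0.80, 0.70, 0.60, 0.50} per variant and R² type,
inclusive boundaries; (2) percentage of models with *both* R²c and R²v
≥ 0.9 / ≥ 0.5 per response and grouping-factor level, with the random
control excluded (it is a null, not a processing choice) and empty
groups flagged via a zero model count; (3) top-3 models per response by
descending R²v, ascending RMSEP, ascending factor count.

## Synthetic data generator

The generator emulates the *statistical structure* the calibration
assumes, not instrument physics.

* **Design**: 17 oil types with the sample-count pattern
  (3,2,4,2,3,3,1,2,2,4,2,2,1,1,1,1,3) — 37 samples — three replicates,
  both techniques, all three resolutions.  Other shapes are
  configurable; counts outside the default are drawn from 1–4.
* **Composition**: per type, a mean fatty-acid composition from a
  Dirichlet with small concentrations (wide between-type spread: some
  types are high-α-linolenic linseed/chia analogues, others
  high-linoleic), plus an unsaponifiable fraction (0.3–2.2%) and a
  hydroperoxide marker (0.05–1.2%); per sample, multiplicative
  log-normal jitter (σ = 0.08) around the type mean, renormalised to
  100%.
* **Spectra**: each component has a Gaussian band library (shared acyl
  backbone — C=O ester 1745, CH₂/CH₃ stretches 2855/2925/2956,
  bending/fingerprint bands — plus a cis =C–H stretch near 3010 cm⁻¹
  whose amplitude grows with double-bond count, the trans 966 cm⁻¹ bend
  for the elaidic analogue, broad O–H bands for unsaponifiable and
  hydroperoxide).  The noiseless spectrum is the composition-weighted
  band sum; ATR blocks get a 2000/ν attenuation envelope as a
  penetration-depth proxy.  Replicates add multiplicative scatter
  exp(N(0, 0.05)), a random quadratic baseline (coefficient sd 0.01 on
  a [−1,1]-scaled axis) and white noise of sd 0.002·√(8/resolution)
  a.u. — finer resolution, noisier channels.  These magnitudes are
  realistic for bench FT-IR absorbance near 1 a.u. and are fixed
  defaults, not fitting knobs.  The band library is loadable from YAML
  so tests can use two-band toy libraries.
* **Responses**: fatty-acid values are the composition; iodine value is
  Σ compᵢ·coeffᵢ with coefficients 0 (saturated), 0.90 (oleic/elaidic),
  1.81 (linoleic), 2.74 (α-linolenic) — generator definitions matching
  textbook iodine values of the pure acids.  The remaining six values
  are `linkage·signal + (1−linkage)·uniform noise` mapped into
  pharmacopoeial ranges (e.g. peroxide 9.29–123, saponification
  178–196), where the signal is a fixed functional of the
  composition/marker and the linkage defaults are 0.8 for
  unsaponifiable matter and 0.1 for the acid/saponification/ester/
  hydroxyl/peroxide values.  This makes the generator's ground truth
  mirror the empirical finding the random control formalises: IR
  predicts what is linearly encoded in the spectrum and nothing else.

What passing tests on this generator do **not** show: robustness to
real-instrument artefacts (atmospheric lines, detector nonlinearity,
ATR anomalous dispersion, wavenumber miscalibration between sessions),
to non-Gaussian band shapes, or to reference-method error in the
response values.  Conclusions about *relative* merits of preprocessing
variants on real spectra should be re-derived on real spectra; the
package's claim is that the machinery is correct, leak-free and
null-calibrated.

## Numerical choices and degenerate inputs

* Axis uniformity tolerance 1e−6 relative; NIPALS early-stop 1e−12 on
  the residual covariance norm; Gram-vs-primal CV agreement pinned at
  1e−9 in tests.
* Selection count rounding: half away from zero, floor one.
* Tie-breaks: selection ranks toward lower wavenumber; `best_k` toward
  fewer factors; best-model tables by (R²v desc, RMSEP asc, factors
  asc).
* All-zero rows (normalisation), constant rows (SNV), constant
  responses, and empty CHEM selections raise typed degenerate-input
  errors that the grid converts to flagged records.
* CSV round-trips are exact: values are written with 17 significant
  digits and re-parsed with correctly rounded conversion.

## Problem sizes

The default study runs the full 7488-cell grid on the 37-sample
dataset; the largest cells carry ~111 spectra × ~3500 points (≈1400
retained variables after selection) and the whole grid completes in a
few minutes on one CPU thanks to the Gram-formulation CV and feature
memoisation.  Unit tests use reduced designs (5 types, one block) so
the fast suite stays in seconds.

## Known limitations

* PLS1 only — one response per model, as in the study design; no PLS2,
  kernel PLS or prediction intervals.
* No MSC, smoothing or baseline-correction preprocessing; no
  per-response window optimisation (the CHEM windows are global).
* The generator's ATR envelope is a smooth proxy; it does not model
  penetration-depth physics or refractive-index dispersion.
* Leave-one-sample-out is the only CV scheme; with 29 calibration
  samples the RMSECV profile can be flat near its minimum, and the
  smallest-k tie-break then decides.
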