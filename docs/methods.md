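# Methods

`leafspec` implements an end-to-end workflow for estimating leaf-scale
photosynthetic pigment contents — total chlorophyll (Chl_a+b) and total
carotenoid (Car), both in μg/cm² — from six-band proximal multispectral
images. This note documents the models, the synthetic data the pipeline is
exercised on, the numerical choices, and the limitations.

## Wet-lab reference chemistry

Ground truth comes from 95%-ethanol extracts read at 665, 649 and 470 nm:

    Chl a (mg/L) = 13.95·A665 − 6.88·A649
    Chl b (mg/L) = 24.96·A649 − 7.32·A665
    Chl a+b      = 6.63·A665 + 18.08·A649          (sum of the above)
    Car  (mg/L)  = (1000·A470 − 2.05·Chl a − 114.8·Chl b) / 245

The carotenoid equation is read with the whole numerator over 245, the
standard Lichtenthaler form for this solvent. Concentration converts to
area content as `C·n·V / area`, with the convention mg/L ≡ μg/mL (so
mg/L × mL / cm² gives μg/cm² with no extra factor); there is no external
reference value for this conversion, so only internal self-consistency
matters, and the synthetic lab tables round-trip through these equations
exactly. Negative computed concentrations are possible for pathological
absorbance combinations; they are returned unclamped (so algebraic
identities stay exact) with a warning.

## Synthetic scenes: what is emulated, and what is not

No public dataset accompanies the system modelled here, so
`synthetic_scene` generates ground-truthed scenes: 64 leaves from three
canopy layers (upper/middle/lower) tiled on a black board next to a
reference panel, in six bands (450/555/660/720/750/840 nm), 16-bit counts.

**Pigment distribution.** Chl_a+b and Car follow truncated normals over
the reference ranges (Chl_a+b 2.35–54.25 μg/cm², mean 26.96, SD 13.02; Car
2.12–9.54, mean 6.10, SD 2.05), coupled by a Gaussian copula with
correlation 0.8. Because the reference mean/SD are *sample* statistics of
bounded data — and truncation strictly shrinks a parent normal's SD — the
parent parameters are calibrated by fixed-point iteration on the exact
truncated moments so that the realized pooled mean and SD match the
reference values (realized CV ≈ 48% for Chl_a+b, ≈ 34% for Car). Layer mean
shifts (±6 μg/cm² Chl, ±0.8 Car) are mean-balanced: upper-canopy leaves run
low, lower-canopy leaves high, the pooled mean stays on target.

**Reflectance law.** Each leaf element reflects
`R_b = R∞_b · exp(−(kChl_b·chl + kCar_b·car))` with plateau
R∞ = (0.10, 0.55, 0.50, 0.60, 0.62, 0.62) and per-band specific
absorptions kChl = (0.010, 0.030, 0.045, 0.020, 0, 0),
kCar = (0.060, 0.010, 0, 0, 0, 0) per μg/cm². This law is a rendering
fixture, not a radiative-transfer model: the coefficients were chosen once
so that reflectance falls with pigment in the green/red/red-edge bands, is
flat in the NIR, and red-edge/green indices carry the most pigment
information — the qualitative structure seen on real leaves. No
PROSPECT-style realism, no BRDF, no camera response curves.

**Distortions.** Each leaf receives an affine scatter distortion
(gain ~ LogNormal(0, 0.15), offset ~ N(0, 0.02) in reflectance units)
standing in for specular reflection and leaf inclination — exactly the
distortion family MSC assumes — plus per-pixel Gaussian sensor noise
(SD 0.005 reflectance). Within each leaf, a smooth radial pigment gradient
(±10%, normalised so the masked map mean equals the leaf's table value
exactly) and a darker main vein (reflectance ×0.85) give pixel maps the
leaf/vein contrast of real imagery. The scatter/noise SDs are round
"plausible field conditions" numbers fixed at design time; nothing in the
pipeline is tuned to them.

**What passing tests therefore show.** The recovery tests demonstrate that
the pipeline inverts its own forward model under scatter and noise — i.e.
correctness of the machinery, not field-level accuracy. Real leaves add
structural variation (anatomy, water, surface wax) that the exponential
law does not generate, so LOOCV accuracies on synthetic scenes
(R² ≈ 0.99) sit well above what field data yields; the synthetic numbers
are upper bounds from a cleaner world, not reproductions.

## Calibration and segmentation

Counts → reflectance by ratio to the panel mean per band times the known
panel reflectance (default 0.99/band). This panel-ratio formula emulates a
flat-field calibration workflow and is invariant to global illumination
scaling. Segmentation thresholds the 840-nm band at 0.25 (strict `>`;
pigments do not absorb in the NIR, so leaves sit far above the black
background), labels 8-connected components, drops components under
50 px, and renumbers by descending area. Connectivity, the min-area floor
and the strict boundary are this package's choices where the procedure is
otherwise underdetermined. The reference panel itself exceeds the
threshold, so the panel region is excluded from the mask before labeling.

## Multiplicative scatter correction

The "ideal spectrum" is the mean over all leaf pixels of a group image
(recomputed per scene). Each spectrum is regressed on the ideal across the
six bands (OLS, spectrum ≈ a + b·ideal) and corrected as (spectrum − a)/b.
This removes any affine distortion with positive gain exactly and is
idempotent for a fixed ideal; fitted |b| < 1e-8 raises a degenerate-fit
error. One code route serves both leaf-mean spectra (modeling) and whole
pixel cubes (mapping); leaf-mean MSC is the modeling default. Corrected
reflectance may leave [0, 1] — MSC is affine — and downstream index
guards handle it.

## The 32-variable feature set

Six band reflectances (aliased B1–B6 in wavelength order 450→840 nm; the
numbering is declared here, wavelength-ascending) plus 26 published
vegetation indices form the fixed-order feature table. Each index has two
modes: `as_printed` reproduces the formulations as tabulated in applied
summaries, literally — including MSR and MSRre without square roots, RDVI
identical to NDVI, CVI with Blue² and GRNDVI with Blue — and `canonical`
substitutes the originally published forms (√ in MSR/MSRre denominators,
RDVI = (NIR−Red)/√(NIR+Red), CVI = NIR·Red/Green², GRNDVI with Red). The
printed idiosyncrasies look like typesetting slips, but intent is not
guessed: `as_printed` is the default and the mode is recorded in outputs.
Printed MSRre is the one formula not invariant to a common positive
scaling of the bands (it mixes a reflectance difference with the constant
1); canonical RDVI scales as √c. Both are documented exceptions in the
scale-invariance property test, not "fixed".

Divisions whose denominator magnitude is below 1e-9 yield NaN ("masked")
rather than ±inf; a leaf with any masked index is dropped from the table
with a logged count (no imputation). Features are z-scored (sample SD,
n−1) — chosen over min–max because both learners are scale-sensitive and
the index magnitudes span orders of magnitude — and the parameters are
stored for application to map pixels. Correlation ranking uses descending
|Pearson r| with ties broken by registry order.

## Variable selection

All three algorithms share one evaluation function, `cv_rmse`: repeated
k-fold (5 folds × 5 repeats by default) cross-validated RMSE of an
induction learner (PLS, LM, or RBF-SVM), pooling held-out predictions
within a repeat and averaging over repeats. Hyperparameter tuning inside
`cv_rmse` is nested by default (a fresh 3-fold grid search inside every
training partition, avoiding selection bias); a documented `tune_once`
mode runs one 5-fold grid search on the full subset up front and is used
for the heavy SVM wrapper searches, where nested tuning multiplies cost
~15× without changing the selections on these data sizes.

* **CORR** walks the |r| ranking, evaluating every prefix k = 1..32; the
  chosen subset is the prefix with minimal RMSE, smallest k on ties
  (parsimony). Learners are re-tuned at every k.
* **SFS** grows a subset greedily from empty and stops when no candidate
  improves on the best previous subset (or a cap, default uncapped, is
  reached); accepted-step RMSEs are strictly decreasing by construction.
  Each iteration re-seeds its resampling deterministically (base seed +
  1000·iteration).
* **RFE** starts from all 32 variables and drops the least important one
  per loop, recording each subset's RMSE; the chosen subset has the lowest
  recorded RMSE (fewest variables on ties). Importance is |coefficient|
  for linear learners. The RBF-SVM has no native weights, so importance is
  seeded held-out permutation importance: within each of 5 CV folds, the
  validation-RMSE increase when one feature column is permuted (10
  permutations), summed over folds. This evaluates the same statistic as
  re-running the full CV per permutation at a fraction of the cost.

## Regression models and validation

* **PLSR**: latent factors tuned over 1..min(15, p); features arrive
  z-scored, the model centers internally. Factor counts exceeding the
  feasible rank are skipped with a warning.
* **SVR (RBF)**: C ∈ {0.1, 0.5, 1, 2, 5, 10} and
  γ ∈ {0.005, 0.01, 0.05, 0.1, 0.5, 1} — logarithmic coverage of the
  design ranges [0.1, 10] × [0.005, 1], enforced at construction. Targets
  are standardized inside each fit (the kernel and the ε-tube are
  scale-sensitive) and restored on prediction; ε is fixed at 0.1 on the
  standardized target.

Validation is leave-one-out: feature normalization *and* tuning are redone
on each fold's n−1 training rows, so the held-out leaf leaks nothing
(perturbing a sample's target cannot change that sample's own prediction).
Merits are R² = squared Pearson correlation of measured vs predicted and
RMSE = √mean((y−Y)²). Printed variants of both formulas circulate with
typesetting corruption that makes them dimensionally inconsistent (an R²
numerator squaring residuals over a product of first-power deviation sums;
an RMSE deviating each measurement from the mean prediction); these
literal variants are kept behind `definition="as_printed"` /
`as_printed=True` fidelity flags rather than silently corrected. A
`one_minus_residual` R² (1 − SSres/SStot) is also available.

## Pixel mapping and layer reporting

A model fitted on leaf-mean spectra is applied to every leaf pixel of the
(typically MSC-corrected) reflectance cube: subset features per pixel,
stored normalization, predict. Pixels with masked features or predictions
outside the training target range widened by 20% of its span are flagged
as outliers — flagged, never silently dropped; the 20% margin is a
configurable stand-in for the unexplained outlier removal a field workflow
applies to specular patches. Layer summaries use 50 equal-width bins over
each layer's non-outlier range (50 bins is this package's choice; nothing
canonical fixes it) and report the pixel mean against the mean lab value of
that layer's leaves. For a linear model on a uniform noiseless leaf the
map mean equals the leaf-level prediction exactly (zero Jensen gap); for
the exponential forward law with within-leaf gradients a small gap is
expected and observed.

## Determinism and problem sizes

Every stochastic step (scene rendering, resampling, permutation
importance) is governed by explicit integer seeds; same seed ⇒
bit-identical scenes, selections and reports. Counts are held as float64
clipped to [0, 65535] in memory and quantised to uint16 only on TIFF
export, so exact-inversion invariants (panel recovery, clean-scene
roundtrip to 1e-6) hold in memory. The default scene is 360×480 px with 64
leaves (~500 px each) — large enough for stable per-leaf means and
pixel histograms, small enough that the full test suite and the
acceptance script each run in minutes on one core. The distributional
checks use n = 5000 pigment draws.

## Known limitations

* The pigment→reflectance law and all rendering details (ellipse leaves,
  single straight vein, radial gradient) are fixtures; conclusions about
  field accuracy cannot be drawn from synthetic recovery numbers.
* Bands are treated as ideal delta-like channels; no spectral response
  curves, band misregistration, vignetting or geometric correction.
* The affine per-leaf distortion is exactly the model class MSC inverts;
  real scatter is only approximately affine, so MSC's advantage here is an
  upper bound.
* Truncated marginals coupled by a Gaussian copula reproduce the reference
  moments but not necessarily the true joint shape of pigment
  distributions in a canopy.
* No embedded selection (random forest, lasso), no model families beyond
  PLSR/SVR, no uncertainty intervals, no canopy/UAV or temporal scope.
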