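# Methods

## Measurement model

A push-broom NIR hyperspectral camera records raw counts S(λ, n) per
wavelength λ and pixel n. Relative reflectance is

    R(λ, n) = (S(λ, n) − D(λ, n)) / (W(λ, n) − D(λ, n)),

with W a white-reference image and D a dark image. References may be full
cubes or per-(column, band) arrays for line-scan systems whose references are
constant along the scan. White plates are often recorded at a different frame
rate than samples; `ReferenceCubes.white_scale` (default 1.0, i.e. vendor-
normalised counts) applies an exposure correction to W before the ratio.
Values above 1 are legal — specular (Fresnel) geometry on a curved, glossy
fruit surface can return more light than the diffuse white plate.

Analysis is restricted to 913–2166 nm (200 bands on the synthetic grid);
beyond 2166 nm the signal-to-noise ratio of InGaAs-type sensors degrades.
The wavelength axis is always taken from file metadata, never recomputed
from a nominal band spacing, because nominal spacings rarely reproduce the
calibrated band centers exactly. Cubes are stored row-major with the band as
the trailing axis, 0-based indices; on disk either as ENVI (.hdr text header
plus raw float64 binary, BSQ or BIL) or a portable `.npz` container.

## Pretreatments

* **Savitzky–Golay smoothing**: window 7, polynomial order 2 (order
  configurable; 2 is the default because fruit reflectance is locally smooth
  and higher orders re-admit noise). Mirror padding preserves the band count.
* **SNV**: per spectrum x, (x − mean(x)) / sd(x) with the n−1 sample SD.
  Exactly removes per-pixel affine scatter (multiplicative gain + offset).
* **SG second derivative**: resolves overlapping absorption bands and removes
  baseline/slope. The least-squares fit is unreliable within half a window of
  each edge, so `trim` bands are dropped per side — default (window−1)/2,
  with an asymmetric `(left, right)` override because some published band
  counts imply an odd total trim that no symmetric rule can produce.
* **Autoscaling**: per-band centering/unit-SD scaling, fitted on training
  data only and stored with the model; never refitted at prediction time.
  Inside model fitting, a band whose SD is below 1e-9 of the largest band SD
  is treated as constant (unit scale): dividing by a round-off SD would
  amplify float noise into full-variance pseudo-signal.

When combined, the order is fixed: smoothing → SNV → second derivative, with
autoscaling applied downstream as part of model fitting.

## Segmentation

The six ROI masks per measured surface are built without training data:

1. Pixels with R(1077 nm) > 1.205 survive (background and resin tray fall
   below; both thresholds are strict inequalities). 1077 nm sits on a flat,
   bright part of the flesh spectrum, far from the water bands.
2. Survivors are smoothed (SG 7) and SNV-transformed; pixels with the SNV
   value at 1940 nm > −1.325 survive. Sepals carry far more surface water
   than flesh, so their deep 1940 nm absorption pushes this value well below
   the gate. Whether SNV should see smoothed or raw spectra is not
   observable from the final masks at realistic noise; smoothed is the
   default with a flag to disable.
3. Pixels reaching 2.2 relative reflectance at any band are discarded as
   saturated. Specular highlights clip far above any diffuse flesh
   reflectance; 2.2 leaves ~5% headroom above the brightest legitimate
   flesh pixel under worst-case scatter while sitting well below the
   synthetic clipping plateau of 2.5.
4. The surviving fruit spectra are smoothed, SNV-treated, autoscaled and
   decomposed by PCA **fitted per surface** (fruit-to-fruit variation would
   otherwise dominate a pooled PC1). The PC1 score image is binarised with
   Otsu's method over a 256-bin histogram. PCA sign is arbitrary, so classes
   cannot be labelled by sign: the smaller class is labelled achene, which is
   safe because achenes cover roughly 9% of a strawberry surface.
5. The fruit mask's bounding box is split at the midpoint of its longer
   axis into bottom/top halves; pixels exactly on the midpoint line go to
   the bottom (deterministic tie rule). Which half is "top" depends on how
   fruit were laid on the slider, hence the `top_side` flag.

Otsu implementation: threshold = the histogram **edge** whose split
maximises the between-class variance. When several splits tie exactly — the
empty bins between two well-separated score clusters — the contiguous tied
run is averaged, keeping the threshold centred in the gap. This convention
(MATLAB `graythresh` behaves the same way) makes the partition invariant
under negation of the scores, which matters because PC1 sign is arbitrary.

Mean ROI spectra are computed from **raw** reflectance; modelling
pretreatments are applied downstream to the averaged spectrum, not per pixel.

## Chemometrics

**PLS1.** SIMPLS is the default (deterministic, no deflation of X); NIPALS
is available and, for a single response, produces identical coefficient
paths up to round-off — both must match ordinary least squares when run to
full rank, which the tests enforce against an independent OLS oracle and
against scikit-learn. The coefficient path for 1..A latent variables comes
from one decomposition. If the residual covariance is numerically exhausted
early, the path truncates; requesting more LVs than the data's rank is an
error at the public API.

**LV selection.** 10-fold cross-validation, folds stratified by the Brix
rank (consecutive rank blocks receive a random permutation of fold labels)
so every fold spans the calibration range — this stabilises the fold-SD the
selection rule depends on. RMSECV per LV is pooled over out-of-fold
predictions; the SD is taken across folds at the globally minimising LV; the
**smallest** LV whose RMSECV is within one SD of the minimum is chosen
(parsimony favours transferable models). Cap: 20 LVs. Autoscaling is refit
inside every training fold, so no scaling information leaks.

**CARS.** Defaults: 50 Monte-Carlo runs, 80% sample ratio, the same 10-fold
assignment reused for every run so subset RMSECVs are paired. The enforced
retention fraction decays exponentially, pinned to 1 at run 1 and 2/p at run
N (p bands), matching the standard two-point calibration of the decay; ties
in the |coefficient| ranking break toward the lower band index; coefficients
are ranked on autoscaled predictors so the ranking is scale-fair. The
per-run LV count is the full-table CV selection, capped by subset size. If
adaptive resampling ever leaves fewer than two bands the schedule stops
early with the runs completed so far.

**Train/test split.** Each fruit is measured on two sides; a seeded coin
flip sends one side's records to training and the other's to testing, giving
a 1:1 split in which no fruit contributes the same surface to both sets —
the split tests transfer to an unseen surface, not interpolation.

**Model grid.** 2 (raw/SNV) × 2 (second derivative or not) × 2 (CARS or
not) × 3 ROIs = 24 patterns, all sharing one train/test split; each pattern
runs pretreatment → (CARS) → CV LV selection → final fit → train/test
metrics, reported sorted ascending by R²p.

## Mapping

The calibration (pretreatment chain + stored autoscaling + coefficients) is
applied to every flesh pixel. The prediction map — not the spectra — is then
smoothed with a mask-aware Gaussian filter (default σ = 1 px): kernel
weights are renormalised inside the mask so background never bleeds into
edge pixels; σ = 0 is the exact identity, and the masked normalisation can
never push values outside the input's [min, max]. Violin summaries use a
Gaussian KDE with Silverman bandwidth, linear-interpolation quantiles, and
flag regions under 5 pixels as low-support; a zero-spread region gets a
narrow triangular density of unit area rather than a KDE failure. Rendered
PNGs embed no timestamps, so identical inputs give byte-identical files.

## Synthetic scenes

The generator emulates the measurement, not the biology:

* **Endmembers** (background, tray, sepal, flesh, achene) are smooth
  continua minus Gaussian absorption features. Flesh carries the O–H bands
  at 970/1420/1900 nm and C–H bands at 1165/1780 nm; achene has far less
  water (weak 1420/1900 nm) plus a C–H₂ feature near 1710 nm; sepal's deep
  1940 nm water band is what the SNV gate keys on. The constructor
  self-checks every threshold-separation invariant (including worst-case
  scatter at the 1077 nm gate) and refuses to build a library that could
  silently break segmentation.
* **Brix coupling**: sugar content linearly deepens the 1420/1780/1900 nm
  features (a Beer–Lambert proxy), so wavelength selection has a known right
  answer. The scene's Brix field runs linearly along the fruit's long axis,
  default 5 at the base to 10 at the apex (strawberries sweeten toward the
  apex); achene speckles are placed at a target 8.7% of fruit pixels.
* **Nuisances**: per-pixel multiplicative scatter U(0.8, 1.2), additive
  offset U(−0.05, 0.05) — exactly the affine structure SNV removes — plus
  white Gaussian noise (default SD 0.02, ~2% of signal) and a few pixels
  clipped to a 2.5 plateau to emulate specular saturation.
* **Flat calibration tables** (`generate_dataset`): flesh endmember plus
  Brix-weighted narrow features (index-space SD 0.5 bands) at five named
  wavelengths; `noise_sd` (default 0.2 Brix%) is measurement noise on the
  recorded Brix value, with small spectral noise (SD 0.003) and mild affine
  scatter so PLSR has realistic nuisance structure to reject.
* All randomness flows through one `numpy` Generator seeded explicitly; no
  global state. Identical seeds give byte-identical cubes, tables, splits
  and figures.

What the synthetic scenes deliberately do **not** model: fruit curvature and
its illumination gradients, instrument point-spread and wavelength
miscalibration, mixed pixels at class boundaries, temperature-dependent water
band shifts, and any biological covariance between sugar and water content.
Passing tests therefore demonstrate that the algorithms recover known
structure under scatter and noise — not that a specific instrument will
reach a specific accuracy on real fruit.

## Numerical conventions

* Sample SD (n−1) everywhere, in SNV, autoscaling and fold SDs alike.
* Strict inequalities at both segmentation gates; midpoint-line pixels to
  the bottom half; |coefficient| ties to the lower band index; Otsu ties
  averaged over the contiguous run.
* `nearest_band` breaks equidistant ties toward the lower index.
* Problem sizes in the test suite and acceptance script — 128×128 scenes,
  n = 400 calibration tables, 20 repetitions, 30-fruit grids — were chosen
  as the smallest sizes at which the stochastic recovery criteria are
  comfortably stable across seeds.

## Known limitations

* The ENVI reader covers the header fields this pipeline needs (dimensions,
  data type, interleave BSQ/BIL, wavelength list); it is not a general ENVI
  implementation.
* The top/bottom split assumes the fruit's long axis aligns with one image
  axis (true for tray-mounted line scans); an oblique fruit would need a
  principal-axis split instead.
* CARS randomness means the selected band set varies between seeds; only
  the recovery of genuinely informative bands is stable, not the exact
  subset size.
* Per-pixel prediction applies a model calibrated on averaged spectra;
  pixel-level noise is higher than the calibration data's, which is why the
  map is smoothed before interpretation.
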