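# Methods

`honeynir` implements a chemometric pipeline for honey near-infrared (NIR)
spectroscopy: prediction of eight physicochemical traits (moisture, HMF,
diastatic activity, electrical conductivity, glucose, fructose, reducing
sugars, pH) and 3-class botanical-origin discrimination (chestnut CH,
polyfloral PF, pooled multifloral MF) across three instrument
configurations. Because the pipeline is validated on synthetic data, this
note documents both the analysis methods and the generative model, and is
explicit about what passing tests do and do not show about real honey
spectra.

## Synthetic study design

### Composition model

Per-class reference values come from a published 30+30 CH/PF composition
table (group means with a pooled SEM per variable). Per-class SDs are
reconstructed as `SD = SEM * sqrt(30)`. Draws are truncated normals
(clipped at ±4 SD and at physical bounds: moisture within the 13–25 %
refractometer operating range, all quantities positive). Conventions:

* `reducing_sugars = glucose + fructose` exactly, matching the reference
  means (20.4 + 38.5 = 58.9 for CH; 30.2 + 38.4 = 68.6 for PF).
* Electrical conductivity and pH are deterministic monotone functions of a
  latent "mineral" concentration (conductivity is the latent itself; pH is
  the affine map calibrated through both class means). Both trace mineral
  and organic-acid load rather than any specific NIR-active bond, so they
  are predictable from spectra only through correlated constituents.
* The MF class has no published composition table; it is drawn as a 50/50
  CH/PF mixture with 1.5× inflated SDs, giving intermediate means and a
  wider spread. One parent is picked per sample so that the sugar/mineral
  pattern of each MF sample is internally coherent.

A consequence of the reconstructed SDs worth knowing when interpreting the
ANOVA tests: the moisture contrast (17.1 vs 17.7, SD ≈ 0.99) has an effect
size of d ≈ 0.61, i.e. ~65 % power at n = 30/group. Direction-recovery
tests therefore check the *sign* of each significant contrast (plus
fructose non-significance), not per-replicate significance, which no
faithful generator could deliver in ≥ 90 % of draws at this effect size.

### Spectral model

Absorbance is additive Beer–Lambert chemistry under an
instrument/presentation layer:

```
clean(λ) = pathlength · Σ_analyte conc_a · Σ_bands amp · exp(−(λ−c)²/2σ²)
           + α + β·λ + class_offset
row(λ)   = clean(λ) · scatter + ε(λ),   scatter ~ N(1, 0.02),  ε ~ N(0, noise_sd)
```

Planted bands (centers / σ in nm, amplitudes in absorbance per unit
concentration per unit path):

| analyte | bands | rationale |
|---|---|---|
| moisture | 1440/18 (0.050), 1920/14 (0.040) | dominant water O–H first overtone and combination bands |
| glucose | 1450/15 (0.020), 2100/25 (0.020) | sugar O–H/C–H overtone shoulder and C–H combination band |
| fructose | 1390/15 (0.015), 2270/25 (0.015) | sugar bands shifted from glucose's — the two sugars are NIR-separable because their band positions are offset, not because either owns an exclusive window |
| HMF | 2150/20 (0.0004) | single tiny band: low concentration, poor predictability by construction |
| diastase | none | enzyme at trace level, no usable NIR signature |
| mineral (EC/pH) | 1650/150 (0.0015) | very weak, very broad; sub-noise per column — conductivity is spectrally indirect |

This reproduces the documented spectral phenomenology: four dominant
features (the 1420–1470 cluster, 1900–1940, 2050–2150), mean absorbance
ordered PF > MF > CH at every grid point (class baseline offsets +0.06 /
0 / −0.06 absorbance units, a crystallisation/scattering proxy), and
narrow-range saturation (below). Band positions/widths are also the
ground truth for selection-recovery tests: the "informative set" of an
analyte is every grid point within ±2σ of one of its bands.

Band amplitudes and the mineral band were calibrated once against the
module's own recovery requirements: an early layout with fructose bands at
1430/2080 nm (inside glucose's ±2σ regions) made wavelength-selection
recovery structurally impossible — fructose is essentially uncorrelated
with glucose across classes, so fructose-dominated columns scored near
zero selectivity ratio and punched holes in the middle of the glucose
mask; similarly a 2.5× stronger mineral band consumed most of the SR
top-quartile budget over its 600 nm span. Both are generator design
choices, not post-hoc tuning of analysis thresholds, and they are fixed.

### Instrument profiles

| profile | range (nm) | step | mode | noise SD | path | saturation |
|---|---|---|---|---|---|---|
| benchtop | 850–2500 | 0.5 | transflectance | 0.002 | 1.0 | — |
| wide_portable | 1350–2500 | 16 | transflectance | 0.010 | 1.0 | — |
| narrow_portable | 1102–1600 | 2 | transmittance | 0.005 | 1.4 | > 2 AU |

Noise SDs are representative of a scanning monochromator vs. MEMS-type
portable units. The narrow-range profile models an over-long transmission
path (8 mm cuvette) as a 1.4× path gain; wherever the clean absorbance
exceeds 2 AU the detector noise is inflated 5×, which concentrates the
artefact in the 1400–1600 nm water/sugar region — exactly where that
instrument's only glucose information lives. The wide-range grid stops at
2486 nm because (2500 − 1350)/16 is not an integer; the upper bound is
inclusive-at-most.

## Pre-processing

Operator order is fixed: scatter correction (SNV or MSC) → linear
detrending → Savitzky–Golay (window 3–21 odd, polyorder 2–3, derivative
0–2; window 1 = no filtering) → column scaling (mean centring or
autoscaling). SNV uses the sample SD (n−1). The MSC reference and all
column statistics are estimated on calibration rows only and reused on
validation rows. SG derivatives are scaled by `1/step^deriv` so outputs
are per nm and band positions are comparable across instrument grids (an
index-unit convention would make derivative magnitudes grid-dependent);
edge samples are handled by evaluating the local polynomial fit
(`mode="interp"`). Autoscaling leaves constant columns centred but
unscaled rather than dividing by zero. The full enumeration grid has
3 × 2 × 58 × 3 = 1044 specs (58 = no-filtering + all valid SG triples;
window 3 admits only polyorder 2). Spec string ids include the SG
polyorder because the conventional "SG (7) 1st derivative" notation does
not distinguish polyorder 2 from 3.

## PLS engine

PLS1 via NIPALS with X-block deflation only; y-loadings are recomputed
against the centred response per component (equivalent to y-deflation by
score orthogonality). Convergence tolerance 1e-10, ≤ 500 inner iterations
(one pass suffices for a single response). At full predictor rank the
coefficients equal OLS, which the tests exploit as an oracle. Component
extraction stops early if the residual covariance vanishes.

Diagnostics use the standard literature definitions (the originating
report names but does not print them):

* **VIP**: `VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a)` with
  `SS_a` the response variance captured by component a; mean squared VIP
  is identically 1, so VIP ≥ 1 marks above-average influence.
* **Selectivity ratio**: target projection of X onto the normalised
  regression vector; SR_j = explained/residual variance of column j.
  Columns with zero residual variance get the max finite SR (logged).

RMSECV pools all held-out residuals across folds before the square root.

## Wavelength selection

1. **Candidates**: grid points with VIP ≥ 1.0 AND SR above its 0.75
   quantile; runs separated by ≤ 2 points are merged, runs shorter than 5
   points dropped; each surviving run is then expanded by 25 % of its
   length per side (overlaps re-merged). The expansion is principled, not
   cosmetic: VIP ≥ 1 is a relative-weight criterion whose threshold
   crossing sits at ~±1.6σ of a Gaussian band *independent of SNR* (for a
   single band on p points at step Δ the crossing solves
   `exp(−d²/σ²) = σ√π/(Δ·p·s)` with s the band's weight share), so raw
   runs systematically under-cover band shoulders. If the combined mask is
   empty the VIP criterion alone is used (logged); if still empty an error
   instructs full-spectrum use.
2. **siPLS**: greedy forward combination of candidate intervals by RMSECV
   (component count chosen 1..15 per evaluation); accept while the
   relative improvement is ≥ 0.5 %; ties break to the lower start index.
   Deterministic and presentation-order independent.
3. **CARS-PLS** (optional refinement): 30 Monte-Carlo iterations, each
   fitting PLS on 80 % of samples over the surviving variables, ranking by
   |coefficient|; retention schedule `r_i = max(round(p·0.9^i), 30)` — a
   single-rate exponential as stated, not the classical two-parameter
   `a·e^(−k·i)` form; enforced top-`r_i` selection followed by adaptive
   reweighted sampling (draws ∝ |coefficient|, topped up from the ranking
   if duplicates fall below the floor). The iteration with minimal RMSECV
   defines the selection. CARS operates on single wavelengths (standard
   form) after siPLS.

The selection stage runs on SNV + mean-centred spectra by default. This
matters: without scatter correction the multiplicative jitter leaves a
residual floor that a single interval already reaches (measured:
single-interval RMSECV ≈ full-spectrum RMSECV), so no second interval can
improve the fit by ≥ 0.5 % and the greedy search degenerates. For the
classification target the cascade uses integer-coded class labels as its
working response (VIP/SR/siPLS are regression constructs).

## Calibration and evaluation

* Learners: PLS-R (our engine), k-NN (Euclidean/Manhattan), random forest
  (200–500 trees, depth 10–20, seeded), SVM/SVC (linear, polynomial, RBF,
  sigmoid). k-NN/RF/SVM operate on PCA scores fitted on calibration rows
  only — the component count is the reported "PC". PLS-DA is deliberately
  not offered; classification uses the k-NN/RF/SVC implementations.
* Validation: Venetian-blind k-fold (`fold = row_index mod k` in stable
  sample order, k = 5 default) and bootstrap (B = 100; calibrate on the
  draw, score out-of-bag, skip degenerate iterations, report the mean and
  retain the dispersion). Pre-processing, PCA and the learner are refit
  inside every fold/iteration — a leakage test asserts that mutating
  validation rows cannot change calibration outputs.
* Metrics: R²/RMSE/MAE for regression; accuracy, balanced accuracy (mean
  per-class recall), macro-F1 (per-class F1 averaged, 0 when undefined,
  logged) and MCC for classification. MCC uses the correlation-coefficient
  form over the C×C confusion matrix, which reduces exactly to the binary
  TP/TN/FP/FN formula at C = 2 — the binary formula is what the
  originating report prints while reporting MCC for 3 classes.
* Grid search: exhaustive over candidate preprocessing × model specs;
  winner by minimum RMSE (regression) or maximum macro-F1
  (classification); ties break to fewer latent variables/PCs, then the
  lexicographically smaller preprocessing id. The R²-maximising criterion
  is also exposed (`criterion="r2"`); RMSE is the default and the run log
  records which was used.

The default workflow candidate set is deliberately compact (3
pre-processing chains; PLS at 4/8/12 LVs plus a linear SVR for
regression; linear SVC, k-NN, RF for classification) — enough to exercise
every code path at interactive runtimes; the full 1044-spec grid is
available to callers who want it.

## What the synthetic validation does and does not show

The generator emulates: class-conditional composition with realistic
covariance through class structure, duplicate scans, instrument-specific
grids/noise, multiplicative scatter, class-ordered absorbance levels, the
saturation artefact, and localized Gaussian absorption bands with planted
ground truth. It does **not** emulate: crystallisation kinetics and its
scattering signature, temperature effects, non-Gaussian band shapes,
wavelength-registration error, inter-batch drift, or real covariance
between sugars within a floral class. Consequently: passing recovery tests
shows the selection cascade finds *planted* bands under the stated noise
model; R² values on synthetic data (≈ 0.99 for glucose) exceed what real
honey calibrations achieve, because real reference-method error and
matrix effects are absent. The qualitative contrasts — benchtop ≥
portable, diastase unpredictable, accuracy > balanced accuracy under
class imbalance — are the transferable conclusions, and those are what
the acceptance suite asserts.

## Numerical choices and degenerate inputs

* Truncated-normal draws clip at ±4 SD and physical bounds; seeds are
  explicit everywhere (no global RNG state).
* SNV rejects zero-variance rows by index; MSC rejects |slope| < 1e-12.
* RMSECV at component counts beyond a fold's trainable rank reuses the
  maximal-rank model for that fold.
* CARS with p < 30 degenerates to the full spectrum with a warning.
* Venetian-blind fold sizes differ by at most one by construction.
* The pooled SEM printed by the composition report is `sqrt(MSE/n)` with
  n the per-group size (harmonic mean when unequal) — a documented
  convention, since a single printed SEM does not identify one.
* Bootstrap iterations with an empty out-of-bag set or a missing class in
  the calibration draw are skipped and counted.
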