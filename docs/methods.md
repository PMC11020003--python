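# Methods

## Synthetic spectra: the generative model

Tissue reflectance is modelled as a scattering baseline attenuated by
haemoglobin absorption:

    R(λ) = A (λ/500 nm)^(−b) · exp(−BVF · L · [s·μ_HbO2(λ) + (1−s)·μ_Hb(λ)]) + ε(λ)

with blood volume fraction BVF ∈ [0,1], oxygen saturation s ∈ [0,1],
scatter amplitude A > 0 and power b ≥ 0 (Mie-like power law), effective
optical path L in mm, and iid Gaussian noise ε with standard deviation
`noise_sd` in reflectance units. μ_HbO2/μ_Hb are whole-blood absorption
coefficients (mm⁻¹) bundled as `data/hemoglobin_extinction_synthetic.csv` —
a *synthetic*, physically motivated approximation built from anchor points at
the known band positions (oxy Q-bands 542/577 nm, deoxy band 555 nm, deoxy
760 nm bump, ~800 nm isosbestic crossing) and monotone-cubic interpolation
over 440–1010 nm. Downstream code depends only on this qualitative band
structure, not on tabulated accuracy.

Default class parameters (package choices, tuned for separable-but-
overlapping classes, not claims about any measured cohort):

| parameter | normal | tumour |
|---|---|---|
| blood volume fraction | 0.015 | 0.04 |
| haemoglobin saturation | 0.85 | 0.60 |
| scatter amplitude / power | 1.0 / 1.2 | 1.15 / 1.0 |
| path length (mm) | 5 | 5 |
| noise sd (reflectance) | 0.01 | 0.01 |

Tumour tissue carries more, less-oxygenated blood — the contrast DRS
exploits in practice. Per-patient biology is emulated by multiplicative
log-normal jitter (σ = 0.15) on BVF and scatter amplitude, drawn once per
patient, which makes patient-wise cross-validation a genuine generalisation
test rather than a formality. The generator does **not** model specular
glare, probe-pressure effects, fat/stool contamination, water/lipid
absorption, wavelength-dependent noise, or detector nonlinearity; passing
tests therefore demonstrate correctness of the pipeline's machinery, not
clinical-grade performance on real tissue.

A lamp-shaped white reference (tungsten-like Gaussian peaking at 900 nm) and
a small dark offset allow the generator to emit raw detector counts
(I = D + R·(W−D)) so the calibration stage is exercised end to end.

## Preprocessing

Order: calibrate → resample → outlier-reject → SNV. Outliers are judged on
calibrated physical reflectance because SNV deliberately erases the
per-spectrum scale on which aberrant acquisitions (air gaps, saturation) are
conspicuous.

- **Calibration**: R = (I−D)/(W−D); values outside [0,1] are kept, since SNV
  later removes scale/offset and clipping would bias shape features.
- **Grid**: 1922 equally spaced points, 450–1000 nm inclusive
  (step 550/1921 ≈ 0.286 nm); linear interpolation, no extrapolation, no
  pre-smoothing.
- **SNV**: subtract the per-spectrum mean, divide by the sample standard
  deviation (divisor n−1); constant spectra are a degenerate-input error.
- **Outlier rule**: residual per spectrum = mean calibrated intensity over
  the grid; flag iff |r − median(r)| > 1.5 × MAD with *unscaled* MAD (no
  1.4826 consistency factor) and a strict inequality at the boundary. The
  25th/75th percentiles are computed for diagnostics only. Note that for
  continuously distributed residuals this rule flags roughly 30% of spectra
  (1.5 × MAD ≈ 1.01 σ under normality): it is an aggressive trim, retained
  deliberately as specified; dataset sizes elsewhere account for the loss.
  "Residual" interpretation (whole-spectrum, not per-wavelength) is a design
  choice: the rule's purpose is removing whole erroneous acquisitions.

## Shape features and saturation unmixing

Peak finding runs on a lightly smoothed copy (moving average, 15 grid points
≈ 4.3 nm, configurable) to suppress per-point noise; each candidate is then
refined to the unsmoothed local apex within half a window, and candidates are
ranked by unsmoothed intensity, so the reported primary peak is never below
the secondary. The secondary peak must lie ≥ 20 nm from the primary so the
two lobes of one haemoglobin band are not counted twice. Spectra with no
interior local maximum (constant/monotone) fall back to the global maximum
and are flagged degenerate. Band means average the closed wavelength
intervals 480–550, 580–700, 450–720 nm on the SNV values.

Haemoglobin saturation is estimated by bounded least squares of −log R over
500–600 nm against [μ_HbO2, μ_Hb, 1, (λ−550)/50] with the haemoglobin
coefficients constrained non-negative; the constant+slope nuisance absorbs
the locally near-linear log-scattering baseline. sO₂ = c_oxy/(c_oxy+c_deoxy),
flagged undefined when the total haemoglobin signal is below 10⁻⁶. This is a
closed-form approximation chosen over Monte Carlo photon-transport lookup
tables, which would add nothing testable here; noise-free recovery error is
≤ 0.012 across sO₂ ∈ [0.1, 0.9] (the acceptance script recomputes this).

Boruta is implemented from scratch: each iteration permutes every feature
into a shadow copy, fits a random forest (default 300 trees, mean decrease
in impurity) on [real | shadow], and scores a hit for every real feature
beating the best shadow; a two-sided binomial test of the hit count against
p = 0.5 at threshold 0.01 assigns confirmed/rejected, else tentative.
Defaults: 100 iterations. Tests run smaller forests (30–50 trees) and fewer
iterations to keep the suite fast; statistical conclusions are unchanged.

## SpecNet and baselines

SpecNet is implemented directly in numpy (einsum convolutions, explicit
backprop, Adam at 10⁻³, batch 32, cross-entropy, early stopping on
validation loss with patience 10, best-weights restore). Architecture
defaults k₁ = 11, k₂ = 2, n₄ = 64 are package choices exposed in
`SpecNetConfig`; n₂ = n₁−k₁+1 (valid convolution, stride 1) and
n₃ = ⌊n₂/k₂⌋ (floor where k₂ ∤ n₂). The descriptor's per-block counts
20(k₁+1), (20n₃+1)n₄, (n₄+1)n₅ are asserted equal to the instantiated
arrays' sizes. Training is deterministic given the config seed.

Baselines (rf, xgb, lgbm, mlp, svm) use library defaults with fixed seeds
and n_jobs = 1 for determinism. Tree/SVM/MLP baselines may consume shape
features, the full intensity sequence, or both (`design_matrix`
representation flag); SpecNet consumes the intensity sequence only.

Cross-validation is patient-wise: patients are greedily packed (descending
spectrum count, seeded tie shuffle) into the fold minimising the resulting
sum of squared per-class fold counts — approximate stratification, since the
exact patient-level problem is bin packing. Fold metrics are summarised as
mean ± 95% t-interval (t₀.₉₇₅,k₋₁ · SE across folds). AUC is trapezoidal
integration of the ROC with thresholds at distinct scores, which equals
pairwise concordance with ties counted half (property-tested against
exhaustive enumeration). Tumour is the positive class at threshold 0.5.

## Tracking

HSV gate defaults: hue 100–140° (of 360), saturation ≥ 0.4, value ≥ 0.3,
minimum blob area 50 px²; hue wraparound is supported by dual-interval
masking; the largest connected component wins (single-marker assumption).
The Kalman filter uses a constant-velocity state (x, y, vx, vy), unit frame
step, Q = q·I₄ (q = 1 px²/frame²), R = r·I₂ (r = 2 px²), Joseph-form
covariance updates with explicit symmetrisation, initialisation from the
first detection with zero velocity and a large velocity variance (10⁴), and
track loss after 15 consecutive misses with re-initialisation on the next
detection. For exact constant-velocity motion with vanishing q and r the
filter's predictions are exact (machine precision), which the tests assert
in the limit q = 10⁻¹², r = 10⁻⁹.

## Overlay

Probability → colour is linear per channel from green (0,255,0) at p = 0 to
pink (255,105,180) at p = 1 (pink fixed by choice; round-half-up to
integers). Sites are alpha-blended filled disks (default α = 0.6), drawn in
sequence order, onto a copy of the frame. Rendering is offline; a live GUI
is out of scope.

## Problem sizes and determinism

Default synthetic study used by the acceptance script: 20 patients × 2
classes × 50 spectra (5-fold patient-wise CV with the random-forest
baseline, plus a label-permutation null), a separable 200-spectrum set for
SpecNet training (≤ 30 epochs), 1000-trial brute-force oracle comparisons
for the MAD rule and AUC, and a 60-frame tracking scene with 10% occluded
frames — sizes chosen so the whole script completes in about a minute on one
CPU while leaving every statistical conclusion unambiguous. All randomness
flows from explicit integer seeds (numpy `default_rng`); the demo pipeline
writes byte-identical metrics JSON across repeated runs with one config.

## Known limitations

- The absorption table is a constructed approximation; absolute saturation
  estimates on real spectra would require a measured extinction reference.
- The MAD×1.5 outlier rule is aggressive on clean continuous data (see
  above); a consistency-scaled MAD or larger factor would trim less.
- Approximate stratification can leave fold class fractions a few percent
  from the global fraction when patients are few or very unequal.
- The numpy SpecNet is CPU-bound and intended for spectra-scale inputs, not
  large image batches; no GPU path.
- Linear-SVM probabilities come from sklearn's internal calibration
  (`SVC(probability=True)`), which is slated for deprecation upstream.
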