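# drsmargin

Diffuse reflectance spectroscopy (DRS) measures broadband light diffusely
reflected from tissue; its spectral shape encodes haemoglobin absorption and
microstructural scattering, and therefore distinguishes tumour from normal
tissue at a resection margin. `drsmargin` is an end-to-end, fully synthetic-
testable implementation of a DRS tumour-margin assessment pipeline for
surgeons' intraoperative feedback systems and for researchers prototyping
spectral tissue classifiers:

- **Calibration & preprocessing** — white/dark reference calibration
  R(λ) = (I−D)/(W−D), linear resampling onto a fixed analysis grid of 1922
  equally spaced samples over 450–1000 nm, per-spectrum standard normal
  variate (SNV) normalisation, and outlier rejection by the median/MAD rule
  (flag spectrum *i* iff |rᵢ − median(r)| > 1.5·MAD, rᵢ = mean calibrated
  intensity).
- **Shape features** — primary/secondary peak intensity and wavelength, band
  means over 480–550, 580–700 and 450–720 nm, and a haemoglobin oxygen
  saturation coefficient sO₂ = c_HbO₂/(c_HbO₂+c_Hb) estimated by constrained
  unmixing of −log R over 500–600 nm against oxy/deoxy whole-blood absorption
  curves; Boruta all-relevant feature selection against permuted shadow
  features.
- **Classification** — *SpecNet*, a five-layer 1D CNN
  (input n₁ → 20-filter convolution of length k₁, n₂ = n₁−k₁+1 → max-pool of
  width k₂, n₃ = ⌊n₂/k₂⌋ → fully connected n₄ → softmax n₅ = 2), implemented
  from scratch in numpy with per-block trainable-parameter counts
  20(k₁+1), (20n₃+1)n₄ and (n₄+1)n₅; plus RF/XGB/LGBM/MLP/SVM baselines.
  All models are evaluated under **patient-wise stratified 5-fold
  cross-validation** (no patient's spectra ever span training and test) with
  accuracy, sensitivity, specificity and trapezoidal ROC AUC.
- **Probe tracking & overlay** — HSV segmentation of a green probe marker,
  constant-velocity Kalman filtering of the tip position, and a graduated
  green→pink colourmap rendering per-site tumour probability onto video
  frames.
- **Synthetic data** — a generator producing tissue-like reflectance spectra
  (scattering power law × Beer–Lambert haemoglobin attenuation, per-patient
  parameter jitter) and marker videos with known trajectories, so the whole
  pipeline is testable without any measured data.

## Worked example

```python
import numpy as np
from drsmargin import (SyntheticDatasetSpec, generate_dataset, preprocess_set,
                       estimate_hb_saturation)
from drsmargin.models import cross_validate, design_matrix

study = generate_dataset(SyntheticDatasetSpec(
    n_patients=12, spectra_per_class_per_patient=25, seed=1))
processed, report = preprocess_set(study)
print(f"kept {len(processed)} of {len(study)} spectra "
      f"(MAD x {report.threshold_factor:g} flagged {int(report.flags.sum())})")
sat = [estimate_hb_saturation(s).value for s in processed[:3]]
print("saturation of first three spectra:", np.round(sat, 3))
X, y, patients = design_matrix(processed, "intensities")
result = cross_validate(X, y, patients, kinds=["rf"], k=5, seed=1)["rf"]
print(result.summary())
```

prints

```
kept 464 of 600 spectra (MAD x 1.5 flagged 136)
saturation of first three spectra: [0.825 0.823 0.813]
metric          value             95% CI
accuracy        1.000     (1.000, 1.000)
sensitivity     1.000     (1.000, 1.000)
specificity     1.000     (1.000, 1.000)
auc             1.000     (1.000, 1.000)
confusion    TP=200 FP=0 TN=264 FN=0
```

The MAD rule removes spectra whose mean calibrated reflectance is far from
the set median (here mostly spectra of patients whose jittered blood volume
is extreme); the saturation estimates sit near the generating normal-tissue
value of 0.85; and the default synthetic class contrast (tumour: more blood,
less oxygenated) is fully separable by a random forest under patient-wise
cross-validation — perfect metrics here reflect the clean synthetic
contrast, not expected clinical performance.

The same stages are available from a CLI:

```sh
drsmargin simulate --patients 8 --out study/
drsmargin preprocess --in study/spectra_raw.drsspec \
    --white study/white.drsspec --dark study/dark.drsspec --out proc/
drsmargin run --demo --seed 7 --out demo/        # full pipeline
```

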