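# lungraman

Single-point fingerprint Raman spectroscopy (800–1700 cm⁻¹) can separate
cancerous/necrotic from normal or benign lung tissue: protein-associated
vibrational bands — above all amide I at ~1657 cm⁻¹ and tyrosine ring
breathing at ~852 cm⁻¹ — are elevated in malignant tissue. Turning that
physical contrast into a classifier is mostly a signal-processing problem:
the Raman signal sits on a fluorescence background an order of magnitude
larger, a substantial fraction of intraoperative measurements are too noisy
to use, and with ten patients the validation must be leak-proof at the
patient level.

`lungraman` implements that full analysis chain for spectroscopists and
biomedical-ML practitioners:

- **synthetic cohort generator** — measurement-level simulation of the
  acquisition protocol (10 repeat frames at 75 ms, a 50 ms dark frame,
  instrument response, wavenumber miscalibration, shot + read noise, a
  tunable fraction of low-SNR measurements) with hidden ground truth,
  so every downstream stage is testable without patient data;
- **preprocessing** — repeat averaging, dark subtraction scaled by the
  integration-time ratio, instrument-response correction against a
  certified broadband reference, polynomial wavenumber calibration from a
  peak standard, **BubbleFill** baseline removal (the fluorescence
  baseline is the upper envelope of circular "bubbles" grown from below
  until they touch the spectrum), and SNV normalization
  `z = (x − mean(x)) / sd(x)`;
- **quality filtering** — a quality factor `QF ∈ [0, 1]`, the fraction of
  an SNV spectrum's energy at scales wider than a smoothing window;
  spectra with `QF ≤ 0.4` are rejected;
- **classification** — per-wavenumber features (1060–1100 cm⁻¹ excluded
  as possible surface-blood contamination), feature ranking by the entry
  order of an L1-regularized linear-SVM path, a hinge-loss linear SVM on
  the top-k features, leave-one-patient-out (LOPO) cross-validation with
  in-fold selection, and a grid search over C ∈ [0.01, 5], k ∈ [5, 20];
- **evaluation** — ROC/AUC (equal to the Mann–Whitney pair statistic),
  Youden-J operating point, an N=100 random-label permutation control,
  per-band rank-sum statistics, and exact cohort bookkeeping.

## Worked example

```python
import numpy as np
from lungraman import classify, evaluate, preprocess, quality, synthetic_cohort as sc

instrument = sc.default_instrument()
refs = sc.synth_reference_frames(instrument)
calibration = preprocess.fit_calibration(
    preprocess.detect_calibration_peaks(refs["calibration_frame"]),
    sc.default_reference_peaks(), order=2,
    pixel_range=(0, instrument.n_pixels - 1))
certified = sc.certified_reference_shape(calibration(np.arange(instrument.n_pixels)))
response = preprocess.estimate_response(refs["broadband_reference_frame"], certified)

cohort = sc.generate_cohort(sc.CohortConfig(seed=1), instrument=instrument)
processed = []
for meas in cohort:
    spec = preprocess.preprocess_measurement(meas, calibration, response)
    spec.qf = quality.quality_factor(spec.snv_intensity)
    processed.append(spec)

split = quality.split_by_qf(processed, threshold=0.4)
print(f"retained {split.summary.n_retained}/{split.summary.n_total} "
      f"(rejected {split.summary.rejected_fraction:.0%})")

fm = classify.build_feature_matrix(split.retained)     # 860 wavenumber features
search = classify.grid_search(fm)                      # 7 x 16 (C, k) grid, LOPO AUC
preds = search.best_predictions
ok = preds.valid()
roc = evaluate.roc_auc(preds.scores[ok], preds.y[ok])
print(f"best C={search.best.C} k={search.best.k}  AUC={roc.auc:.2f}  "
      f"sens={roc.operating_point['sensitivity']:.0%} "
      f"spec={roc.operating_point['specificity']:.0%}")
```

Output (seed 1):

```
retained 130/200 (rejected 35%)
best C=2.0 k=13  AUC=1.00  sens=98% spec=97%
```

130 of 200 simulated measurements survive the quality cut (the generator
plants 33% low-SNR measurements on average; this seed drew 35%, and the QF
filter catches almost exactly those). The LOPO AUC near 1 means the
decision scores of held-out patients' cancer spectra almost always exceed
those of normal/benign spectra; the selected features concentrate in the
amide I and tyrosine bands where the generator planted the class effect.

The same workflow is available from the shell:

```sh
lungraman run --config config.yaml --seed 1 --outdir results/
```

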