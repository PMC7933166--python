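# painsignal

Semi-automated pain tracking for critically ill patients from routinely
recorded per-minute vital signs.

ICU patients who cannot communicate (sedation, intubation, tracheostomy) are
assessed for pain with observational scales such as the Critical-Care Pain
Observation Tool (CPOT, 9 levels, 0–8; a score ≥ 3 is treated as "pain
present"). These assessments happen only a few times a day, so pain between
assessments goes unseen. `painsignal` implements a machine-learning pipeline
that predicts the binary CPOT label at each assessment time from the
*fluctuation* of the vital signs over the preceding hour, together with
demographics and the sedation level (Richmond Agitation–Sedation Scale,
RASS, −5…+4) — the ingredients of a continuous, semi-automatic bedside pain
monitor. Because real ICU vital-sign datasets are access-restricted, the
package ships a seeded synthetic cohort generator with the statistical
structure the analysis assumes (≈ 3 % pain-positive assessments, assessments
every 8 h plus pain-triggered extras, sedation-dependent variability,
pain episodes that transiently raise vital-sign level and fluctuation), so
every stage is testable end to end with known ground truth.

## Method

For each CPOT assessment at time *t* and each predictor channel
(systolic/diastolic arterial pressure, pulse rate, respiratory rate; SpO2 is
recorded but never a predictor):

1. **Preprocessing** — per-minute records failing plausibility bounds, a
   maximum minute-to-minute jump, or a flatline screen are flagged invalid
   (never deleted, so the time grid is preserved).
2. **Slicing** — the 60 minutes (*t* − 60, *t*] are extracted; the window is
   used only if ≥ 90 % of its minutes are valid (54 of 60).
3. **Fluctuation integration** — rising and falling fluctuations over
   consecutive valid minute pairs:
   R = Σ max(xₜ − xₜ₋₁, 0),  F = Σ max(xₜ₋₁ − xₜ, 0);
   R + F is the window's total variation.
4. **Leveling** — to cancel between-patient differences, R and F are min–max
   normalized against the range of the 60 rolling one-hour total-variation
   integrals computed every minute during hours 1–2 after ICU admission:
   z = (v − min)/(max − min), with no clipping.
5. **Assignment** — sex, age group (20–44 / 45–64 / ≥ 65) and the latest
   RASS within 3 h are appended; the label is 1 iff CPOT ≥ 3.

Because positives are ≈ 3 % of assessments, the positive class is oversampled
*inside each training fold* with ADASYN (SMOTE and Borderline-SMOTE are also
implemented in-repo). Random forest, RBF-kernel SVM, and logistic regression
are compared by stratified 10-fold cross-validation (each fold a 9:1
train/validation split, grouped by patient so no patient straddles a split),
with grid-searched hyperparameters; default grids pin the selected optima
C = 10, γ = 10 (SVM), max_depth = 14, 17 trees, Gini (RF), C = 1.0,
tol = 10⁻⁴ (LR). Reported per-model AUROC is the mean of per-fold AUROCs;
the merged out-of-fold scores give the ROC curve, an operating-point table at
predefined sensitivity/specificity targets, and the optimal point maximizing
the harmonic mean 2·Se·Sp/(Se + Sp).

## Worked example

```bash
cat > demo.yaml <<EOF
cohort:
  n_patients: 80
n_folds: 5
EOF
painsignal run --config demo.yaml --seed 11 --out demo_out
```

prints

```
random_forest: test AUROC 0.876 (train 1.000)
svm_rbf: test AUROC 0.738 (train 1.000)
logistic_regression: test AUROC 0.945 (train 0.992)
best model: logistic_regression; artifacts in demo_out
```

Under the default pain effect size (1.0: episode minutes have doubled
minute-to-minute increments plus a transient level bump), all three models
separate pain from no-pain well above chance on held-out patients, and the
train/test gap shows the expected optimism of the training fit.
`demo_out/` then contains the cohort tables (`patients.csv`, `vitals.csv`,
`assessments.csv`, `ground_truth.csv`), the feature matrix (`dataset.csv`
plus `exclusions.json` — here 607 of 709 assessments were retained; 82
were dropped for an unusable baseline hour and 20 for windows below the 90 %
presence rule), `report.json`, and `operating_points.csv`, whose first rows
read

```
condition,sensitivity,specificity,threshold,achieved
sensitivity>=0.6,0.625,0.998,0.994,True
sensitivity>=0.7,0.708,0.997,0.959,True
sensitivity>=0.8,0.833,0.844,0.122,True
sensitivity>=0.9,0.917,0.789,0.066,True
```

i.e. at a threshold accepting ≥ 90 % of true pain events, ≈ 79 % of
pain-free assessments are still correctly identified. The same pipeline is
available as a library:

```python
from painsignal import CohortConfig, ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(cohort=CohortConfig(n_patients=80),
                                         n_folds=5), seed=11)
print(report.models["random_forest"].test_auroc)
```

`painsignal simulate`, `featurize`, and `evaluate` run the individual stages
on files, fully seeded.

## Limitations

The synthetic generator is a stand-in for restricted bedside data: it
reproduces the statistical structure the method relies on, not real
physiology (no circadian rhythm, interventions, drug kinetics, or waveform
morphology), so performance on synthetic cohorts demonstrates that the
pipeline recovers the signal it was designed for — not clinical accuracy.
The noise-removal rules are documented, overridable stand-ins for the
clinical source's non-public screens. See `docs/methods.md` for the full
model description, parameter defaults, and design decisions.
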