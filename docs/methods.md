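# Methods

This note documents the models, parameter defaults, numerical conventions,
and design decisions behind `painsignal`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The prediction problem

At each CPOT assessment time the pipeline predicts the binary pain label
(CPOT ≥ 3) from eleven features: eight leveled fluctuation integrals (four
predictor channels × rising/falling), sex (female 0 / male 1), age group
(20–44 → 0, 45–64 → 1, ≥ 65 → 2; the third band is read as "65 and older"),
and the most recent RASS within 3 hours as a signed integer. SpO2 is
simulated and preprocessed but never used as a predictor. Predictor channel
order is fixed: SBP, DBP, pulse rate, respiratory rate.

## Synthetic cohort generator

The generator emulates the data-generating process the analysis assumes and
supplies ground truth (latent pain, corruption masks) for testing.

**Vitals.** Each channel is a per-patient AR(1) deviation process around a
patient-specific mean: d_t = φ·d_{t−1} + σ_t·ε_t, x_t = μ + d_t + bump_t,
one record per minute on an integer, 0-based, admission-anchored grid shared
by all modules (half-open window conventions throughout). μ, σ, φ are drawn
per patient from plausible adult ICU ranges (e.g. pulse μ ∈ [60, 100] bpm,
σ ∈ [0.5, 2] bpm/min, φ ∈ [0.90, 0.97]). Sedation scales the innovation
s.d. by 0.7 per RASS step below 0.

**Pain episodes.** Episodes arrive as a Poisson process
(`pain_episode_rate`, default 0.098 episodes per patient-day, applied
outside a 3-hour admission settling window) with peak intensity
U(0.65, 1.0), a 5-minute ramp, a U(20, 60)-minute plateau, and exponential
decay with a 30-minute half-life. While an episode is active the channel
innovations are multiplied by (1 + `pain_effect_size`) and an additive level
bump proportional to `pain_effect_size` × latent intensity is applied
(e.g. up to 15 mmHg on SBP at effect 1). At `pain_effect_size = 0` the
vitals are therefore exactly independent of pain — the null cohorts used to
check that the pipeline does not manufacture signal.

**Assessments.** CPOT/RASS/CAM-ICU events occur every 8 h starting 4 h
after admission, plus one extra within 30 min of each episode onset (the
"obvious pain" trigger); every patient has at least five assessments.
Observed CPOT is round(8 × expressed intensity + ε), ε ~ N(0, 0.6²),
clamped to [0, 8]; expressed intensity is the latent intensity attenuated by
0.96 per sedation step (deep sedation masks pain expression). The peak-
intensity floor (0.65) and the mild default attenuation keep episode-
triggered assessments CPOT-positive with probability ≈ 1 in every sedation
stratum, which preserves the null structure: at zero effect size the labels
are independent of RASS as well as of the vitals. Stronger attenuation
(configurable) makes sedation dominate CPOT expression; the test suite uses
that regime to reproduce the qualitative finding that RASS then carries the
largest random-forest feature importance. CAM-ICU is emitted (positive
probability 0.217 when assessable, unassessable at RASS ≤ −4) but never
consumed by features.

**Calibration.** `pain_episode_rate`'s default was set once by simulation so
that the default configuration yields a fraction of CPOT ≥ 3 assessments
within one percentage point of `pain_prevalence_target` (0.033): sweeping
the rate over eight seeds at ~600–1,200 patients gave a mean prevalence of
3.2 % at 0.094 and 3.5 % at 0.100; 0.098 centres the target (per-seed range
≈ 3.0–3.8 %). Stays default to U(48, 96) h, which with the 8-hour schedule
plus pain extras gives ≈ 10 assessments per patient, matching the ratio of
the motivating study's counts (117,190 assessments / 11,527 patients).
Demographics default to 58 % male and age-band probabilities
(0.20, 0.30, 0.50), consistent with a median age of 65; the sedation mix is
42.8 % calm / 8.3 % agitated / 48.9 % sedated.

**Artifacts.** `artifact_rate` (default 0.004) of minutes are replaced by
spikes 5–50 % of the plausible span beyond the channel's physiologic bounds
(SpO2 spikes only go low — saturation cannot exceed 100 %);
`missing_rate` (default 0.01) of minutes are dropped (NaN, invalid). The
injected corruption mask is retained. The artifact default anticipates that
the jump screen flags both endpoints of the jumps a spike creates, so the
recovered invalid mask exceeds the injected mask by ≈ 2 minutes per spike;
at 0.4 % spikes the expected mask disagreement is ≈ 0.8 %, within the 1 %
the mask-agreement test allows.

**What the generator does not model:** circadian and treatment-induced
trends, drug pharmacokinetics, waveform morphology, delirium dynamics
(CAM-ICU is a label only), inter-channel physiological coupling, and
informative missingness. Passing tests therefore show the pipeline recovers
the fluctuation signal it targets under controlled conditions — not that it
attains any particular accuracy on real patients.

## Noise removal

Three screens per channel, each evaluated against the incoming validity and
unioned: plausibility bounds (defaults: pulse 20–250 bpm, SBP 30–300 mmHg,
DBP 15–200 mmHg, RR 2–60 /min, SpO2 50–100 %), a maximum credible
minute-to-minute jump (40/50/35/20/15 channel units respectively, flagging
both endpoints), and a flatline screen (≥ 5 identical consecutive values).
The clinical source's own per-variable rules are not public, so these are
standard monitor-artifact screens, explicitly non-canonical and overridable
via YAML. Evaluating all screens against the input validity (rather than
chaining) makes the operation idempotent and monotone: loosening any rule
can only shrink the invalid set. Invalidation never deletes records, so the
90 % presence rule remains computable.

## Baseline "integrated value" interpretation

The per-patient baseline is described ambiguously in prose accounts of this
procedure ("the integrated value of the amount of fluctuation from 1–2 h
after admission was calculated every minute, 60 records"). The default
reading here computes, for each minute m in [60, 120), the total-variation
integral of the trailing one-hour window ending at m — so baseline records
and evaluation-window integrals share units and scale, and min–max leveling
is dimensionally coherent. The alternative reading (per-minute absolute
differences as the 60 records) is available via
`baseline_mode="per_minute_diff"`. All 60 rolling windows must satisfy the
90 % presence rule, else the patient is excluded (`baseline_unavailable`).
A baseline range below ε = 10⁻⁹ channel units (possible only for
degenerate, e.g. constant, series) excludes the patient
(`degenerate_baseline`). Leveled values are not clipped: fluctuation beyond
the baseline range is exactly the signal of interest. Rising and falling
integrals are leveled separately per channel (8 features) rather than
pooled; pooling is not specified by the source procedure and would discard
information.

Exclusion gates are checked in a fixed order (baseline availability and
degeneracy per patient, then window availability, presence, recent RASS per
assessment) and every exclusion is logged, so dataset rows + exclusion rows
always equal the number of assessments.

## Oversampling

SMOTE, Borderline-SMOTE, and ADASYN are implemented in-repo (the comparison
oracles in the tests are brute-force k-NN audits). All generate
G = (n_maj − n_min)·β synthetic minority points as x_i + λ(x_z − x_i),
λ ~ U(0, 1), with x_z one of the k (default 5) nearest minority neighbors;
they differ in allocating G across seeds (uniform / danger-points-only with
k-NN majority fraction in [0.5, 1.0) / proportional to the normalized
majority fraction r_i). Integer allocation uses largest-remainder rounding,
so counts are exact: at β = 1 the classes balance to within one sample.
With β < 1 the G formula interpolates counts rather than pinning the
minority/majority ratio to β exactly; the balance contract is asserted at
β = 1. Neighbor search uses Euclidean distance on the features as assembled
(leveled features are roughly commensurate); `standardize=True` z-scores a
copy for the distance computation only. Edge cases: single-class input and
a lone minority point raise; ADASYN with no majority neighbors anywhere
falls back to uniform allocation; Borderline-SMOTE with no danger points
returns the input unchanged with a warning. Oversampling always happens
inside the training side of a split — resampling before splitting would
place synthetic near-copies of minority rows on both sides and inflate the
apparent AUROC.

## Evaluation design

"Ten cross-validations at a 9:1 ratio" is realized as stratified 10-fold
cross-validation: each fold is a 9:1 train/validation split; grid search
(k-fold CV on the training portion, mean AUROC as the selection metric,
since AUROC is the headline metric) and oversampling are refit inside each
training portion. A single 9:1 split with the grid search inside is exposed
as `split_and_crossvalidate`.

Two estimator decisions matter at 3 % prevalence:

* **Fold grouping.** Folds group all assessments of a patient by default
  (`split_unit="patient"`, StratifiedGroupKFold). Repeated assessments of
  one patient share demographics, RASS, and the leveling denominators, so
  assessment-level folds let a flexible model recognise the patient across
  the split; on zero-effect cohorts this inflates held-out AUROC well above
  chance, which is disqualifying for an evaluation design. The
  assessment-level split remains available via config.
* **AUROC aggregation.** Classifier scores are not comparable across folds
  (each fold fits its own model; SVM margins carry fold-specific offsets),
  so the reported AUROC is the unweighted mean of per-fold AUROCs. The
  merged out-of-fold scores are used only where a single curve over all data
  is needed: the test ROC curve, the operating-point table, and the optimal
  point. Both merged and averaged values appear in the report. With ~55
  positives in a 200-patient cohort the fold-mean null AUROC has a standard
  error near 0.05; null-recovery checks against a ±0.05 band are therefore
  ~1σ tests and can fail by hairlines at particular seeds even when the
  pipeline is sound.

ROC conventions: thresholds are the distinct scores, classification is
positive iff score ≥ threshold, ties share one vertex, the curve is anchored
at (sens 0, spec 1) and (sens 1, spec 0), and AUROC is the trapezoidal area,
identically the tie-corrected Mann–Whitney statistic. Operating points do
not interpolate: the achieved point for a target is the vertex with the
smallest sensitivity (resp. specificity) ≥ target, ties resolved toward the
other coordinate; unreachable targets report the nearest vertex, flagged.
The optimal point maximizes 2·Se·Sp/(Se+Sp), ties toward higher specificity;
a zero argument returns 0 by continuity. A three-way harmonic mean
(sensitivity, specificity, AUROC) is exposed but unused — the two-way mean
is what the operating-point analysis requires. SVM and LR are standardized
inside the training pipeline (fit on training data only); the forest
consumes raw features. Feature importances are normalized impurity
decreases from a final forest refit on the full dataset.

Determinism: a single root seed fans out via `SeedSequence` to named cohort/
resample/split streams; reports are byte-identical under a fixed config and
seed, and a run is reproducible from its persisted `run.json` alone.

## Problem sizes

Tests and the acceptance script use cohorts of 40–300 patients
(~400–2,400 assessments) and a 1,100-patient cohort (~10⁴ assessments) for
the prevalence-calibration check; these sizes give stable estimates for the
properties under test while keeping any single run under a minute. The
restricted clinical cohort that motivated the pipeline (11,527 patients) is
deliberately out of reach of the simulator's purpose: reproducing its
headline accuracies is not a goal; recovering designed-in signal, and
refusing to find signal in null data, is.

## Numerical choices

* Leveling ε = 10⁻⁹ channel units for degenerate-baseline detection.
* Shift/scale invariance of leveled features is exact in real arithmetic;
  float64 rounding of shifted or rescaled minute differences leaves
  ulp-level residue, so invariance tests assert at relative tolerance 10⁻⁹.
* Largest-remainder allocation breaks ties by index order; k-NN neighbor
  lists break distance ties by stable sort.
* RASS lookback ties on identical timestamps resolve to the latest event in
  insertion order.
* Flatline detection compares raw values for exact equality (AR(1) floats
  never tie; real monitors emit quantized repeats when frozen).
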