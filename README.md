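# locomo

Instrumented five-time sit-to-stand (FTSTS) analysis of locomotive
syndrome (LS) from a single trunk-worn inertial measurement unit.

Locomotive syndrome is the age-related decline of locomotor function that
puts older adults at risk of losing independent living. It is screened
with the GLFS-25 questionnaire (25 items graded 0–4; total score `< 7`
non-LS, `7–15` stage 1, `≥ 16` stage 2), but questionnaire staging is
subjective. An instrumented FTSTS — standing up from and sitting back
onto a 40 cm chair five times with arms folded, wearing one IMU at the
pelvis — offers a quantitative alternative: the kinematics of the
sit-to-stand transitions carry the staging signal.

`locomo` implements that analysis chain end to end, for researchers in
wearable-sensor biomechanics and digital health who want a tested,
reproducible reference pipeline:

- **`locomo.synth`** — synthetic FTSTS cohort generator (the study data
  are not public): smooth sit-stand-sit cycles with closed-form
  ground-truth transition times, class-dependent kinematics, and
  staging-consistent GLFS-25 scores for a 47/29/49/49 non-LS / stage-1 /
  stage-2 / young cohort (174 participants).
- **`locomo.preprocess`** — zero-centering, polyphase resampling to
  50 Hz, 3rd-order Butterworth low-pass at 5 Hz (zero-phase by default).
- **`locomo.segmentation`** — transition detection from the local minima
  of the gyroscope pitch angular velocity; SiSt (sit-to-stand), StSi
  (stand-to-sit), SSS (full cycle) and whole-test windows.
- **`locomo.features`** — the 144-metric feature set: 9 metric families
  (duration, max, range, RMS, peak resultant AMax, jerk, total spectral
  power, SEF50, SEF95) × 4 channels (ML, AP, SI, resultant) × 4
  contexts (FTSTS, SiSt, StSi, SSS), plus coefficient-of-variation
  supplements across repetitions.
- **`locomo.modeling`** — SMOTE class balancing, stratified 80/20 split
  (random state 42), train-fitted z-scoring, PCA or mutual-information
  feature selection, grid-searched classifiers (linear/RBF SVM, KNN,
  decision tree, random forest, gradient boosting, logistic regression)
  and a 512-256-128-64-32 ReLU funnel MLP with softmax output, L2
  regularisation, Adam and early stopping.
- **`locomo.pipeline` / `locomo` CLI** — one-command reproducible runs
  with per-stage seeds, manifests and CSV/JSON artifacts.

## The core statistics

For each acceleration channel `x` over a segment of `N` samples at rate
`f_s` (duration `T = N / f_s`):

- resultant: `res_i = sqrt(ML_i² + AP_i² + SI_i²)`
- range: `max(x) − min(x)`; RMS: `sqrt(mean(x²))`; AMax: `max(res)`
- jerk (smoothness): `(1/T) Σ_i (x_{i+1} − x_i)²`
- total power: `Σ_k |X_k|²` over the one-sided DFT, DC excluded
- SEF50 / SEF95: the smallest frequency below which 50% / 95% of the
  one-sided power lies.

Transition windows come from the pitch angular-velocity troughs: rapid
forward trunk flexion at both seat-off and seat-on produces one dominant
negative trough per transition, so trough times localise the transitions
and alternation (starting seated) labels them SiSt / StSi.

## Worked example

```sh
python examples/classify_cohort.py
```

```
cohort: 174 participants
feature table: 174 rows x 144 metrics
class counts before balancing: {'NonLS': 47, 'Stage1': 29, 'Stage2': 49, 'Young': 49}

MLP+PCA: accuracy=0.97 precision=0.97 recall=0.97 F1=0.97
        NonLS  Stage1  Stage2  Young
NonLS       8       0       0      1
Stage1      0       6       0      0
Stage2      0       0      10      0
Young       0       0       0     10
```

The cohort's stage-1 class is deliberately under-represented (29 of 174);
SMOTE raises it to the majority count (49) before training. The
confusion matrix rows are true stages, columns predictions: the synthetic
classes are built to be separable, so held-out accuracy is high, and the
residual confusion sits between kinematically adjacent groups (here
non-LS vs young). `examples/simulate_recording.py` and
`examples/segment_and_extract.py` walk the earlier stages one at a time.

The same run from the shell:

```sh
locomo run --config configs/default.yaml --out runs/demo --seed 42
```

writes `cohort.csv`, per-participant recordings, `segments.csv`,
`features.csv`, `report.json` and a `manifest.json` recording the config
hash and per-stage seeds. Individual stages are available as
`locomo synth|preprocess|segment|features|fit`.

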