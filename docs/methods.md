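# Methods

## Scope and data model

`locomo` analyses the instrumented five-time sit-to-stand test (FTSTS)
for locomotive-syndrome (LS) staging. The unit of analysis is an
`ImuRecording`: tri-axial trunk acceleration (mediolateral ML,
anterior-posterior AP, superior-inferior SI; m/s²) and tri-axial angular
velocity (deg/s) at a known sampling rate, recorded while a participant
rises from and returns to a chair five times. Older participants carry a
GLFS-25 score staged as non-LS (`< 7`), stage 1 (`7–15`) or stage 2
(`≥ 16`); young adults are a fourth, unstaged class.

## Synthetic cohort generator

No public FTSTS/LS dataset exists, so the package ships a generator that
emulates the statistical structure the analysis assumes.

Each sit-stand-sit cycle is built from a smooth pitch-angle profile: a
logistic flexion-extension ramp for the rise and its mirror for sitting
down. Pitch angular velocity is the analytic derivative — a unit-shape
pulse `−4·s(1−s)` of a logistic `s` — so every postural transition
produces exactly one dominant negative trough whose centre time is known
exactly and is recorded as a ground-truth event (seat-off at 25% of the
cycle, seat-on at 75%). AP acceleration is a biphasic
(accelerate-then-brake) pulse and SI a monophasic bump centred on the
same instants; ML is slow postural sway. White Gaussian noise models
tremor and sensor noise (accelerometer σ per group, gyroscope σ scaled
15 deg/s per m/s²). Per-cycle durations are log-normal with configured
mean and CV; a 1 s quiet lead-in/out and configurable inter-cycle pauses
complete the trace. An optional flag adds a constant gravity projection
to SI to exercise zero-centering.

Default cohort composition is 47 non-LS, 29 stage-1, 49 stage-2 and 49
young participants (174 total), keeping stage 1 the under-represented
class the balancing step exists for. Per-group kinematic defaults
(cycle means 1.5 / 1.8 / 2.4 / 3.0 s from young to stage 2, with
correspondingly decreasing pitch-velocity and acceleration peaks, and a
multiplicative 8% between-subject jitter) are **configuration choices
made to produce separable classes of plausible magnitude; they are not
measurements of any real cohort**. GLFS-25 scores are drawn uniformly
within each stage's interval, since only the cut-offs matter downstream.
All sampling flows from `numpy` seed sequences: equal seeds give
bit-identical cohorts.

What the generator does **not** emulate: validated biomechanics, sensor
orientation drift or Kalman-filtered attitude, packet loss, failed or
partial rises, and any overlap structure between classes beyond the
configured means and jitter. Passing tests therefore demonstrate the
pipeline's correctness and sensitivity on well-posed input, not clinical
accuracy on field data.

## Preprocessing

Order: zero-center → resample → low-pass. Zero-centering subtracts each
acceleration channel's whole-recording mean (gyroscope channels are rate
signals with a physically zero resting value and are left uncentred,
because shifting them would bias the trough detector). Resampling to
50 Hz uses polyphase rational resampling; the signal is padded by odd
reflection over about three anti-alias filter half-lengths and trimmed,
which suppresses the boundary transients zero-padding would leave
(verified against an analytic sine to < 1e-3 absolute). The low-pass is
a 3rd-order Butterworth at 5 Hz. It is applied forward-backward
(zero-phase) by default so that filter group delay cannot shift
transition times; `zero_phase: false` gives the literal causal
single-pass filter. Filtering precedes segmentation.

## Segmentation

Transitions are the strict local minima of the (preprocessed) pitch
angular velocity with prominence ≥ 20 deg/s and pairwise separation
≥ 0.5 s (`scipy.signal.find_peaks`). Both defaults are conservative for
self-paced FTSTS and configurable. The pitch channel is read directly as
angular rate; `differentiate: true` supports the alternative reading
(first difference of an integrated pitch angle), and a test confirms the
two agree on generator output.

Minima alternate SiSt / StSi starting from the first event (participants
start seated). Windows extend from each trough to where the
pitch-velocity magnitude falls below 10% of the trough depth
(`boundary_fraction`), capped at the midpoint to the neighbouring
trough; the published cue defines only the minima, so the boundary rule
is this package's choice. SSS windows span SiSt start to StSi end of the
same repetition; the FTSTS window spans first SiSt start to last StSi
end. Indices are 0-based half-open. An odd trailing event is dropped
with a warning; no events at all is an error naming the recording.

## Feature set

Nine metric families × 4 channels (ML, AP, SI, resultant) × 4 contexts
(FTSTS, SiSt, StSi, SSS) = 144 primary metrics. Duration and AMax (peak
resultant magnitude) do not genuinely vary by channel; they are
replicated across channels so the grid closes at 144, and a `compact`
layout (120 entries) drops the replicates. For the three repeated
contexts the reported value is the mean across the five repetitions and
the sample-SD (ddof = 1) coefficient of variation is attached as a
supplement (`cv_`-prefixed columns), not counted in the 144. A CV is
flagged undefined (None/NaN) rather than propagated when there are fewer
than two repetitions or a zero mean.

Numerical choices: jerk uses raw consecutive sample differences squared,
summed and divided by the window duration (no Δt inside the sum), so its
value is rate-dependent with units m²/s⁵ — all recordings pass through
the same 50 Hz preprocessing, which keeps it comparable across
participants. Spectral metrics use the unwindowed, unpadded one-sided
DFT with the DC bin excluded (signals are zero-centered upstream).
SEF is the smallest bin frequency at which cumulative power reaches the
requested fraction; a zero-power signal has no SEF and raises. The `max`
metric is the peak absolute value of the channel.

## Classification stack

The feature table (rows = participants, 144 columns + labels) feeds:

1. **SMOTE** to the majority count: synthetic rows are
   `x + u·(x_nn − x)`, `u ~ U(0,1)`, toward one of the k = 5 nearest
   same-class neighbours; originals are preserved verbatim. A class that
   needs growing must have more than k rows.
2. **Stratified 80/20 split**, random state 42.
3. **z-scoring** with train-set statistics (scikit-learn semantics,
   population SD); constant training columns are dropped with a warning.
4. **Dimensionality reduction**: PCA to the smallest component count
   reaching 95% cumulative explained variance (the study never states
   its component count, so the retained-variance default is flagged
   here), or SelectKBest by mutual information (train-estimated).
5. **Models**: grid-searched SVM-lin / SVM-rbf / KNN / DT / RF / GB / LR
   (5-fold CV accuracy, ties to the first grid point, folds clamped to
   the smallest class), and the funnel MLP (512-256-128-64-32, ReLU,
   softmax output, L2 = 0.001, Adam at 0.001, up to 200 epochs, batch
   64, early stopping with patience 20 on a 10% validation split),
   implemented with scikit-learn's `MLPClassifier`, whose multiclass
   loss is exactly softmax over one-hot coded targets.
6. **Evaluation**: accuracy, weighted (default; macro selectable)
   precision/recall/F1 with zero-division guarded, and the confusion
   matrix (rows true, columns predicted).

Two orderings are exposed because the published recipe is internally
inconsistent about them. The default is leak-free: split first, then
SMOTE / scaler / PCA / MI fitted on training rows only (a property test
asserts that perturbing test rows leaves every fitted transform
bit-identical). `paper_order: true` applies SMOTE to the full table
before splitting and fits PCA on the full standardized matrix,
reproducing the literal published order for comparison; z-scoring stays
train-fitted even there, since it is explicitly an anti-leakage step.
The full published hyperparameter grids are kept verbatim in
`DEFAULT_GRIDS`; routine runs and the orchestration default use the
reduced `SMALL_GRIDS` so an end-to-end run stays interactive — this is
the package's own default problem size, and the full grids remain one
argument away.

## Orchestration and reproducibility

`run_pipeline` chains synth → preprocess → segment → features → fit.
Each stage receives a SHA-256-derived child seed (< 2³¹) of the single
global seed; the manifest records the config hash, package version,
per-stage seeds and stage outputs. Reruns with the same config produce
bit-identical CSV artifacts. External recordings (CSV with header
`t,acc_ml,acc_ap,acc_si,gyr_roll,gyr_pitch,gyr_yaw` plus a
`cohort.csv` manifest) can replace the synth stage.

## Limitations

- Synthetic classes are separable by construction; reported accuracies
  characterise the pipeline, not clinical performance.
- The segment-boundary rule and the SiSt/StSi polarity assignment are
  conventions; field data with atypical movement strategies may need
  different thresholds.
- Jerk and total power are rate- and length-sensitive by definition;
  compare them only across identically preprocessed recordings.
- SMOTE interpolates in feature space and ignores feature correlations'
  clinical meaning; it balances counts, not information.
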