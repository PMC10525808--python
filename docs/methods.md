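# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the places where the design was genuinely open.

## Signal model of the synthetic cohort

Each lifting contraction is simulated as band-limited Gaussian noise:
white noise filtered by a zero-phase 4th-order Butterworth band-pass
centred on the planted centre frequency, shaped by raised-cosine on/off
ramps (10% of the burst duration per side) and rescaled to an exact
target RMS. This is the standard stationary surrogate for surface EMG:
it has no motor-unit structure, no amplitude non-stationarity within a
contraction, and no movement artifacts, so passing tests demonstrate
that the *pipeline* recovers planted spectral structure — not that it
would be robust to every artifact of real recordings.

Cohort layout (defaults) follows the study design the analysis targets:
8 subjects, two trials each (NO-RISK, RISK), 30 lifts per trial, four
channels (ER_L/R, ML_L/R) at fs = 1600 Hz, 2 s bursts separated by 4 s
of rest with ±0.2 s onset jitter, 3 s of quiet lead-in/out. Planted
condition effects:

- RISK burst RMS is `power_ratio_risk` = 1.4 times the NO-RISK RMS
  (stronger contraction under heavier load);
- the RISK centre frequency starts 6 Hz below the NO-RISK baseline and
  drifts down by `fatigue_drift_risk` = 15% from the first to the last
  lift (spectral compression under fatigue); the NO-RISK drift is 0;
- multifidus channels receive both contrasts amplified by
  `ml_contrast` = 1.25 (lumbar muscles are the more stressed in
  lifting) and sit 10 Hz above the erector-spinae baseline.

Parameters not fixed by the study design were chosen once for sEMG
realism: burst RMS 1e-4 V, which puts ROI total power at ~1e-8 V² (the
magnitude typical of back-muscle recordings); noise floor 2e-5 V so
thresholding is non-trivial; NO-RISK centre 90 Hz (ER) with a 100 Hz
noise bandwidth, placing the occupied band comfortably inside the
15–400 Hz analysis band even after the largest drift; per-subject
centre-frequency jitter SD 4 Hz and amplitude jitter CV 0.15 (log-
normal), shared between a subject's two trials so the paired structure
is preserved and leave-one-subject-out CV is genuinely harder than
pooled CV.

Every planted burst is annotated (interval, centre frequency, RMS), and
the generator is deterministic per seed via spawned `SeedSequence`
streams (one per subject trial).

## Preprocessing and segmentation

The cascade is: 8th-order Butterworth band-pass 15–400 Hz →
rectification → 4th-order Butterworth low-pass 20 Hz → Savitzky–Golay
smoothing (cubic, frame 3001 ≈ 1.88 s). "8th/4th order" are read as the
overall transfer-function orders. All filters are applied forward–
backward (zero-phase) so segment boundaries are not lag-shifted; a 1 s
reflection pad keeps the low-frequency edge transient symmetric, making
the time-reversal invariance hold to ~1e-14. The Savitzky–Golay stage
is computed by FFT convolution with the SG kernel plus scipy-equivalent
polynomial edge fitting; the direct implementation is ~10³ slower at
this frame length on 3-minute channels (tests assert equivalence to
1e-9).

Segmentation threshold: a configurable fraction (default 0.2) of the
smoothed envelope's maximum, estimated with the first and last 2 s
excluded; one threshold per channel. Runs above threshold separated by
gaps < 0.5 s are merged and runs < 0.5 s discarded.

Boundary refinement. The 1.88 s SG window smears burst edges by
~0.22 s, so the SG-trace crossings locate bursts robustly but place
their boundaries systematically outside the true contraction. Each
boundary is therefore snapped to the crossing of the *same* threshold
on the 20 Hz envelope (the SG input), requiring the envelope to stay
sub-threshold for 0.15 s so momentary dips inside a contraction are not
taken for its end. This brings worst-case boundary error on default
cohorts to ~0.1 s (well within the 0.25 s the truth-matching tests
demand) and can be disabled (`SegmentationParams(refine=False)`) to get
the raw SG crossings.

## Spectral features

The TPS of each ROI is the one-sided periodogram of the mean-removed,
rectangular-windowed raw segment with density scaling (V²/Hz), so the
integral over frequency equals the segment variance (Parseval; tests
require 1%). Features are computed on the spectrum restricted to the
15–400 Hz pass-band. Median frequency interpolates linearly within the
crossing bin of the cumulative trapezoidal area; peak ties break to the
lowest frequency; mean frequency is the plain power-weighted mean.

Kurtosis and skewness are, by default, the standardized fourth/third
moments of the *vector of TPS values* — the spectrum treated as a
sample of power readings. For a peaky EMG spectrum this yields values
in the tens, the magnitude such studies report; frequency-domain shape
moments or time-domain amplitude moments would be near 3 and 0 instead.
Both alternatives remain selectable (`moment_target="frequency"` /
`"amplitude"`) because the convention is not fixed by the feature names
alone. Kurtosis is non-excess (Pearson); skewness is the g₁ moment
estimator.

Left/right channels of one muscle are processed independently and their
feature values averaged per lift (arithmetic mean); lifts with
undefined features (zero power) become rows flagged `valid = False`
rather than errors.

## NIOSH equation

Multiplier formulas and the frequency/coupling tables follow the NIOSH
Applications Manual in metric units: HM = 25/H (H clamped to
[25, 63] cm, beyond → 0), VM = 1 − 0.003|V − 75|, DM = 0.82 + 4.5/D
(D ≥ 25, > 175 → 0), AM = 1 − 0.0032·A, FM by table lookup with linear
interpolation between tabulated frequencies (above 15/min → 0), GM from
coupling quality and origin height. The load constant is sex- and
age-banded (M: 25/20 kg under/over 45 y; F: 20/15 kg); age exactly 45
falls in the older band (conservative). A zero multiplier gives RWL 0,
an undefined (infinite) LI, and a NOT-PERMISSIBLE class; LI = 1 is
classed boundary-safe.

## Paired statistics

Pairing unit: lift i of the NO-RISK trial against lift i of the RISK
trial of the same subject, pooled over subjects (240 pairs at default
scale). The Shapiro–Wilk gate sends a comparison to the paired t-test
only when *both* samples pass at α = 0.05; constant samples fail safe
to Wilcoxon. Wilcoxon is exact for n ≤ 25 without zero differences,
normal-approximated otherwise; all-zero differences return p = 1 with a
degenerate flag. No multiple-testing correction is applied across the
14 feature tests — deliberate, matching common practice in this
literature; the per-feature p-values are reported as-is. Pooling lifts
ignores within-subject correlation, so the p-values are descriptive for
the synthetic cohort rather than strictly calibrated for clustered
data; the simulation-based type-I checks (≤ 7% at α = 0.05) cover the
pooled i.i.d. regime.

## Classifier benchmark

Fixed hyperparameters: SVM polynomial kernel
K(u,v) = (1.495·⟨u,v⟩ + 1.894)^1.882 (passed as a callable kernel since
the power is non-integer; C = 1 as the regularization constant is not
otherwise specified); kNN k = 11 Euclidean; decision tree with entropy
splits, min 2 instances per leaf, no pruning (the J48 confidence factor
is recorded but inert because pruning is off); gradient boosting with
92 rounds, depth 5, learning rate 0.832; logistic regression with the
SAG solver, 197 epochs, tolerance 0.005 (SAG derives its own step size,
so the nominal fixed step 1.886 is recorded but inert); Gaussian naive
Bayes with a 0.068 standard-deviation floor per feature (the floor
dwarfs the variance of the ~1e-8-scale power features, which is one
reason NB trails the other models — NB receives no normalization).
Min-max normalization (fit on training rows only, applied without
clipping) is used for LR, kNN and SVM exactly.

Ten-fold CV is stratified and shuffled from the run seed; its confusion
matrix and AUC pool the out-of-fold predictions/scores of all folds.
LOSO CV reports per-split metrics and their mean ± SD. AUC is the
rank-based Mann–Whitney statistic (ties 1/2), computed from
`decision_function` where available, else the positive-class
probability. NO-RISK is the positive class throughout.

## Information gain

Features are discretized with Fayyad–Irani MDL: recursive binary
splitting at the gain-maximizing midpoint, accepted while
gain > (log₂(N−1) + Δ)/N. When no cut is accepted the feature falls
back to equal-frequency 10-bin discretization so a near-zero gain can
still be measured (expected chance level ≈ 0.014 bits at n = 480);
constant features stay single-bin with IG 0. MDL cuts depend only on
the value ranks, so the ranking is invariant to monotone transformations
— and to min-max normalization in particular. The muscle share is the
summed IG of the `_ML` columns over the total.

## Fatigue trends

For each (feature ∈ {F_mean, F_median}, muscle, condition): each
subject's 30-lift series is min-max normalized to [0, 1] and its lift
ordinal mapped to [0, 1]; a single OLS line is fitted to the pooled
pairs (intercepts are then comparable across subjects and studies). The
slope's p-value is the standard t-test on the coefficient. Pooling
across subjects (rather than averaging per-subject slopes) was chosen
for power at 8 subjects; per-subject fits can be obtained by calling
`fit_trend` per group. Constant series (possible only in degenerate
configurations) are skipped with the normalization error surfaced.

## Problem sizes and determinism

Default test and acceptance runs use the full default cohort (16
recordings, ~300k samples per channel, 480 feature rows); error-rate
simulations use 100–1000 repetitions at the sizes stated in the tests.
All randomness flows from explicit integer seeds (`numpy` Generators or
scikit-learn `random_state`); identical configs reproduce every output
file byte for byte (signals serialized at 17 significant digits, result
tables at 10).

## Known limitations

- The burst model is stationary within a contraction; real sEMG is not.
- Segmentation assumes rest gaps longer than the merge threshold and a
  noise floor well below the contraction envelope.
- The statistics pool over subjects; mixed-effects modelling is out of
  scope.
- Classifier internals follow scikit-learn, not the analytics platforms
  these hyperparameter sets originate from; hyperparameters, not
  behaviour, are matched bit for bit.
- The kurtosis/skewness convention on real data cannot be verified
  without the original recordings; the default is the one consistent
  with the reported magnitudes.
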