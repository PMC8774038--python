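# Methods

This note documents the models, estimators and design choices behind
`mi_erd`, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate about real recordings.

## Data model

A **Recording** is a channels × samples matrix (µV) at a fixed sampling
rate with cue events (0-based sample onsets). The montage is the fixed
64-label 10-10 layout of the PhysioNet motor movement/imagery files, in
file order; runs 3/7/11, 4/8/12, 5/9/13 and 6/10/14 carry real hand,
imagined hand, real fists-or-feet and imagined fists-or-feet tasks
respectively, and the four studied contrasts pair those run types. Left
vs right (T1 vs T2) cues are pooled within a run type: the contrasts
classify task type, not laterality. Nine subjects with known annotation
errors (38, 88, 89, 92, 93, 94, 100, 104, 106) are excluded by default;
the list is overridable.

**Epoching** cuts one trial per cue covering `[onset − 2·fs, onset + 2·fs)`
— a half-open window whose first half is the rest baseline and whose
second half (including the onset sample) is the task window. Rest-block
(T0) annotations are not events; the baseline is always the 2 s
immediately preceding the cue. Events too close to a recording edge are
skipped and counted. Runs are concatenated (event onsets shifted by the
cumulative sample offset) before cleaning; epoching happens after.

## Cleaning

Two arms:

* **filter** — zero-phase (forward–backward) FIR band-pass, default
  1–48 Hz, Hamming window, `4·fs/low_hz` taps rounded odd (641 taps at
  160 Hz). Zero-phase filtering avoids phase distortion of the
  post-stimulus window; the squared magnitude response is flat within
  ±1 dB in the passband and > 40 dB down by 60 Hz, so 50 Hz mains is
  removed without a separate notch.
* **filter+ica** — FastICA decomposition (fixed seed) with automated
  component rejection. A component is flagged when |kurtosis| > 8
  (transient artifacts: blinks, pops) or when its frontal mixing-weight
  fraction > 0.6 **and** its sub-4 Hz power fraction > 0.7 (the ocular
  signature). Flagged components are zeroed, highest composite score
  first, at most `max_reject` (default 5), and the signal is
  reconstructed. These thresholds are deliberately conservative — they
  act only on gross artifacts — and the whole criterion set is a simple
  automated rule, not a re-implementation of any particular
  semi-automatic ICA-review workflow (which involves manual inspection
  and is out of scope). Cleaning never alters event annotations.

## ERD features

Band power is the rectangular-window periodogram integrated over bins
whose centres lie inside the band, inclusive at both edges. The 2 s,
320-sample windows give 0.5 Hz bin spacing, so the band edges (8, 13, 14,
25 Hz) fall exactly on bin centres; the bin at 13.5 Hz belongs to neither
alpha nor beta but to the joint 8–25 Hz band. The ERD value is
`(P_task − P_rest) / P_rest`, with the denominator floored at the
smallest positive float so a silent rest window cannot divide by zero.
The ratio form makes every feature invariant to rescaling a whole trial.

The periodogram estimator was chosen over time-domain band-pass filtering
for determinism and exact testability (an independent DFT bin-sum oracle
reproduces it to machine precision); a FIR variant
(`band_power(..., method="fir")`) exists as a sensitivity check but has a
broader transition band and is not the default. ERD is computed per
trial — classification needs one feature vector per trial — from that
trial's own rest window, never from a grand-average baseline.

## ReliefF + nested-subset channel selection

ReliefF weights are the standard k-nearest-hits/misses formulation
(binary labels): features are range-normalised, neighbours found by
Manhattan distance, and each sample adds the mean normalised difference
to its k nearest misses and subtracts that to its k nearest hits,
averaged over samples, giving weights in [−1, 1]. Zero-range (constant)
features contribute zero difference and get weight 0 by convention.
Default k = 10 (a common default for the algorithm), reduced
automatically when a class has fewer than k + 1 members; all samples are
used (no subsampling).

Selection ranks features by descending weight (stable ties by feature
index), forms the d nested prefixes of the ranking, scores each prefix by
stratified cross-validation accuracy with one fixed, seeded fold
assignment shared by all prefixes, and keeps the argmax — ties broken
toward the smaller subset, since fewer channels is the preferable
hardware outcome in BCI use. Hyperparameters are resolved once on the
full feature set and reused for every prefix (`retune_per_group` would
multiply the cost 64-fold for little benefit; the wrapper compares
subsets under one fixed classification procedure).

The winning accuracy (`selection_accuracy`) is a maximum over 64
data-dependent candidates and therefore optimistically biased. The
package reports it — it is the directly comparable quantity — and also
`outer_cv_selection_accuracy`, which redoes ranking, subset choice and
fitting inside each outer fold and scores only held-out trials. On
label-permuted data the outer estimate stays within binomial chance
bounds while the selection maximum may sit above them; that gap is the
selection optimism, and the test suite checks exactly this behaviour.

## Classifiers and tuning

SVM, KNN and decision tree, each wrapped in a pipeline that standardises
features with train-fold statistics (SVM and KNN are scale sensitive).
Search spaces: SVM — kernel ∈ {linear, RBF}, C log-uniform [1e−3, 1e3],
RBF γ log-uniform [1e−4, 10]; KNN — k ∈ [1, 30], metric ∈ {Euclidean,
Manhattan}; TREE — max depth ∈ [1, 20], min leaf size ∈ [1, 20]. Budget
default 30 evaluations of stratified 5-fold CV misclassification loss.

The default tuning strategy is a seeded Bayesian loop: one third of the
budget as random initialisation, then a Gaussian-process surrogate
(RBF + white kernel on parameters encoded into the unit cube, log-scaled
where the range is log-uniform) proposing the expected-improvement
maximiser among 256 seeded candidate draws per iteration. A pure seeded
random search is available as `tuning_strategy="random"` and is used in
fast tests. Both are deterministic given the seed; ties keep the earliest
evaluation, and a degenerate (constant-column) feature matrix returns the
default parameters with a warning.

Metrics come from the out-of-fold confusion counts: accuracy
`(TP+TN)/(TP+TN+FP+FN)`, sensitivity `TP/(TP+FN)`, specificity
`TN/(TN+FP)`, and AUC as the Mann–Whitney rank statistic of the decision
scores (ties counted half). Decision scores are oriented toward the
declared positive class; the evaluation harness predicts every trial
exactly once with a model not trained on it.

## Synthetic generator

Each channel is alpha rhythm + beta rhythm + broadband Gaussian noise.
A rhythm mixes a *stable carrier* — a random-phase multisine with one
equal-power component per 0.5 Hz bin inside the band, so every 2 s
window carries identical carrier band power — and a *fluctuating part* —
band-pass-filtered white noise whose 2 s band power varies from window
to window, emulating the waxing and waning of real sensorimotor rhythms.
`oscillation_stability` (default 0.95) is the stable fraction of band
power.

ERD is planted by scaling the task window of each trial's planted
(channel, band) oscillation by `sqrt(1 + erd_class)`, which makes the
expected task/rest band-power ratio `1 + erd` by construction. Because
the per-trial feature is a ratio with a stochastic denominator, there is
a small Jensen bias (≈ +1% at the default stability); the default was set
by the rule "smallest stability whose bias plus 2.5 standard errors at
100 trials stays within ±0.05 of zero under the null", keeping the null
mean-ERD check meaningful while retaining ~13% trial-to-trial band-power
variability. A fully deterministic oscillation (stability 1.0) makes
single planted channels separate perfectly and the wrapper's accuracy
curve saturate at subset size 1, which is both unrealistic and
uninformative for selection tests.

Defaults emulate the real recordings' structure: 64 channels (10-10
montage prefix for smaller counts), 160 Hz, 2 s rest + 2 s task per trial
with a 1 s inter-trial gap, unit-RMS band rhythms, broadband noise at
σ = 0.5 (in-band dilution ≈ 2%, so a planted −0.5 measures ≈ −0.48).
Optional artifacts: raised-cosine blink pulses (0.3–0.5 s) at Poisson
times with a frontal spatial profile, and a common 50 Hz line sinusoid.
Optional nearest-neighbour channel mixing (leakage weight, default off)
stresses channel selection; there is no volume-conduction or forward head
model, no 1/f background and no inter-subject variability — so passing
tests demonstrate that the *pipeline* recovers planted effects of
realistic size, not that real-data accuracies will match.

The generator can write its recordings as 16-bit EDF+C files with cue
annotations in the PhysioNet naming dialect (`SxxxRyy.edf`, T1/T2 texts),
which is how the EDF reader is tested end-to-end. The writer rounds the
physical range to the header's stored precision so a round trip is exact
up to 16-bit quantisation, and event onsets round-trip exactly.

## Numerical and degenerate-input choices

* Sample indexing is 0-based everywhere; epoch windows are half-open.
* `erd_value` floors the denominator at the smallest positive float.
* ReliefF neighbour searches break distance ties by sample index (stable
  sort), making rankings fully deterministic.
* Argmax over the accuracy curve takes the first maximum, i.e. the
  smallest subset.
* The EDF writer requires an integer sampling rate (1 s records) and
  clips to the 16-bit digital range.
* FastICA failures on rank-deficient data surface as an input error
  advising channel pruning; `max_reject = 0` is an exact no-op.

## Problem sizes in the test suite

The suite exercises the recovery and power properties at 80–100 trials
per class, 64 channels, 20 generator seeds for the recovery rate and 5
for directional comparisons — sizes at which the planted effects are
comfortably detectable and a full run stays fast on a single CPU. The
acceptance script uses the same sizes.

## Known limitations

* The ICA rejection rule targets blinks and gross transients only; it
  does not model muscle, cardiac or channel-specific noise, and its
  thresholds were not validated against expert component labelling.
* The PhysioNet pathway (reading, pooling across subjects, per-subject
  accuracies) is implemented and tested against generated EDF files, but
  the published group-level accuracies require the actual 100-subject
  download and are not reproduced here.
* Only binary contrasts are supported; multi-class extensions (and CSP or
  time-course ERD/ERS analyses) are out of scope.
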