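# Methods

## Pipeline model

The analysis classifies 30 Hz smartphone motion data into nine activity
classes (C1–C9: slow/normal/brisk walking, jogging, sitting, and
normal/brisk up- and downstairs). Thirteen raw activity codes (A1–A13)
map onto these classes: prescribed treadmill activities A1–A4 share
classes C1–C4 with their self-paced counterparts A10–A13; A5–A9 map
one-to-one onto C5–C9. Recording files are comma-separated with an
explicit header `t,ax,ay,az,gx,gy,gz` (timestamps stored rather than
inferred from row index, so dropout gaps are detectable; a gap larger
than two sample periods logs a warning). Recording ends are trimmed —
default 2 s from each end, configurable — to emulate the removal of
device-handling artifacts; the analysis itself does not depend on the
trim length.

## Features

Windows are full-length only, offset by `size × (1 − overlap)` samples
(50% overlap throughout, i.e. a 1 s step for the default 2 s window);
trailing partial windows are dropped, and windows never span recording
boundaries. Per window the features are means, sample standard
deviations (ddof = 1, matching the convention of the classic
machine-learning toolkits), the acceleration-magnitude sum, and the
magnitudes of DFT coefficients k = 1…5 of each acceleration axis.

Two points here were genuinely open and are fixed as follows:

* **DC handling.** "First five coefficients" is read as indices 1–5
  with the DC term excluded, because the window mean is already a
  separate feature and |X_0| = N·mean would duplicate it. An
  `include_dc` flag switches to indices 0–4.
* **No taper/detrend.** No windowing taper, detrending, or
  zero-padding is applied before the FFT; the analysis being
  re-implemented used none.

## Classifier

kNN is implemented from scratch (it is the point of the package, not a
wrapped library call): squared Euclidean distance on range-normalized
features, k = 1 by default, mirroring the documented defaults of the
instance-based learner in the toolkit era this analysis comes from.
Deterministic tie rules replace the unspecified ones: equidistant
neighbors prefer the lower training-row index (a stable sort makes
this automatic), tied votes prefer the class earliest in C1…C9 order.
Zero-range features map to 0 under normalization and so contribute
nothing to distances; out-of-range query values are deliberately not
clipped. Distances are rounded at 1e−12 before comparison so that
exact geometric ties survive floating-point summation order.

Gaussian naive Bayes (internal baseline only) floors per-class
variances at 1e−9 × (feature range)² to tolerate constant synthetic
features, and smooths class priors by adding one pseudo-count.

## Evaluation protocol

Stratified 10-fold cross-validation: within each class, indices are
shuffled by a seeded generator and dealt round-robin, so per-class fold
counts differ by at most one and the assignment is reproducible.
Windows are pooled across participants (windows from one participant
can appear in both training and test folds) — this mirrors the
protocol being reproduced; a `by_participant` grouping mode provides
the leakage-aware alternative that protocol did not run, and a
`normalizer_scope="global"` option exists purely as a leakage
diagnostic. The range normalizer is fitted per fold on training rows
only. Report tables round half-up to one decimal. The paired sensor
ablation evaluates both feature sets on the identical window set and
identical fold assignment, so accuracy deltas are attributable to the
gyroscope columns alone.

## Synthetic data generator

Each cyclic class is a per-axis sum of sinusoids at a class-specific
stride cadence plus harmonics 2–3 (amplitude fractions 0.5/0.25),
with independent white Gaussian noise per channel and sample; sitting
is noise only (SD 0.01 g / 0.02 rad/s). Default cadences are 1.4, 1.9,
2.3, 2.7 Hz for slow walk through jog and 1.6/2.0 Hz for normal/brisk
stairs — plausible stride rates, strictly ordered by pace, all far
below the 15 Hz Nyquist limit. Acceleration amplitudes (0.1–0.7 g)
rise with intensity, so acceleration-magnitude RMS orders
sitting < slow < normal < brisk walking < jogging. Channel noise
defaults to 0.04 g / 0.08 rad/s, chosen once as a plausible sensor
noise floor that leaves adjacent speed classes partially overlapping
through the 0.8–1.2 subject amplitude/cadence multipliers.

The structural choice that carries the ablation experiment: each
up/down stair pair (C6/C7 and C8/C9) shares *identical* acceleration
parameters (including a small extra vertical amplitude) and sits close
in cadence and amplitude to a level-walking class, while its
rotation-rate amplitude vector is distinctive (dominant axis differs
between ascending and descending). Accelerometer-only features
therefore cannot separate up from down stairs (≈50% on those pairs)
and confuse stairs with level walking, while the gyroscope recovers
them — reproducing, by construction, the direction of the published
sensor ablation.

Subject variability is a per-subject amplitude multiplier, cadence
multiplier (both uniform on 0.8–1.2) and per-axis phase offsets. The
armband placement used for jogging is a fixed axis permutation plus a
1.1× rescale. Per-recording noise streams derive from the master seed
via `SeedSequence(seed, spawn_key=(1, subject, class, repeat))`, so any
recording regenerates in isolation and generation order is immaterial.

What the generator does **not** emulate: biomechanical gait dynamics
(impact transients, asymmetry), orientation drift, sensor bias or
quantization, activity transitions, or any calibration to the original
recordings — no raw-signal statistics from them are available.
Consequently, passing synthetic tests demonstrates the correctness and
the qualitative behavior of the pipeline (separability limits, the
sign and mechanism of the gyroscope effect), not real-world accuracy
figures. With pooled cross-validation and same-subject windows in the
training folds, kNN on the default synthetic collection is nearly
saturated (≈100%); the published real-data accuracies (87.7–90.2%
across window sizes) are not a synthetic target.

## Problem sizes and determinism

The default synthetic collection is 16 subjects × 9 classes × 60 s at
30 Hz (144 recordings, ≈8 500 two-second windows) — a deliberately
compact stand-in for the original multi-minute recordings that keeps
the full evaluation, window-size comparison and ablation runs in the
tens of seconds while leaving every window size in the 1–10 s
comparison well populated. All randomness (generator noise, subject
profiles, fold shuffles) flows from explicit seeds; identical
configuration and seed give byte-identical reports, and every
experiment writes a run manifest (config hash, seed, package version)
sufficient to reproduce it.

## Known limitations

* Pooled cross-validation overstates accuracy relative to
  subject-held-out evaluation; the `by_participant` mode exists to
  quantify that gap but is not the default protocol.
* The published reference matrix has two internal one-off
  inconsistencies (its printed C1 accuracy of 94.1% vs the 94.2% its
  own row implies; a printed misclassification total of 274 vs an
  off-diagonal sum of 275). The package always reports what the matrix
  itself implies.
* The synthetic window-size comparison shows its own ordering (longer
  windows lose the low-frequency DFT bins that cover gait cadences and
  have fewer windows to train on); it is not expected to reproduce the
  published 1/2/5/10 s ranking.
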