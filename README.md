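# imuact

Activity classification from smartphone inertial sensors.

Smartphones carry a 3-axis accelerometer (user acceleration, in g, with
gravity removed) and a 3-axis gyroscope (rotation rate, rad/s). Sampled
at 30 Hz while the phone rides in a pocket or armband, these six
channels are enough to tell apart nine classes of everyday movement —
slow/normal/brisk walking, jogging, sitting, and walking up or down
stairs at normal or brisk pace — which matters for mobile-health
research because activity *intensity* (normal vs brisk walking, walking
vs jogging) determines metabolic load. `imuact` is a complete, tested
re-implementation of this classification analysis for researchers who
want to reproduce it, stress-test it, or extend it without access to
the original recordings.

## Method

1. **Windowing.** Each recording is cut into sliding windows (default
   2 s = 60 samples, 50% overlap; 1/5/10 s supported for comparison).
2. **Features.** Per window: mean and sample standard deviation of each
   acceleration axis, each rotation-rate axis, and the acceleration
   magnitude √(Ax²+Ay²+Az²); the sum of the acceleration magnitude;
   and |X_k| for k = 1…5 of the DFT of each acceleration axis
   (X_k = Σ_t x_t e^(−2πi k t/N)). 30 features with both sensors, 24
   with the accelerometer alone.
3. **Classifier.** k-nearest neighbor (default k = 1) with Euclidean
   distance on range-normalized features, (x − min)/(max − min), the
   normalizer fitted on training rows only. A Gaussian naive-Bayes
   baseline is included for comparison.
4. **Evaluation.** Stratified 10-fold cross-validation accumulated into
   a 9×9 confusion matrix; per-class recall (diag/row), weighted
   average accuracy (trace/total), error tallies, window-size and
   gyroscope-ablation comparisons.

Because the original 16-participant recordings are an external dataset,
the package ships a synthetic 6-axis gait generator whose nine class
specs reproduce the statistical structure the analysis relies on
(cadence and amplitude ordered by intensity, stair classes separable
from level walking only through the gyroscope), plus the published
confusion matrix and sensor-ablation table as packaged fixtures for the
metric arithmetic.

## Worked example

```python
>>> import imuact
>>> report = imuact.replay_reference()   # packaged published confusion matrix
>>> print(report.to_text())
Activity                  Accuracy
C1. Slow walking          94.2%
C2. Normal walking        92.0%
C3. Brisk walking         90.1%
C4. Jogging               91.7%
C5. Sitting               100.0%
C6. Normal upstairs       69.8%
C7. Normal downstairs     79.4%
C8. Brisk upstairs        70.4%
C9. Brisk downstairs      52.3%
Weighted average          90.2%

Confusion tallies: walking_speed=101, stair_vs_level=103, brisk_walk_vs_jog=57
```

Reading: sitting is recognized perfectly, level-ground walking at
90–94%, stair walking is hardest (52–79%). Of the misclassified
windows, 101 are confusions among walking speeds, 103 between stair
and level walking, 57 between brisk walking and jogging.

The same pipeline end-to-end on synthetic data:

```python
>>> from imuact import ExperimentConfig, run_sensor_ablation
>>> table = run_sensor_ablation(ExperimentConfig(out_dir="out", seed=3))
>>> print(table.tail(1).to_string(index=False))
           class  accel_only_pct  accel_gyro_pct  delta_pct
weighted_average            75.3           100.0       24.7
```

Without the gyroscope, up- and downstairs walking collapse onto each
other and onto level walking (the stair classes drop to ~46%); adding
rotation-rate features recovers them — the same direction of effect as
the published ablation (+6.5% overall).

A CLI mirrors the library: `imuact generate | featurize | train |
evaluate | windows | ablate | replay-fixture`, each driven by a YAML
config plus overrides.

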