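# signkin

Sign-language recognition from depth-sensor hand skeletons: a kinematic
feature model of the forearm/hand/fingers, time-series augmentation by
window and magnitude warping, a zoo of sequence classifiers, and a
user-independent nested cross-validation harness — plus a synthetic
skeleton-cohort generator that doubles as a forward-kinematics test
oracle.

## Who this is for

Researchers in human activity recognition / gesture classification who
work with per-frame 3-D landmark trajectories (LeapMotion-style skeletal
tracking: fingertips `EF1..EF5`, knuckle rows `M/P/D`, elbow `EL`, wrist
`WR`, styloids `RS`/`US`, palm centre `PALM`, 25 named landmarks per
hand) and who care about evaluation that generalises to *new* subjects
rather than memorising the ones in the training set.

## The model

Per frame and per hand, 30 scalar features (60 for both hands):

* **d₁..d₄** — Euclidean distances between successive fingertips, and
  **d₅..d₉** — fingertip-to-palm distances (mm);
* **wrist flexion/extension, radial/ulnar deviation** — an intrinsic
  **Z–X–Y** Euler decomposition of the hand frame relative to the
  forearm frame (the Y/pronation angle is discarded).  The hand frame
  takes Z along (M₂−M₅), X normal to the plane of (M₂−RS) and (P₅−RS),
  Y = Z×X; the forearm frame takes Y along (EL−US),
  X = Y×(RS−US) normalised, Z = X×Y;
* **α₁..α₅, φ₁..φ₅** — signed projection angles of each digit's
  proximal segment in the hand XY and YZ planes (planes swapped for the
  thumb);
* **β₂..β₅, θ₁..θ₅** — interphalangeal link angles in [0°, 180°].

Every sign is cubic-spline resampled to **m = 100** frames and
standardised per feature *group* (fingertip distances, palm distances,
hand–forearm angles, digit orientation, digit links):
`f ← (f − μ_g)/σ_g`.  Training matrices can be augmented 40× by slicing
the 100 frames into 10 parts, warping each part to a random length in
{5..15} and resampling back (window warping), then adding a random
sinusoid scaled by 0.2× the column range (magnitude warping).

Classifiers: k-NN (k = 10), random forest (1000 trees, depth 5), linear
SVM on flattened 6000-vectors; and four neural architectures (MLP
256/512/1024, a 4-layer time-axis ConvNet, a 4-layer LSTM RNN, and
DeepConvLSTM = 4 conv layers → 2 LSTM layers → softmax) trained with
Adam (η = 0.001, staircase ×0.9 every 5 epochs), mini-batches of 500,
dropout keep-probability 0.8, and early stopping on validation
accuracy.  The networks are implemented in pure numpy with analytic
backpropagation (verified against finite differences in the test
suite).

Evaluation is **user-independent nested k-fold CV**: outer loops rotate
a held-out test group of subjects (each subject tested exactly once);
inner folds rotate the remaining subjects between training and
validation; the K fold models vote on the test subjects (ties broken by
mean softmax probability).  A contrasting `holdout_eval` (stratified
80/20 splits ignoring subject identity) demonstrates how much accuracy
such evaluation inflates when subjects are identifiable.

## Worked example

```python
import numpy as np
import signkin as sk

# 6 subjects x 4 sign classes x 8 repetitions, with subject-specific
# signatures planted on top of a modest class signal
spec = sk.CohortSpec(n_subjects=6, n_classes=4, repetitions_per_class=8,
                     class_separation=5.0, subject_variability=6.0,
                     subject_confound=10.0, noise_sd=0.5, seed=7)
cohort = sk.build_subject_datasets(sk.generate_cohort(spec))

report = sk.run_nested_cv(cohort, "knn", test_group_size=2, K=2, seed=1)
print(f"user-independent: {report.mean_accuracy:.3f} ({report.sd_accuracy:.3f})")

held = sk.holdout_eval(cohort, "knn", repeats=10, seed=1)
print(f"pooled holdout:   {np.mean(held):.3f} ({np.std(held):.3f})")
```

prints

```
user-independent: 0.729 (0.130)
pooled holdout:   0.818 (0.118)
```

The nested, user-independent estimate is the honest one; the pooled
holdout estimate is inflated because every subject contributes samples
to both sides of the split, so the model partly recognises *who* is
signing instead of *what* is signed.

The same pipeline is scriptable from the shell:

```bash
signkin simulate --subjects 10 --classes 8 --reps 10 --seed 0 --out cohort.csv
signkin validate cohort.csv
signkin evaluate cohort.csv --model deepconvlstm-small --test-size 5 --k 5
signkin holdout cohort.csv --model knn
```

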