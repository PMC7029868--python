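# Methods

## The kinematic feature model

Each hand contributes 30 per-frame features computed from 25 named
landmarks (fingertips `EF`, knuckle rows `M`/`P`/`D` per digit, elbow
`EL`, wrist `WR`, radial/ulnar styloids `RS`/`US`, palm centre `PALM`),
all in millimetres in the sensor frame.

**Coordinate frames.**  The hand frame takes Z along (M2 − M5), a
provisional X normal to the plane spanned by (M2 − RS) and (P5 − RS),
then Y = Z × X and X re-derived as Y × Z so the returned triad is
orthonormal and right-handed to machine precision even when the raw
landmarks are slightly inconsistent.  The forearm frame takes Y along
(EL − US), X = Y × (RS − US) normalised, Z = X × Y (exactly orthonormal
by construction).  Degenerate constructions (coincident defining
points, zero-length axes, norms below 1e−12) raise a singular-geometry
error carrying the offending frame index.

**Wrist angles.**  The relative rotation `R_forearm^T · R_hand` is
decomposed as intrinsic Z–X–Y Euler angles (scipy's `Rotation`); the Z
angle is flexion/extension, the X angle radial/ulnar deviation
(restricted to [−90°, 90°]), and the Y angle is discarded.  At gimbal
lock (|X angle| within 1e−6 of 90°) the decomposition sets the
discarded Y angle to zero and the result is flagged rather than
rejected.

**Digit angles.**  For fingers i = 2–5 the proximal segment (Mi − Pi)
is expressed in hand coordinates; α_i is the signed angle of its XY
projection from +Y toward +X, φ_i the signed angle of its YZ projection
from +Y toward +Z (`atan2` convention, (−180°, 180°]).  The thumb uses
(M1 − D1) with the planes swapped (α₁ from YZ, φ₁ from XY).  The
projection-plane swap for the thumb is implemented exactly as the
feature catalogue defines it.  A vanishing projection (segment normal
to the plane) returns 0 with a degeneracy flag instead of erroring, so
one sensor dropout does not invalidate a whole sequence.  Link angles
β, θ are unsigned interior angles computed as `atan2(|u×v|, u·v)`,
which is numerically stable near 0° and 180° where the arccos form
loses precision.

Because every feature is a relative distance or angle, a global rigid
motion leaves the whole feature vector unchanged (tested at 1e−9) and a
uniform scaling scales only the nine distances.

**Sign conventions.**  Projected angles are signed; the magnitude-only
alternative would discard the abduction direction.  The left hand uses
the identical construction (no mirroring): left/right features live in
separate columns, so the anatomical mirroring of the left hand is
absorbed by the classifier.

## Preprocessing

Sequences are resampled to 100 frames by a cubic spline over normalised
time [0, 1] (uniform input spacing, or normalised timestamps when
present), evaluated at 100 uniform points with the endpoints preserved
exactly.  The boundary condition is **not-a-knot** (scipy's default):
it reproduces polynomials up to cubic exactly, which gives the
resampler a sharp correctness oracle; a natural spline would flatten
curvature at the sequence ends.

Standardisation is per feature *group* — fingertip distances, palm
distances, hand–forearm angles, digit orientation, digit links — so
that the five physically distinct families are each brought to unit
scale without letting a wide-range family dominate.  The default scope
is **training-set mode**: group moments are pooled over the training
subjects of the current fold only and applied unchanged to validation
and test data, so no held-out statistics leak into the model.  A
per-instance mode (each matrix standardised by its own moments) is
available for self-contained pipelines.  Near-constant groups floor σ
at 1e−8 with a warning.

## Augmentation

One pass = window warp then magnitude warp, repeated 40 times per
training sample:

* *Window warp* — the 100 frames are cut into 10 contiguous parts; each
  part is spline-resampled to a random integer length in {5..15}
  (inclusive uniform); the concatenation is resampled back to 100.  The
  part-length draws are shared across all 60 columns of a sample:
  warping columns independently would destroy the temporal synchrony
  between joints that makes a sign a sign.
* *Magnitude warp* — per column independently, a sinusoid with period
  uniform in [0.5, 2] window-lengths, phase in [0, π] and amplitude A in
  [−0.2, 0.2] is scaled by the column's value range and added.  The
  distortion is therefore bounded by 0.2 × range, a "slight" smooth
  amplitude change rather than a new movement.

Augmentation applies to training samples only; matrices tagged with a
validation/test role are refused with a leakage error.  In training-set
standardisation the warps are applied before standardisation and the
fold statistics are fitted on the augmented training collection.

## Classifiers

Classical baselines consume flattened 6000-vectors: k-NN with k = 10
(capped at the training-set size for very small folds), random forest
with 1000 trees of depth 5, and a linear-kernel SVM.  A chance-level
`constant` stub (most-frequent-class) is registered for calibration
tests.

The neural architectures — MLP (6000→256→512→1024 sigmoid→softmax),
ConvNet (4 time-axis conv layers, 16/16/32/64 channels, kernels
20/20/10/5 × 1, strides 1/2/2/2, ReLU, then dense 128 tanh), a 4-layer
LSTM RNN (256 units), and DeepConvLSTM (the conv stack feeding 2 LSTM
layers, last time step → softmax) — run on a small numpy engine with
analytic backpropagation, verified against central finite differences.
Design points:

* Kernels slide along the time axis only (1-wide in the feature axis)
  and no pooling is used; "same" padding keeps the four stride-2 stages
  at 100→50→25→13 time steps, leaving a usable sequence for the LSTMs.
* Dropout is inverted dropout at keep probability 0.8 on every hidden
  layer, training time only.
* Training minimises softmax cross-entropy with Adam (default moments),
  learning rate 0.001 with a staircase ×0.9 decay every 5 epochs,
  mini-batches of 500 (capped at the training-set size).
* Early stopping watches validation accuracy with patience 5 and
  restores the best-epoch parameters; a raw "stop at first decrease"
  rule is noise-dominated.  Training metrics in the history are
  accumulated from the mini-batch passes (dropout active), which avoids
  an extra full forward pass per epoch.
* Initialisation is seeded Glorot-uniform; LSTM forget-gate biases
  start at 1.  Parameters and activations are float32 by default
  (float64 available via the `dtype` parameter); runs are bit-wise
  reproducible given a seed.

A reduced registry entry `deepconvlstm-small` (channels 8/8/16/32,
64-unit LSTMs, mini-batch 64, learning rate 2e−3, ≤ 30 epochs) exists
for desk-scale experiments where the full model would be gratuitous.

## Evaluation protocol

`make_nested_splits` assigns subjects to outer test groups by a seeded
random partition (each subject tested exactly once) and, per outer
loop, rotates the remaining subjects through K inner folds whose
validation sets partition them.  `run_nested_cv` trains one model per
inner fold — fresh seeded initialisation each time, fold statistics
fitted on that fold's training samples only — and ensembles the K
models on the test subjects by majority vote.  Vote ties (2–2 or
1–1–1–1) are broken by the highest mean softmax probability among the
tied labels: deterministic, and it uses the only extra evidence
available.  Per-loop accuracy is micro accuracy over all test samples
of the loop; the report carries per-loop accuracies, their mean and SD,
mean best-validation accuracy over all inner folds, and a pooled
row-normalised confusion matrix.

`holdout_eval` is the deliberately naive contrast: stratified 80/20
splits of the pooled samples, repeated 10 times, ignoring subject
identity.  On cohorts where subject identity is informative it
overestimates accuracy relative to the nested protocol — the
demonstration the harness exists to make.  Hyperparameter search is out
of scope: all hyperparameters are fixed at the documented values and
every outer loop is treated uniformly.

## Synthetic cohorts and the forward-kinematics oracle

The generator emulates what a depth sensor records during signing:
26 smooth scalar channels per hand (wrist flexion/deviation, digit
projection and link angles, a rigid global forearm motion as rotation
vector + translation), each a sum of ≤ 3 sinusoids.  Class identity
lives in template coefficients (a cohort-wide base template plus
class-specific deltas scaled by `class_separation`, in degrees);
subject identity in per-subject offset/amplitude/phase perturbations
(`subject_variability`, degrees) and a per-subject bone-length scale;
repetition-to-repetition jitter is 0.3× the subject scale and is drawn
per (subject, repetition) *shared across classes*, so a cohort with
zero separation, variability and noise carries no class signal at all.
Confound offsets are always drawn and scaled by `subject_confound`,
so cohorts generated from one seed with different confound magnitudes
differ only by the planted offsets.  Landmark noise is Gaussian in
millimetre space, mimicking sensor error, not angle-space noise.

Forward kinematics is constructed so the extractor recovers the
generating angles exactly at zero noise: the forearm triad realises its
frame directly; knuckles and palm sit in the hand frame's YZ plane; the
wrist rotation is applied as Rz(flexion)·Rx(deviation) with zero
pronation; digit chains are built from the projection angles and bent
by exact axis-angle rotations realising β and θ.  One structural
constraint follows: the pinky's in-plane angle α₅ is held at 0 so that
P5 — which participates in the hand-frame construction — stays in the
palm plane for any wrist pose.  The pinky still moves through φ₅, β₅
and θ₅.  Default study conditions are 10 subjects × 8 classes × 10
repetitions, raw lengths 60–140 frames, separation 12°, variability 3°,
noise 0.5 mm — a strongly separable cohort small enough for single-CPU
experiments.

**What the generator does not emulate:** sensor dropouts and occlusion
artefacts, self-contact and anatomical joint-limit coupling, the
heavy-tailed temporal structure of real signing, or mirrored left-hand
anatomy.  Tests passing on these cohorts therefore validate the
*machinery* (formulas, protocol, leakage guards), not recognition
accuracy on real sign language.

## Scaled-down experiment sizes

The end-to-end acceptance experiment runs the default cohort
(10 × 8 × 10) with `deepconvlstm-small`: test groups of 5 subjects give
2 outer loops, and the 5 remaining subjects force K = 5 inner folds
(4 train / 1 validation subject), since K must partition the non-test
subjects.  The leakage demonstration uses 8 subjects × 5 classes ×
8 repetitions with a 20° planted confound over a 6° class signal and
k-NN as the probe model (maximally sensitive to identity leakage, and
cheap).  Larger cohorts change none of the code paths, only the wall
time.

## Known limitations

* The raw-archive format of public LeapMotion datasets is not parsed;
  the package defines its own documented CSV/JSONL dialect and an
  adapter would be separate work.
* The numpy engine is CPU-only and single-threaded beyond BLAS; it is
  sized for method studies, not production training.
* Wrist-angle sign conventions for the left hand follow the right-hand
  construction rather than mirrored anatomical conventions; this is a
  column-consistent relabelling, irrelevant to classification but
  relevant if the features are interpreted clinically.
* Automatic sign segmentation from continuous capture is out of scope;
  sequences are assumed pre-segmented.
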