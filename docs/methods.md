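# Methods

## Signal model of the synthetic generator

Each trial is the 2 s grasp-and-lift phase of one (subject, grasp,
position, repetition) cell; reach and return phases are not generated
because only the grasp phase is analysed. The design is 5 grasps × 9
positions × `n_reps` repetitions per subject (default 5 → 225 trials),
six EMG channels at 1024 Hz and six IMU channels at 60 Hz.

EMG per channel is an AR(2)-filtered Gaussian process, normalised to unit
process variance and then scaled:

    emg = A(g, ch) · (1 + position_effect · δ(p, ch)) · AR2(g, ch) + ε

* `A(g, ch) = 0.1 · (1 + class_separation · amp[g, ch])` encodes grasp
  identity in amplitude (drives MAV, WL, RMS);
* the AR(2) pole radius and angle move away from a shared base point
  (r = 0.55, θ = 0.3π) proportionally to `class_separation`, encoding
  grasp identity in spectral shape (drives ZC, SSC, AR coefficients).
  Both channels of information exist because the feature set contains
  both amplitude and spectral-shape features; amplitude alone would make
  the AR features uninformative;
* `δ(p, ch)` is a per-subject standard-normal draw: a multiplicative
  channel gain is the simplest mechanism consistent with muscles
  modulating contractile strength across limb positions, and produces the
  characteristic per-position drift of class centres in raw feature
  space;
* `ε` is white noise with `noise_sd` (default 0.01 a.u.).

The fixed `amp`/pole-offset signature tables are generator design
constants (drawn once from a hard-coded stream), so grasp identities are
stable across dataset seeds. The accelerometer reads the unit gravity
vector rotated by the position's azimuth (−45°/0°/+45° for position
groups P1–P3/P4–P6/P7–P9) and a distance-dependent tilt (10°/20°/30° for
near/mid/far); the gyroscope is zero-mean noise whose variance grows with
reach distance. Both make the IMU channels position-informative, mirroring
sensor fusion in limb-position-robust myoelectric control.

Per-trial RNG substreams are derived from the counter
(seed, subject, grasp, position, rep), so generation is order-independent
and bit-reproducible.

**Calibration.** `class_separation = 1.0` and `position_effect = 0.25`
were fixed once so that the separability index of the normalised 66-D raw
features over all positions lands in the mid-single digits (≈ 7 for the
default design) — overlapping but structured clusters, the regime in
which projection choice matters. These defaults are study conditions, not
tuning knobs.

**What the generator does not emulate:** motor-unit physiology,
electrode-shift or fatigue nonstationarity, inter-channel crosstalk,
movement transients, and real inter-subject variability. Passing tests
demonstrate correctness of the pipeline's mathematics and the qualitative
mechanisms (cluster drift, supervised-projection advantage), not
performance levels on real recordings.

## Preprocessing

Zero-phase (forward-backward) filtering is used throughout so features are
not phase-shifted relative to labels: 5th-order Butterworth band-pass
20–450 Hz, then a 2nd-order IIR notch at 50 Hz with Q = 30 (≈ 1.7 Hz
bandwidth). IMU channels are smoothed with a centred 5-sample moving
average (≈ 83 ms at 60 Hz) whose window shrinks symmetrically at the
edges. Sampling rates below 900 Hz are rejected (the 450 Hz edge must sit
below Nyquist).

Window and step lengths in samples are `round(t · rate)`: at 1024 Hz a
150 ms window is N = 154 samples advanced by 51; at 60 Hz M = 9 advanced
by 3. Nearest-sample rounding keeps the EMG and IMU spans aligned to
< 1 ms. Windows are emitted while they fit inside both streams — 38 per
2 s trial. Filtering is applied once per recording before segmentation,
so window contents are independent of segmentation order.

## Features and normalisation

The 66-D vector is, in fixed column order, per EMG channel
{MAV, ZC, WL, SSC, a₁…a₆} and then the six IMU RMS values. ZC and SSC use
strict inequalities and no amplitude deadband; WL is the plain sum of
absolute first differences. AR(6) coefficients follow the standard
convention u_i = Σ_p a_p u_{i−p} + ε_i and are estimated by Burg's method,
chosen for stability on 154-sample windows; a constant window is
degenerate and its AR features are set to 0 during extraction.

Normalisation maps each feature by x ↦ 2(x − min)/(max − min) − 1 using
training-fold statistics only. Test values are not clipped, so they may
leave [−1, 1]; a constant training feature maps to 0.

## Projections

All four project to k = 4 = c − 1 dimensions.

* **PCA** centres by the training mean and projects on the top-k
  covariance eigenvectors (exact SVD).
* **LDA** solves the symmetric-definite generalised eigenproblem
  S_b v = λ S_w v and projects on the top-k eigenvectors; S_w receives a
  ridge of 1e−9 · trace(S_w)/m on the diagonal to survive degenerate
  inputs.
* **SRELM**: hidden parameters (aᵢ, bᵢ) ~ U(−1, 1) from a stored seed;
  activation g(d) = 1/(1 + e^d) — the mirrored logistic, equivalent in
  function class because the parameter draws are sign-symmetric; responses
  Z are an orthonormal basis of the class-indicator span with the
  constant direction removed (QR of [1 | indicators], keeping columns
  1…c−1); output weights U = (HᵀH + αI)⁻¹HᵀZ with defaults L = 1000,
  α = 1. `transform` reuses the training-stage hidden parameters — fresh
  draws would make U meaningless. An exhaustive (L, α) grid search by
  cross-validated error is provided (ties → smaller L, then smaller α).
* **t-SNE** is exact (Barnes-Hut and parametric variants are out of
  scope): bandwidths by ≤ 50 bisection steps to |log-perplexity error| <
  1e−5; perplexity 30; learning rate 200; momentum 0.5 → 0.8 at iteration
  250; early exaggeration ×4 for the first 100 of 1000 iterations; seeded
  N(0, 1e−4) initialisation; embedding recentred each step. These are the
  classic defaults of the original algorithm. t-SNE has no out-of-sample
  map; train and test rows are embedded jointly with labels withheld
  (transductive), and because the normaliser is fitted per training fold,
  the joint embedding is recomputed per fold.

## Classifiers

KNN uses k = 3 and Euclidean distance. SVMs use cost 1; RBF and
polynomial kernels use gamma 1; the polynomial kernel is the
inhomogeneous (γ x·x′ + 1)³: the homogeneous form (coef0 = 0) collapses
numerically on SRELM outputs, whose entries scale like 1/√n because the
response columns are orthonormal. Multiclass SVM is one-vs-one. The
neural network is 4-14-c (tan-sigmoid hidden, linear outputs) trained by
full-batch gradient descent, learning rate 0.01, momentum 0.9, 500
epochs, MSE against one-hot targets, argmax prediction; inputs are
internally min-max scaled to [−1, 1] — the conventional preprocessing of
tan-sigmoid networks, and necessary for the same 1/√n reason. NB is
Gaussian naive Bayes.

Five-fold cross-validation shuffles rows with a seeded splitter (fold
sizes differ by at most one); the normaliser, projector and classifier
are all refitted per fold on the training portion only.

## Cluster metrics

Semi-principal axes are the square roots of covariance eigenvalues (an
ellipsoid's semi-axis is √λ); MSA uses the k largest. Near-singular
covariances receive a 1e−9 · trace/dim diagonal ridge before inversion.
In the position-reduction experiment RI is computed in projected space
between the class means of the training-position subset and those of the
full nine-position test pool, under the training covariance.

## Experiments and problem sizes

The position-reduction schedule fixes the nine nested "best position"
subsets (P5; P5,P9; …; all nine) rather than re-searching subsets. Each
subset uses a seeded 80/20 split within each training position; the test
side is the held-out 20 % of the training positions plus every window of
the excluded positions, so the nine-position subset reduces to a clean
80/20 split and no training row is ever scored.

Adjacent 150 ms windows overlap by 100 ms and are highly redundant, so
experiments expose a `window_stride` that keeps every s-th window per
trial. Package defaults for desk-scale runs: the acceptance script uses
the full 225-trial design with stride 6 (1575 windows); the test suite's
qualitative checks use 2 repetitions with stride 8 over five seeds (450
windows per seed). The exact-t-SNE embeddings, recomputed per fold, are
the dominant cost at any scale.

## Known limitations

* The t-SNE train/test protocol is a documented design choice
  (transductive joint embedding); a per-fold refit or parametric mapping
  would change test-side numbers.
* Absolute error levels and SI/MSA/RI magnitudes depend on the synthetic
  generator's calibration and are not comparable to values measured on
  real multi-subject recordings; only orderings and trends are meaningful.
* The NN's optimizer settings are conventional stand-ins; no early
  stopping or validation split is used.
* SI/MSA/RI assume roughly unimodal, full-rank class clusters; with fewer
  rows than dimensions per class the metrics refuse to compute rather
  than silently regularise away the deficiency.
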