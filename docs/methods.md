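# Methods

This note documents the models and procedures implemented in the
package, the parameters that matter, the numerical choices, and the
design decisions taken where the design was genuinely open.

## Input model

Captures are BVH documents: a HIERARCHY of named joints with offsets
and per-joint channel declarations, and a MOTION block of per-frame
channel values.  Rotations are Euler angles in degrees, composed
intrinsically in each joint's declared channel order; the parser trusts
the CHANNELS declaration rather than assuming a fixed order.  End sites
are not joints.  Translation channels are accepted anywhere but only
the root's are retained (and only for round-tripping; nothing
downstream uses them).  Both `Frames:` and `Frames :` header dialects
are tolerated, and all tokenizing is whitespace-insensitive.

The working profile keeps **17 joints** (hips, two spine joints, neck,
head, and both shoulder–upper-arm–forearm–hand and
upper-leg–lower-leg chains).  Files with richer skeletons are subset by
name with `select_joints`, which reparents kept joints to their nearest
kept ancestor; the profile is a configurable name list because exporter
naming conventions differ.

Writing uses 6-decimal formatting, so parse ∘ write reproduces angles
within 1e-4 degrees (regression-tested round trip).

## Rotation representation

Euler angles suffer gimbal lock, so all comparisons run on unit
quaternions (scalar-first).  Conversion uses intrinsic rotation
composition per the declared channel order (delegated to
`scipy.spatial.transform.Rotation`, cross-checked in tests against an
explicit axis-matrix product oracle).

Since `q` and `−q` encode the same rotation, every operation is
double-cover safe:

* **distance** `d(a, b) = 2 arccos |⟨a, b⟩|` ∈ [0, π] — a pseudometric
  on rotations, evaluated in the numerically stable arcsin form
  `4 arcsin √((1 − |dot|)/2)`.  Dot products within a few ulp of 1 are
  clamped to exactly 1 so identical rotations have distance exactly 0
  at double precision;
* **slerp** applies shortest-arc sign correction and falls back to
  normalized lerp below 1e-10 radians;
* **conversion sign policy**: each frame is canonicalized to `w ≥ 0`,
  then temporal continuity overrides — a frame is flipped whenever its
  dot with the previous frame is negative.  This keeps each joint's
  trajectory continuous on the 4-sphere, which stabilises DTW frame
  costs and makes keyframe slerp segments well-defined.

## Motion-accuracy scoring (DTW)

Per joint, the DTW distance between the student and expert quaternion
trajectories uses:

* frame cost = the quaternion geodesic angle (radians);
* the symmetric unweighted step pattern {(1,0), (0,1), (1,1)}, each
  visited cell contributing its cost once;
* no path-length normalization — compared captures have similar
  durations, and the raw summed cost preserves the skill ordering;
* a Sakoe–Chiba band of half-width `ceil(band_fraction · max(n, m))`
  with `band_fraction = 0.10` by default ("10 % of the span" read as
  the longer sequence).  For unequal lengths the half-width is floored
  at `|n − m|`, the minimal widening that keeps the terminal corner
  reachable; feasibility is therefore guaranteed by construction.

The motion's total distance is the arithmetic mean of the 17 per-joint
distances (distances first, average second).  Properties verified by
test: zero iff frame-wise identical, symmetry, band monotonicity
(narrower band ⇒ distance not smaller), and exact agreement with an
exhaustive path-enumeration oracle on sequences of ≤ 7 frames.

Absolute distance magnitudes depend on capture length and sampling and
are not comparable across instrumentations; only orderings and the
statistics computed from cohorts of distances are meaningful here.

## Features, normalization, PCA

Each motion yields 17 joints × 3 Euler channels × 6 statistics = **306
features**.  The statistics are computed on the raw channel series
(hence invariant to `frame_time`): mean; population variance; its
square root; skewness (third standardized moment, population form);
excess kurtosis (fourth standardized moment − 3, population form);
quartile deviation `(Q3 − Q1)/2` with linear-interpolation quantiles.
A constant series (zero peak-to-peak) has undefined standardized
moments; both are assigned 0, as are non-finite values from
numerically constant series.  Features are computed on Euler channels
rather than quaternion components because three channels per joint is
what makes the 306 count come out.

Min–max normalization maps each feature's training range onto [0, 1];
a constant training feature maps to 0 and out-of-range test values are
clipped.  PCA (mean-centred, full SVD) keeps the smallest component
count whose cumulative explained variance reaches `variance_target`
(default 0.95, configurable; a target of 1.0 keeps everything).  Both
are fitted on training data only — inside every cross-validation fold
they are refit on that fold's training rows, and a poisoning test
verifies held-out rows cannot influence them.

## Classifiers

Grading (ordinal Fail < Pass < Good) and recognition (classes 1–8) use
the same machinery.

Sample-based methods run on the scaled, PCA-reduced features:
k-NN (k = 3, Euclidean, distance-weighted so ties resolve toward the
nearest neighbour), RBF-kernel SVM (C = 1, γ = 1/dims, one-vs-one),
Gaussian naive Bayes, multinomial logistic regression (L2), and a Gini
decision tree.  Defaults follow the methods ultimately selected for
deployment — k-NN for grading, SVM for recognition; all
hyperparameters are configurable.

Sequence-based methods treat motions as quaternion time series:
`dtw_knn` is 1-NN under the band-constrained motion distance;
`dtw_svm` / `dtw_nb` / `dtw_logreg` / `dtw_dtree` embed each motion as
its vector of DTW distances to the training motions (min–max scaled)
— the simplest faithful reading of "DTW combined with classifiers";
`hmm` fits one Gaussian-emission HMM per class (5 states by default,
diagonal covariances, left-to-right topology imposed at initialisation
— forward-only transitions stay structurally zero under EM) on
keyframe quaternion vectors and classifies by maximum log-likelihood.

Neural methods are deliberately not built in; `register_method` accepts
any factory returning a fit/predict estimator, which is the extension
point for them.

Cross-validation is stratified k-fold (default 10), shuffled with a
fixed seed, accuracy per fold and mean reported.

## Keyframe compression

Frames are embedded as concatenated sign-continuous per-joint
quaternions (17 × 4 = 68 dimensions).  k-means (k-means++, 10
restarts, seeded) with `k = max(2, round(ratio · F))` clusters the
frames; each cluster is represented by the frame nearest its centroid,
and the earliest/latest selections are snapped to the first and last
frames so reconstruction covers the full duration.  The default
compression ratio is 0.15.  Reconstruction slerps per joint between
consecutive keyframes at the original frame positions; keyframes are
reproduced exactly.  Reconstruction error is the mean quaternion angle
over all frames and joints — 0 at ratio 1.0, weakly decreasing in the
ratio on smooth motions (trend-tested at fixed seeds).  The
cluster-representative rule, forced endpoints, and the error metric are
this package's choices, made for reconstructability and testability.

## Session integrity

Captures arrive pre-segmented (one file per motion), matching the
capture protocol.  Each capture is recognized, graded, and scored
against the expert template of its recognized class.  Sequence
integrity compares the recognized class list with the lesson's expected
list (no duplicate classes) via a longest common subsequence:

* a class absent from the recognized list is **missing**;
* a class present but outside the LCS was performed out of turn; it is
  paired with the adjacent recognized class it is inverted against and
  reported as an adjacent transposition, in expected order.

A brute-force oracle (all deletion subsets plus all disjoint adjacent
swaps on sequences of length ≤ 5) confirms the detector recovers
exactly the applied edits.  Recognition errors and integrity errors are
reported in separate layers: a misrecognized capture changes the
recognized sequence and is surfaced there, not conflated with missing
counts.  `track_progress` tabulates lesson × motion → performed flag,
grade, distance across a course.

## Validation statistics

* **Student's t** from group summaries (pooled variance, df = n1+n2−2)
  or raw data; **Welch** variant with Satterthwaite df.  Zero pooled
  variance with equal means yields t = 0; with unequal means it is an
  error (infinite statistic).
* **Mann–Whitney U**: U = min(U1, U2) with U1 = R1 − n1(n1+1)/2;
  Z = (U − n1n2/2)/σ with tie-corrected σ and **no continuity
  correction** (the convention that reproduces published Z values from
  published U values); two-tailed normal p.  A rank-sum entry point
  recomputes U and Z from printed group sizes and rank sums (no tie
  information survives publication, so it assumes none).
* **Kendall τ-b** with tie corrections (ordinal grades are heavily
  tied); constant vectors are an error, not NaN.
* **Pearson χ²** of independence, df = (r−1)(c−1), flagged when any
  expected count is below 5.
* **Levene** (mean-centred) as the equality-of-variances screen; its
  published F values are not recomputable from summaries and are only
  simulation-tested (type-I rate near α, power under a 4:1 variance
  ratio).

## Synthetic data

`baduanjin.synth` emulates the structure the pipeline assumes, not
Baduanjin choreography:

* **templates** — per joint channel, a sum of three low-frequency
  sinusoids (0.5–2.5 cycles, class-keyed frequencies/phases, amplitudes
  ≤ 90°), deterministic in (class, seed) and independent of the frame
  count, so different-length captures describe the same movement;
* **skill profiles** — a student capture perturbs a template by
  (1) per-channel amplitude scaling centred on an undershoot of
  `amplitude_noise_sd / 30` with random spread `amplitude_noise_sd / 90`
  — lower skill primarily shows as reduced range of motion, which is
  what makes grades identifiable from time-domain features rather than
  only from dispersion; (2) a global phase shift (SD a fraction of the
  duration, edge-clamped); (3) global tempo resampling (uniform factor,
  output length = F / tempo); (4) i.i.d. angular jitter.  Defaults:
  experienced = (2°, 0.01, 0.95–1.05, 1°), novice = (8°, 0.05,
  0.85–1.15, 4°) — the novice profile strictly dominates;
* **graded datasets** — each sample draws a deviation multiplier `s`
  from its grade's band (Good 0.2–1.0, Pass 1.8–2.8, Fail 3.6–5.0,
  applied to the experienced profile) so grades are recoverable in
  principle and balanced as requested;
* **sessions** — the expected class sequence minus dropouts, with
  listed adjacent swaps applied.  `template_seed` pins which underlying
  choreography is performed and must match the training dataset's seed
  when fitted models will assess the session.

What the generator does **not** emulate: biomechanically plausible
Baduanjin kinematics, anthropometric variation, sensor drift and
magnetometer artefacts, within-motion pauses, or segmentation errors.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that its statistical behaviour has the right direction and
sensitivity under controlled conditions — not that the deployed
accuracies on real student data would be reproduced.

## Problem sizes and determinism

The end-to-end checks use templates of 100 frames (1 s at the 100 Hz
sampling the instrumentation produces) for cohort scoring, 80-frame
motions for grading and 60-frame motions for session assessment, with
cohorts of 27 novice / 33 experienced captures mirroring the reference
study design, 60 grade-labelled samples (two classes) for grading and
24 samples (eight classes) for recognition.  These sizes were chosen so
the whole validation runs in well under a minute while keeping every
statistical conclusion stable across seeds.  All stochastic stages
(k-means, fold shuffling, perturbation draws) consume seeds derived
from a single integer, so identical configurations produce identical
reports.

## Known limitations

* DTW costs are summed without normalization, so distances are only
  comparable between sequences of similar length.
* The band DP is exact but O(n·w) per joint in Python; very long
  captures (many thousands of frames) would benefit from a compiled
  kernel, which this package does not include.
* The HMM route requires every class to have at least as many keyframes
  as states; very short motions reduce the state count automatically.
* Ordinal structure of grades is not exploited by the classifiers
  (they treat Fail/Pass/Good as nominal); τ-b in the statistics module
  is where ordinality enters.
* The LCS integrity analysis assumes expected sequences without
  duplicate classes, which holds for the eight-motion routine.
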