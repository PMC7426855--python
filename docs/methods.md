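# Methods

`videogait` re-implements a video-based clinical gait-analysis workflow:
per-frame 2D pose keypoints from a single sagittal-plane walking video are
normalized into a 12-channel multivariate time series, cut into fixed-length
windows, and mapped by a small 1-D convolutional network (or by
summary-statistic baselines) to visit-level clinical gait metrics.  This
note records the model, its assumptions, the tunable parameters, the
synthetic data used for testing, and the numerical choices made where the
design was genuinely open.

## Input model and preprocessing

The raw input is an OpenPose BODY_25 trajectory: for each of ~500 frames at
29.97 fps, 25 landmarks with image-plane pixel coordinates (x rightward,
y **downward**, origin top-left) and a confidence in [0, 1].  A detection
with confidence 0 or coordinates exactly (0, 0) carries no information and
is treated as missing — both encodings occur in pose-estimator output.
Videos in which more than one person was ever detected, or in which the
subject was never detected, are excluded whole; when a frame contains
several people the reader keeps the highest-total-confidence person but
flags the video so the filter can act.

Normalization proceeds in four steps:

1. **Center and scale.**  Per frame, every keypoint has the right-hip
   position subtracted and is divided by the right-hip→right-shoulder
   Euclidean distance.  This removes camera translation and projection
   scale.  The scale is computed **per frame** rather than once per video:
   the camera pans and the subject's distance varies along the walkway, so
   the projected body size is not constant.  A frame whose hip or shoulder
   is missing, or whose hip–shoulder distance is zero (degenerate pose),
   becomes missing as a whole and is filled by imputation later.
2. **Direction alignment (mirroring).**  Subjects walk back and forth, so
   the trial is segmented into constant-direction runs; runs walking toward
   camera-left have x negated and anatomical left/right labels swapped,
   presenting every frame as a right-side (or mirrored-left) view.  The
   walking direction is the sign of the mid-hip *raw pixel* x-velocity
   (centering erases progression, so the raw coordinate is carried along),
   **median**-filtered over a sliding 15-frame window; runs shorter than 30
   frames are merged into their longer neighbor.  The median, rather than
   the mean, is used because a panning camera produces large single-frame
   velocity spikes whenever the operator re-centers the subject; the median
   is unaffected by them while the mean can flip sign.  If no direction can
   be established (stationary subject) the series is left unmirrored with a
   warning flag.
3. **Smoothing.**  Each coordinate channel is convolved along time with a
   Gaussian kernel, sigma = 1 frame, truncated at 4 sigma.  Missing samples
   are excluded and the kernel is renormalized over the available
   neighbors, so constants are preserved exactly.  Smoothing runs *after*
   mirroring so that x-channels are continuous across a reversal boundary
   and the discontinuity is not smeared into neighboring frames.
4. **Imputation.**  Interior gaps are filled by linear interpolation
   between the nearest observed neighbors; leading/trailing gaps hold the
   nearest observed value.  The pre-imputation mask is retained, because
   the windowing stage's missing-data rule must see the true missingness,
   not the imputed values.

From the aligned series, 12 channels are assembled per limb: ipsilateral
ankle, knee, hip and big-toe (x, y) pairs; the projected knee angle (angle
at the knee between rays to the hip and ankle, degrees — 180° is a straight
leg); a projected ankle angle; the big-toe–ankle distance; and the signed
ipsilateral-minus-contralateral ankle x-difference.  Two conventions here
were open and are fixed as follows: the ankle angle, which is named but not
defined in the source workflow, is taken at the ankle between rays to the
knee and the big toe (the direct analogy to the knee angle); the
toe–ankle distance is Euclidean in normalized units (the ankle–ankle
feature is explicitly an x-difference; this one is not, so a distance is
read as a distance).

## Windowing

Training windows are 124 frames long with a 31-frame stride: starts 0, 31,
…, while start + 124 ≤ T, which yields 13 windows for a clean 500-frame
trial.  A window with **more than** 25% of its pre-imputation cells missing
is dropped (25.0% exactly is retained).  The per-video retained count c(i)
is recorded; the stated upper bound of 12 windows per video in the source
material conflicts with its own enumeration (13 starts for T = 500), and
the enumeration is followed — the bound is read as descriptive of that
dataset after missing-data filtering, not as a rule.

## Models

**CNN.**  Input 124 × 12.  Two blocks of k = 3 convolutional layers
(32 filters, length 8, same-padding; each filter has F·D + 1 weights
including its bias), each convolution followed by ReLU then batch
normalization (that order measured slightly better in the original
tuning), each block closed by max-pooling (r = 2) and dropout 0.5; then
flatten and a single dense output (linear for regression, softmax for
classification).  L2 regularization λ = 3.16 × 10⁻³ applies to the last
four convolutional layers' weights.  Two points needed resolution:

- λ is printed in the source as "3.16 × 10³", which would annihilate the
  network; it is read as 10^−2.5 — a log-spaced search-grid value with a
  lost superscript — and is exposed in the configuration.
- The block count and pooling sizes are not fully recoverable; regularizing
  "the last four" convolutions implies more than four, and two 3-conv
  blocks is the minimal consistent reading.  The resulting network has
  45,601 trainable parameters (regression head); no configuration
  consistent with the stated layer sizes reproduces the printed 47,840
  exactly, so the builder reports its own count (checked against the
  analytic (FD + 1)·D₂ formula in the tests) and the discrepancy is
  documented rather than silently resolved.

The network, including backpropagation and the RMSProp optimizer, is
implemented directly on numpy (float32, im2col/BLAS); the backward passes
are verified against finite differences in float64.

**Baselines.**  Ridge regression and a random forest (200 trees, depth 10)
consume 72 per-video features: the 10/25/50/75/90th percentiles
(linear-interpolation convention) and standard deviation of each channel
over the full-length series.  Ridge features are standardized on the
training set (a quadratic penalty needs comparable scales; trees are
scale-invariant and take raw features); α = 0 reduces exactly to ordinary
least squares, with a minimum-norm fallback for singular systems.

## Training

RMSProp (rho 0.9), batch size 32, initial learning rate 10⁻³ decayed by 20%
every 10 epochs, at most 50 epochs with early stopping on validation loss
(patience 10, best weights restored); the epoch budget and patience are
package choices, since only "early stopping" is specified.  The regression
loss divides each window's squared error by its video's window count c(i),
so a video's total contribution equals its mean window error regardless of
how much usable footage it has; classification uses cross-entropy
(probabilities clipped at 10⁻⁷) with the same weighting.  Regression
targets are z-scored on the training set and mapped back at prediction —
RMSProp's effective step size is poorly matched to degree-scale targets
otherwise; the subsequent linear calibration absorbs any affine map, so
this is purely an optimization aid.

Per-video predictions average the video's window outputs (probability
vectors are averaged before argmax).  Window averaging biases predictions
toward mid-video content, so a linear **debiasing** regression of truth on
prediction is fitted on training-set pairs and applied to held-out
predictions; the per-video *average* is debiased (not individual windows).
Splits are at the patient level — all of a patient's videos land in one of
train/validation/test (default 0.8/0.1/0.1).

For side-independent targets (speed, cadence, GMFCS) both limbs' feature
series contribute windows to the same video datapoint, sharing one c(i)
and one label; for per-limb targets (knee flexion at maximum extension,
the deviation score, SEMLS) each (video, limb) is its own datapoint.

## Evaluation

Regression: Pearson r with a 95% CI from 200 paired bootstrap resamples at
the video level (seeded), mean absolute error, and a two-sided one-sample
t-test on the mean residual truth − prediction (zero-variance residuals are
reported as "no evidence of bias").  GMFCS: confusion matrix with rows =
predicted levels, accuracy, the largest level error, and quadratic-weighted
Cohen's kappa, κ = 1 − Σw·observed / Σw·expected with w_ij = (i − j)² and
independence-expected counts from the marginals (any positive scaling of w
cancels).  SEMLS: AUC by the midrank Mann–Whitney formulation, with ROC
points for plotting, and a logistic-stacking ensemble with a GDI-based
logistic model (the combination rule was unstated; stacking is the package
choice, fitted on training data only).  Prediction error decomposes exactly
into patient, visit-within-patient and trial-within-visit sums of squares
(nested-means identity); the unexplained variance is this SS divided by the
null model's (grand-mean predictor).  Residual-vs-covariate analyses fit
linear and quadratic least squares, select by BIC (counting the noise
variance: 3 vs 4 parameters) and report the chosen model's F-test p.

## Synthetic cohorts

The generator drives a planar sagittal linkage (pelvis, hips, knees,
ankles, heels, toes, trunk, arms, head; child-scale segment lengths) with
truncated-Fourier joint-angle waveforms at a sampled cadence, limbs in
anti-phase; the pelvis translates at the sampled speed along a 9 m walkway
and reverses at the ends, so mirroring is exercised in every trial.  A
latent severity in [0, 1] adds a crouch-like warp to the knee waveform,
yields a GDI-like score 100 − 2.7·RMS(warp) per limb (a monotone deviation
proxy, *not* the clinical GDI formula, which needs 3D kinematics and a
reference population), sets GMFCS by severity quartile and SEMLS through a
logistic link.  Projection to 640 × 480 pixels uses 170 px/m, a camera that
re-centers on the pelvis every 30 frames with sinusoidal jitter
(amplitude 20 px), Gaussian pixel noise (sd 2 px) and independent missing
detections (rate 0.05).  Draws whose stride length is incompatible with the
leg geometry are resampled and counted.

Default sampling ranges — cadence 0.6–1.3 strides/s, speed 0.4–1.4 m/s,
knee-offset 2–25°, per-limb offset asymmetry sd 3° — cover the spread seen
in ambulatory cerebral-palsy gait.  Because the clinical ground truth in
the emulated workflow comes from a *separate* motion-capture session (video
and labels are never simultaneous), the generator's label table carries the
video's true values plus measurement noise (speed 0.06 m/s, cadence
0.03 strides/s, knee 2.5°, deviation score 3.0 points).  The generator does
**not** emulate soft-tissue artifact, assistive devices, occlusion by the
contralateral limb, perspective distortion, double-support timing realism,
or pose-estimator bias that correlates with pathology — so passing tests
demonstrate that the pipeline recovers parameters the keypoints encode, not
that the trained weights transfer to real clinical video.

## Problem sizes and test design

The end-to-end recovery test trains the full CNN for cadence and for speed
on a 200-video cohort (200 patients, one visit), checking held-out
correlation and post-calibration bias; this size gives roughly 20 held-out
videos and trains in minutes on one CPU.  Oracle tests compare the weighted
kappa to a direct double-sum evaluation (1000 random matrices), AUC to the
O(n²) pairwise count with ties, ridge to explicit normal equations, the
error decomposition to its additivity identity (1e−10), and the network
gradients to float64 finite differences.  Statistics on real deposited data
(correlations of the original study) are out of the automated suite's
scope: they require the external dataset and a trained model's run-to-run
variance admits no exact expected value.

## Known limitations

- The CNN is CPU-bound numpy; it is sized for ~50K parameters and
  124-frame windows, not for large-scale architecture search.
- Direction detection needs some uncompensated camera motion or subject
  progression in pixel space; a perfectly subject-locked camera would defeat
  the mid-hip velocity cue (the foot-orientation cue would be the natural
  extension).
- The GDI-like synthetic score shares only monotonicity-in-deviation with
  the clinical GDI.
- GMFCS prediction on small synthetic cohorts can lack rarer levels in the
  held-out set, in which case kappa is undefined and reported as such.
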