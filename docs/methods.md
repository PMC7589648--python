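# Methods

## Problem and setting

A 32×24-pixel thermopile array (operating range −40…85 °C) is mounted on
the ceiling of a ~4 × 5 m room, looking straight down, and sampled at
15 Hz. Each frame is a grid of temperatures in °C. A person appears as a
compact patch roughly 1–6 °C warmer than the room; the within-person
temperature spread is at most about 5 °C after background subtraction, and
the sensor's per-pixel noise (NETD) is 0.1–0.25 K depending on sampling
rate. At this resolution no identifiable features exist, which is the
point: the sensor monitors people (in wards, nursing rooms, bathrooms)
without imaging them.

The task is to classify 15-frame windows (1 s) into eight motions —
falling, sit-to-stand, stand-to-sit, sitting, standing, bowing, crouching,
walking — with falling the safety-critical positive class.

## Pipeline

**Denoising.** Every frame is smoothed with the smallest normalized
Gaussian kernel (3×3, weights 1/16–1/8–1/4). Border handling is
replicate-edge: on a 24×32 grid, zero padding would create a spurious cold
frame border. The filter is linear and mass-preserving on constant images.

**Background model.** A per-pixel exponential moving average,
`BG_i = α·BG_{i-1} + (1−α)·FG_i`, seeded with the mean of 150 target-free
frames (10 s at 15 Hz). α = 0.999, so at 15 Hz a newly static object is
absorbed with time constant `1/((1−α)·15) ≈ 67 s`; static warm clutter
(monitors, heaters) present at initialization is part of the background
and vanishes from the foreground. The update runs on every frame,
including frames with a person present — at α = 0.999 a 3-s transit
perturbs the model by far less than the noise floor. A masked variant
(freeze under detection) exists but is off by default. Foreground =
frame − background, floored at 0 by default since detection reasons only
about warm excursions.

**Detection.** Pixels at least 1 °C above background within the 5×5
neighborhood of a local temperature maximum are "marked" (local maxima are
strict 5×5 maxima; plateau ties resolve to the earliest pixel in row-major
order). Marked neighborhoods are unioned, 8-connected components are
formed, and a human is declared when the largest component holds at least
N_H = 8 pixels (a global-count variant is available by option). The
hottest pixel is a biased location estimate, so the position is refined by
iterating the intensity-weighted centroid of the 5×5 box around the
current (rounded half-away-from-zero) center until the move is under
0.5 px or 20 iterations. Successive barycenters give per-step distance,
direction and speed; frame-to-frame association is nearest-neighbor with
an 8 px/frame gate.

**Segmentation and counting.** For multi-person scenes the foreground is
clipped to [0, 5] °C, quantized to 8-bit, binarized at the Otsu threshold
(exhaustive between-class-variance argmax, lowest level on ties), and
split into 8-connected components of at least N_H pixels. Each component
becomes its own sub-frame with non-target pixels set to the scene minimum.
Touching people merge into one component — an inherent failure mode at
this resolution, reproduced and tested rather than patched.

**Features (LSTM path).** Per frame of a window, for the tracked target:
per-frame barycenter displacement (px); target area (px); area change
rate (area over previous area, with the first-frame and zero-denominator
cases defined as 1.0); maximum and mean temperature on the target; and the
directional distribution ratio — the long/short axis ratio of the standard
deviational ellipse, i.e. the square roots of the eigenvalues of the
coordinate covariance of the target's pixels about their mean. The ratio
is ≥ 1, is invariant to translation and 90° rotation, returns 1.0 for a
single pixel and is capped at 50 for collinear regions. An optional
temperature-weighted covariance exists (off by default). Frames with a
missed detection carry the previous feature column forward and are counted
as gaps. Moving distance is per-frame, not cumulative, matching the
one-vector-per-time-step input of the recurrent classifier.

## Classifiers

Both are implemented in NumPy with explicit forward/backward passes and
are bit-reproducible for a fixed seed.

**3D CNN (raw path).** Input is the normalized window (°C above
background clipped to [0, 5], scaled to [0, 1]), shape (T, 24, 32),
single channel, depth = time. Architecture: 32 convolution filters of
5×5×5 (valid, stride 1) → ReLU → 3×3×3 max pooling (stride 3, valid) →
dense 128 → ReLU with 50% inverted dropout → dense 8 → softmax. For
T = 15 the flattened pool output is 3·6·9·32 = 5184 and the parameter
count is 668,744 (pinned in a test).

**LSTM (feature path).** The 6×T feature matrix is transposed to T steps
of 6 dimensions, standardized per feature (the six features live on
incommensurate scales), and fed to a 128-unit LSTM; the final hidden state
goes through a dense 8-way softmax head. Forget-gate bias starts at 1.

**Training.** Softmax cross-entropy, Adam at learning rate 0.001 (SGD
available by option), batch size 32, up to 100 epochs by default, no early
stopping. Dropout is active only during training, so inference is a pure
function. Class probability vectors always follow the canonical class
order (falling, sit2stand, stand2sit, sitting, standing, bowing,
crouching, walking); argmax ties break to the lowest index.

## Synthetic scene generator

Participant recordings behind systems of this kind are not public, so the
test bed is a seeded simulator. It emulates: a uniform 25 °C room;
optional static warm equipment spots; i.i.d. Gaussian per-pixel noise with
σ in the sensor's NETD band (default 0.2 K); and one anisotropic
2-D Gaussian temperature blob per person, truncated below 1 °C excess so
its support is crisp, peaking 4–6 °C above background (peak 29–31 °C —
the truncation level plus the ≤5 °C within-person spread bounds the peak).
Recordings are 3 s (45 frames); each class has a parameterized trajectory
of center, axis lengths and orientation. The one-shot motions (falling,
sit2stand, stand2sit, bowing) transition over 0.7–1.0 s placed to straddle
the middle of the recording, since evaluation takes one centered window
per repetition; falling displaces the center ~2.5–4 px while the blob
grows and elongates (axis ratio ~1 → ~3) into a lying posture, then stays
static. Static classes differ by blob scale (standing σ 1.3 px, crouching
1.6, sitting 2.0) with small jitter; walking translates at 1.5–2.5
px/frame with a wandering heading, elongated along travel. Synthetic
subjects carry systematic multipliers (body size ±10%, pace ±15%, warmth
±5%) so subject-grouped evaluation is meaningful. Multi-person scenes
place spawn points on a feasibility grid so all pairs stay ≥10 px apart
for the whole recording (or at pinned positions to reproduce the
touching-targets merge).

What the generator does *not* model: perspective and height-dependent
pixel footprint, radiometric calibration, limb-level articulation,
fixed-pattern noise, drafts or ambient drift, and the real inter-person
variability of motion style. Passing the synthetic end-to-end bands
therefore demonstrates that the pipeline and classifiers work as designed
on data with the stated geometry and noise — not that the real-world
accuracies of the reference study would be reproduced.

## Evaluation protocol

Confusion matrices are 8×8 (rows true, columns predicted, canonical
order). Fall metrics are one-vs-rest with falling positive: accuracy,
recall, specificity, precision, F1 from the usual TP/FP/TN/FN ratios; a
zero denominator yields an explicit "undefined", never a silent 0.
Per-class correct answer rates are the diagonal over row sums; the overall
rate is trace over total. Reported percentages round half-up to 0.1
points. Cross-validation is subject-grouped: subjects are partitioned into
disjoint test groups (16 subjects → 8 folds testing a distinct pair each,
a seeded shuffle choosing the pairing), so no person contributes to both
sides of a fold. The window-length sweep retrains per candidate T in
[10, 20] and reports one cross-validated overall rate per T.

Two reference confusion matrices from the original 16-participant study
(LSTM and 3D CNN, 800 samples per true class) ship as text fixtures; every
published metric derived from them is recomputed exactly in the regression
suite. Two recomputations disagree with the study's own summary rounding:
the LSTM overall rate is 5286/6400 = 82.59% → 82.6% (the study prose says
82.5%), and the LSTM specificity is 5519/5600 = 98.55% → 98.6% (the study
table says 98.5%). The recomputed values are pinned; agreement with the
summary figures is not forced.

## Problem sizes and numerical choices

The shipped end-to-end experiments (acceptance test and
`scripts/acceptance.py`) use 50 recordings per class over 8 synthetic
subjects with σ = 0.2 K, hold out two subjects, and train the 3D CNN for
20 epochs (with temporal offsets ±2, ±4 and random ≤6 px spatial shifts as
augmentation — the raw-window classifier has no built-in translation
invariance) and the LSTM for 60 epochs (temporal offsets ±3). These sizes
are the package's chosen benchmark scale; both paths reach their target
bands (≥90% / ≥80% held-out accuracy) well before the default 100-epoch
budget on this data.

Known numerical biases, by design:

* The 3×3 denoise interacts with the blob's 1 °C truncation edge: support
  pixels sitting just at threshold blur below it, so a small blob's
  thresholded area shrinks by a 1–2 px ring (up to ~18% for ~15 px blobs).
  The noise-free area-recovery test therefore checks the render → subtract
  → threshold chain, where recovery is exact; area features used by the
  classifier are consistent within themselves.
* Otsu binarization cuts mid-blob (it maximizes class separation, it does
  not find the 1 °C support edge), so segmented areas are smaller than
  thresholded support. Again consistent across frames and classes.
* Barycenter refinement on a plateau converges to the centroid of the
  5×5 window around the final center; when the blob fits the window this
  equals the global weighted centroid (tested against a brute-force
  oracle).

Degenerate inputs are errors, not guesses: an empty frame list, a
single-level histogram, an empty region, a zero-mass neighborhood, a
single-class training set, and double normalization all raise with
specific messages.
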