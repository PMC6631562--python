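# Methods

## Problem setting

A camera on a vehicle drives along an orchard inter-row at night, imaging
tree canopies at 10 fps. At ~5 km/h and 1024×1024 resolution the scene
content shifts by roughly 20 px per frame horizontally; vertical platform
speed is treated as zero. An external detector (out of scope here) emits
per-frame bounding boxes. The task is to link those boxes into fruit
identities and count each fruit exactly once, despite occlusions, detector
misses (~1.4 per frame in field conditions), hallucinated boxes (~1.4 per
frame), and platform oscillation that rotates and rescales the image
slightly from frame to frame.

## Motion model

Each track is a linear Kalman filter with state (x, y, vx, vy): box-centre
position in pixels and velocity in pixels/frame. The transition is constant
velocity with dt = 1 frame; the measurement is the detection's box centre.
Noise parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| q (process noise, px²) | 1.0 | deliberately large: rotation/scale oscillation and speed variation are unmodelled, so the filter must adapt fast |
| r (measurement noise, px²) | 0.1 | detections locate fruit precisely |
| p0 (initial covariance, px²) | 10.0 | diffuse enough that early measurements dominate; finite so gains stay well-conditioned |
| default speed (px/frame) | (20, 0) | the nominal platform shift; used before any stable track exists |

Q and R are scalar multiples of the identity — the simplest model consistent
with treating oscillation as isotropic noise; all scalars are exposed in
`TrackerConfig`.

A filter is **stable** after four real measurement updates; with q/r = 10
the velocity error then decays by roughly 3× per update, so four updates
suffice for sub-pixel one-step prediction on near-constant-velocity motion
(exact when the initial speed matches the true shift). When an *unstable*
track misses a detection, its own velocity estimate cannot be trusted, so an
artificial measurement z = previous position + v_borrowed is fabricated from
the nearest stable track's filtered velocity (Euclidean distance between
registered positions, ties to the lower id; the global default speed when no
stable track exists) and absorbed as a normal update. Artificial updates are
applied on every unobserved frame while the track survives, but never
increment the stability counter and never reset the unobserved counter —
fabricated data must not self-certify a motion model. A *stable* track that
misses a detection simply registers its predicted position; its covariance
grows by Q each frame, reflecting mounting uncertainty.

## Data association

Tracks are matched to detections by Euclidean distance between each track's
registered position (last posterior, or the committed prediction while
unobserved) and the detection centres. The assignment is a two-pass
Hungarian scheme with a distance gate (default 60 px — three times the
nominal shift):

1. solve the global linear assignment problem over all tracks × all
   detections, with over-gate distances made ineligible (sentinel cost);
2. keep pairs within the gate (equality kept: rejection is "distance
   greater than the gate");
3. re-solve over the tracks left unassigned against **all** detections —
   including already-claimed ones — gated identically;
4. where a detection ends up claimed twice (a multiple-to-one assignment),
   keep the smaller distance; the loser becomes unassigned.

Pass 2 against all detections is what makes step 4 reachable: a displaced
track gets to contest the detection its neighbour stole. Gating *inside*
the solver (rather than only pruning its output) matters: with post-hoc
gating, a surplus detection with no nearby partner — a new fruit at the
frame edge — distorts the global optimum and can divert a track away from
a detection sitting exactly on its predicted trajectory; we observed this
producing spurious identity breaks at frame edges on noiseless scenes.
The inner LAP is solved by `scipy.optimize.linear_sum_assignment`
(rectangular problems directly; surplus rows/columns report unassigned);
the test suite checks it against exhaustive permutation enumeration.

## Track lifecycle and counting

Per frame, in order: size-filter detections (width < 12 px or height < 15 px
excluded — far-side fruit suppression); assign; Kalman-update matched
tracks; propagate unmatched tracks (prediction or artificial update);
remove tracks unobserved for more than `max_unobserved` = 15 consecutive
frames; spawn a new track per unclaimed detection, ids issued in detection
order, initial velocity borrowed from the nearest stable track (else the
default speed). Pruning runs after assignment, so a fruit reappearing
exactly at the 15-frame boundary is still matched. The count is the number
of identities ever created; a fruit hidden longer than the window is
recounted by design (the paper-level audit calls this an occlusion repeat).

## Dual-view baseline

The single-image baseline delimits each tree before counting: pixels
strictly below the Otsu threshold are zeroed (`skimage.filters.threshold_otsu`
behind an adapter aligning its "keep > t" convention with our "zero < t"
contract; constant images degenerate to "zero nothing"); the remaining
intensity is summed per column over the top two-thirds of rows (whole rows,
rounded down) — the region carrying the canopy's sky silhouette; scanning
outward from the image centre, the first column on each side whose profile
is ≤ `near_zero_frac` × max(profile) is the tree boundary. `near_zero_frac`
defaults to 0.02: "near zero" must be scale-invariant across exposure
levels. A side with no such column falls back to a fixed margin (width/4
from centre). Per-tree counts are the sum of the two side counts; fruit
belong to a tree when their centroid falls in the half-open column interval.

## Synthetic scenes

The simulator emulates the acquisition geometry, not the imagery: fruit are
static points (with box sizes 20–60 px wide, aspect 1.0–1.3) on a world
strip of length (n_frames − 1)·shift + frame_width; the camera window
slides so content moves +x and new fruit enter at the left edge; every
fruit is in view at some point. Platform oscillation is per-frame iid
rotation (degrees, N(0, sd)) and scale (1 + N(0, sd)) about the image
centre, so displacement grows with distance from centre. Detector errors:
per-fruit per-frame misses with probability `fn_prob`, Poisson(`fp_rate`)
false positives uniform over the frame with fruit-like sizes (so the size
filter cannot trivially remove them), Gaussian centre jitter, and per-fruit
occlusion windows (geometric duration — memoryless, mean exposed in
config). Ground truth records, per fruit per frame, whether it was in
frame, occluded, or dropped as a miss — which is what lets the evaluation
attribute each identity break to a cause.

Field-condition runs use ~31 visible fruit per frame with 1.4 false
positives and ~1.4 misses per frame (fn_prob = 1.4/31). The engineered
exact-count scenes (50 fruit, 80 frames) additionally enforce a minimum
60 px pairwise fruit separation via rejection sampling: with purely uniform
placement two fruit can sit within one inter-frame shift of each other, and
"every fruit counted exactly once" is then not a well-posed expectation for
any distance-gated tracker. What the simulator does **not** model: fruit
appearance, foliage, correlated detector failures, platform speed drift
within a run, and real false-positive clustering near canopy structures
(simulated FPs are uniform, so almost every FP spawns its own track;
in real imagery FPs hug the canopy and are partially absorbed). Passing
synthetic tests therefore demonstrates the tracking logic, not field
accuracy.

## Evaluation

`error_taxonomy` maps each track to the fruit providing the majority of its
detections (ties to the earliest fruit; FP-majority tracks reported
separately). A fruit claimed by k > 1 tracks contributes k − 1 repeats,
each attributed by the ground-truth cause active in the gap between
consecutive tracks: occlusion, detector miss, else false position
prediction. A fruit that emitted detections but owns no track is a missed
count. The identity estimated = seen + repeats − missed holds exactly by
construction. `count_statistics` compares per-tree machine counts with a
reference tally: bias = mean(est − truth), RMSE, and bias-corrected RMSE
defined as the standard deviation of per-tree errors — the standard reading
of "bias-corrected" consistent with reporting bias separately, and giving
the exact decomposition rmse² = bias² + rmse_bc². With only totals
available, per-tree mean, bias, % of harvest and the correction factor
(reference total / machine total) are computed and the dispersion
statistics are None.

## Numerical and design notes

* Covariances are re-symmetrised ((P + Pᵀ)/2) after each update; tests
  assert symmetry to 1e-9 and non-negative eigenvalues throughout.
* Assignment ties break deterministically (pairs sorted by row index;
  borrow ties by lower track id); detection-column permutations permute
  results identically.
* Problem sizes in the test and acceptance runs (80–120 frames, 50–100
  fruit, ≤ 7×7 oracle matrices, 4000-frame false-positive calibration) were
  chosen as the smallest sizes at which each behaviour is unambiguous;
  a full run of suite plus acceptance script takes well under a minute.
* Degenerate inputs: empty detection files yield empty streams; frames with
  no detections are represented explicitly; constant images return their
  own value as threshold; all-zero column profiles are an error ("no canopy
  signal") rather than a silent fixed-margin fallback.

## Known limitations

* The tracker is purely geometric: no appearance features, no IoU costs.
  Two fruit that swap positions within the gate are indistinguishable.
* Cause attribution for repeats requires simulator ground truth; on real
  video only total repeats/misses are computable (the CLI `evaluate`
  command reports unattributed breaks as false predictions).
* Cross-row double counting is mitigated only by the size filter; no
  geometric registration between the two row passes is attempted.
* Counts at stream edges include fruit first seen in the first/last frame;
  partial-visibility policies at segment boundaries are the caller's
  concern.
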