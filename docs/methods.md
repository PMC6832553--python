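# Methods

`glmbtrack` tracks an unknown, time-varying number of labelled objects from
cluttered detections (and optionally raw images), then estimates whole
trajectories rather than per-frame states. This note records the models, the
numerical choices, and what the synthetic experiments do and do not show.

## Multi-object model

The multi-object state is a labelled random finite set: each object is a
pair (x, l) of a kinematic state and a discrete label, and all labels in a
realization are distinct. Labels are `(time, index)` for objects born from
the birth process and `(parent, time, index)` for spawned objects, so a
spawned label carries its complete ancestry — this is what makes lineage
output possible without any post-hoc matching.

Between frames, each object survives with probability `p_s` and moves by a
Gaussian transition (constant-velocity, or constant-turn with the turn rate
as a fifth state component). New objects enter through a labelled
multi-Bernoulli birth process — either static components at known sites with
existence probability `r_B`, or measurement-driven components centred on the
previous scan's measurements. With a spawn model, every existing object
additionally generates up to `max_offspring` daughters per frame, each with
probability `p_t` and state `f_t(parent) + N(0, Q_t)` (identity `f_t` for
cell division).

Observations are either a finite set of point detections — each object seen
with probability `p_d` plus Poisson clutter with intensity
`kappa(z) = rate / V`, uniform over the surveillance support — or raw
images, where each object contributes a Gaussian intensity blob of spread
`sigma_h` and peak `I/(2 pi sigma_h)` on top of pixel noise `sigma_y`. The
hybrid mode uses both: objects with an associated detection are updated from
the point measurement, miss-detected objects are updated from the image by
scaling the miss factor with the template likelihood ratio `sigma_T`
evaluated on the predicted component (at its mean; the template is truncated
at 3 `sigma_h` and computed in the log domain).

## Forward filter

The posterior is kept in generalized labelled multi-Bernoulli (GLMB) form: a
weighted mixture over hypotheses, each a label set plus the full
label-to-measurement association history, with one Gaussian per label. The
joint prediction–update builds, per parent hypothesis, one categorical
decision variable per existing label (die / miss / measurement j), per birth
candidate (absent / miss / measurement j), and per spawn candidate, with
measurement options exclusive across variables. High-weight children are
selected by a systematic-scan Gibbs sampler over these variables (all unique
visited assignments are kept, the feasible all-survive/all-miss assignment
is the start); child weights are then computed exactly from the model
factors, duplicates merged by summing, and the mixture truncated to the
`h_max` heaviest hypotheses and renormalized. All weights live in the log
domain with log-sum-exp normalization.

The sweep budget per update is shared across parent hypotheses in
proportion to their weights (at least one sweep each). The default resolves
to `max(1000, 10 · n_variables · (|Z| + 2))`; the scenario drivers use a
fixed budget of a few hundred sweeps per frame, which on the simulated
scenarios recovers the enumeration posterior to within the tolerances the
oracle tests check.

For spawning, the daughter is generated from the parent's *posterior* at the
previous frame while the parent moves through the motion model, so the two
are correlated. The implementation forms the joint parent–daughter Gaussian
by an unscented pass through the pair map `x -> (f(x) + q, f_t(x) + q_t)`,
uses the daughter's marginal for the Gibbs proposal costs, and — for
selected hypotheses — performs the exact sequential joint update with
whatever measurements parent and daughter were assigned before keeping each
label's marginal. This returns the density to standard GLMB form every
frame. With nonlinear point observations the joint update falls back to
independent marginal updates; the cell experiments use linear position
observations, where the joint update is exact.

Measurement-driven birth places a candidate at frame k+1 on every frame-k
measurement with existence probability `min(cap, r0 · (1 − a_j))`, where
`a_j` is the posterior probability that measurement j was associated to some
track. The cap is `r_init ≈ 0.99` during the first `n_init_frames = 3`
updates (the very first update bootstraps from its own scan) and `1e-7`
afterwards. Holding the high cap for a short window rather than a single
frame means an object whose first detection is missed still enters as a
birth rather than being forced into a spurious spawn or lost; the mass
weighting prevents duplicate births for already-tracked objects.

## Multi-scan estimator

After each update the MAP estimate is taken: the cardinality distribution
`rho(n)` sums hypothesis weights by label-set size, `N̂ = argmax rho` (ties
to the smaller cardinality), and the heaviest hypothesis with `N̂` labels
(ties by insertion order) is selected. Its tracks are converted to
trajectory tuples (label, birth frame and state, association history) and
merged into the accumulated set: present labels are replaced wholesale
(full-history rewrite), new labels appended, absent labels retained. At the
end of the sequence, tuples shorter than `tau_t` frames (default 3) are
pruned unconditionally, then each surviving tuple is forward-filtered from
its stored birth state — Kalman for linear models, unscented for
constant-turn or bearing-range — using the associated measurement when the
history says detect and prediction only on miss frames, and finally smoothed
backward.

The backward pass is the Rauch–Tung–Striebel recursion with gain
`D = P_k F^T (P̄_{k+1})^{-1}` for linear dynamics, and its unscented
variant (gain = state/prediction cross-covariance times inverse predicted
covariance, sigma points over the augmented state-plus-noise space) for
nonlinear dynamics. The final frame's smoothed moments equal the filtered
ones. Because each label is estimated as one contiguous trajectory, the
output is fragmentation-free by construction — the package asserts this on
every CLI run.

## Smoothing numerics

Unscented parameters default to alpha = 1, beta = 2, kappa = 3 − n, which
keeps sigma-point weights well conditioned for the ≤ 7 augmented dimensions
used here; they are configurable. Covariances are symmetrized after every
update and smoothing step, measurement updates use the Joseph form, bearing
innovations are wrapped to (−pi, pi] (with a circular mean for the predicted
bearing), Cholesky factorizations retry with growing jitter, and a singular
predicted covariance in the smoother falls back to a regularized inverse
with a warning. Constant-turn transition entries use series limits below
|w·dt| = 1e-10 so the w → 0 case reduces exactly to constant velocity.

## Evaluation

OSPA with cutoff `c` and order `p` scores per-frame point sets; the
assignment is solved exactly by the Hungarian algorithm and the reported
total splits into localization and cardinality parts, each bounded by `c`.
OSPA(2) scores *tracks*: the base distance between two tracks at frame k
averages the per-frame cutoff distance over the trailing `w`-frame window,
charging `c` on frames where exactly one exists, and the OSPA construction
is applied over the two track sets (tracks absent from the whole window are
excluded). Defaults are p = 1, w = 10, c = 100 m for the radar-scale
scenarios and c = 10 px for image scenarios; distances use position
components only, with bearing-range tracks compared in Cartesian
coordinates.

Division recovery is scored event-locally, in the spirit of the Cell
Tracking Challenge lineage measures: a true division counts as correctly
recovered when a spawn-labelled track starts within 3 frames of the true
daughter's birth, follows the daughter over its first frames (mean distance
below 30 px), and its decoded parent lies within the same distance of the
true parent just before the division. Scoring locally means a later
identity drift of either track does not disqualify a correctly detected
division; divisions whose daughters live fewer than `tau_t` frames are
excluded from the denominator because the pruning rule removes any track
that short by construction.

## Synthetic scenarios

The generators provide statistical, not pictorial, fidelity: birth sites,
noise levels, detection and clutter rates follow the configured scenario
values, while the actual paths come from a scripted birth/death schedule
with sampled initial velocities.

* **Linear**: constant-velocity objects on [−1000, 1000] m², `sigma_v` =
  5 m/s, position detections with `sigma_eps` = 15 m, `p_d` = 0.95, `p_s` =
  0.99, 66 clutter points per scan, four birth sites, 12 scheduled tracks
  over K = 100 frames, initial speeds N(0, 8² m²/s²) per axis.
* **Constant-turn**: five-dimensional state with turn rate, `sigma_w` =
  pi/180 rad/s, bearing-range detections (`sigma_theta` = pi/90,
  `sigma_r` = 5 m) over a half-disc of radius 2000 m; clutter uniform in
  (bearing, range); bearing measured clockwise from the +y axis.
* **Image / track-before-detect**: constant velocity on a 100×100 pixel
  grid, blobs with `sigma_h` = 4 px and per-object SNR drawn uniformly from
  7–10 dB, where SNR(dB) = 20 log10(peak/`sigma_y`) — an explicit,
  invertible convention for setting the blob intensity; the filter-side
  model fixes 10 dB. Point detections come from hard thresholding at 0.4 ×
  the 10 dB noiseless peak, keeping 8-connected components of at least 5
  pixels (the area floor suppresses single-pixel noise excursions) and
  reducing each to its intensity-weighted centroid; 10 uniform clutter
  points per scan are appended to the extracted set rather than painted
  into the images.
* **Cell**: four founding cells placed at least 100 px apart on a 400×400 px
  field (a sparse early-stage culture), per-frame survival 0.999 and
  division 0.035, daughters at N(parent, `Q_t`) with the diagonal spawn
  covariance (400, 5, 400, 5, pi/90) read in interleaved order,
  detections with `p_d` = 0.88, `sigma_eps` = 2 px, clutter rate 0.05, and a
  live-population cap of 20 with a warning. True cell kinematics use gentle
  constant-turn noise (0.5 px/frame² velocity, pi/90 turn) — much smaller
  than the tracker's deliberately loose model noise of 5 px/frame², which
  is there to absorb model mismatch, as is standard when the assumed
  dynamics only approximate real cell motion.

Printed state vectors and diagonal covariances that interleave position and
velocity are converted to the canonical [px, py, vx, vy, w] ordering by
`interleaved_to_canonical`.

What passing tests on these generators show: the filter, estimator, and
metrics behave correctly under the stated statistical conditions. What they
do not show: robustness to real-microscopy nuisances (uneven illumination,
touching or overlapping cells, segmentation artefacts) or to detector noise
that is not Bernoulli/Poisson/Gaussian.

## Problem sizes and settings used in the shipped experiments

The desk-scale experiments run 100-frame linear scenarios with `h_max` =
1000 and a 300-sweep Gibbs budget per frame, and 50-frame cell scenarios
(≤ 20 cells) with `h_max` = 800 and 600 sweeps; the truncation-bound check
runs 10 frames at the full `h_max` = 20,000 with the default sweep formula.
These sizes make a full multi-run study reproducible on a single CPU while
leaving the algorithms identical at larger settings.

## Known limitations

* Identity switches across close encounters are possible and inherited by
  the estimator; the trajectory-tuple update never deletes a stale label,
  so a switch can leave a duplicate (overlapping) track in the output — the
  multi-scan estimator removes fragmentation, not identity errors.
* Division-parent attribution degrades when several relatives crowd within
  the spawn placement scale: with a 20 px positional spawn spread and slowly
  drifting cells, a multi-generation family occupies a ~50 px neighbourhood
  after a few divisions, and a daughter's true parent is then only weakly
  identified by a single frame of evidence. Per-run parent accuracy on the
  synthetic cell scenario consequently varies from the high 90s% on sparse
  runs down to ~60–70% on heavily clustered runs (averaging roughly 85–90%);
  the wrong choices are almost always an adjacent relative.
* The estimator trusts the final MAP hypothesis; if forward filtering is
  badly wrong, smoothing will polish the wrong trajectory.
* Pruning is unconditional, so genuine tracks shorter than `tau_t` frames
  (e.g. divisions at the sequence end) are removed; `tau_t` is configurable.
* Only one offspring per parent per frame is treated with the exact joint
  parent–daughter update; additional simultaneous offspring are handled
  marginally.
* The separable image likelihood assumes non-overlapping templates; merged
  or occluded blobs violate it.
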