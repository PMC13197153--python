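# Methods

This note records the models, conventions and numerical choices behind
`gazedyn`, and what the synthetic-data validation does and does not show
about real recordings.

## Geometry and signal conventions

**Heading.** Head direction per overhead-camera frame is the signed angle
at the neck-center landmark between the neck→nose ray and the
neck→monitor-center ray, computed as `atan2(cross, dot)` of the two
vectors in image coordinates. The overhead image y-axis points down; with
the monitor at the top of the image this makes a nose rotated toward the
animal's right positive, so rightward port choices end at positive heading
and leftward at negative. The result lies in (−180°, 180°]. Coincident
landmarks raise an error rather than returning a value.

**Eye position.** The eye camera reports pupil- and eyelid-ellipse
parameters. We use a spherical-eye model: the eyeball diameter is
approximated by the eyelid-ellipse major axis, and the horizontal
eye-in-head angle is `arcsin(dx / r)` with `dx` the horizontal pupil-center
displacement from the eye-ellipse center and `r` half the major axis.
This is the simplest mapping consistent with treating the major axis as
the eyeball diameter; the true pixel→degree mapping of any particular rig
is unknown without calibration, which is impossible in a non-head-fixed,
non-fixating animal. Displacements beyond the radius are clipped to ±90°
and flagged. Only horizontal direction and timing are analyzed; absolute
eye-in-head position is not trusted. Pupil size is the pupil-ellipse major
axis, in pixels.

**Likelihood masking.** A frame is invalid if *any* required landmark's
tracking likelihood is below 0.9 (configurable). Masked frames are
dropped from every downstream statistic — never interpolated — because
interpolation across tracking failures would manufacture kinematics.
Filtering is idempotent and monotone in the threshold.

**Two clocks.** The overhead camera runs at 70 or 80 Hz, the eye camera at
80 Hz. All per-frame analyses run on each stream's native grid; only gaze
composition g(t) = θ(t) + e(t) resamples, by nearest neighbour within half
a head-frame period, since no principled interpolation rule exists for
discontinuous saccadic traces. Trials are re-referenced so t = 0 at
stimulus onset, with a 500 ms pre-onset baseline; trial segments are
disjoint (each ends where the next trial's baseline begins).

## Decision time from choice predictivity

At each post-onset frame, the signal values of all included trials are
scored for how well they separate eventual right from left choices, as the
area under the empirical ROC curve over all cut points. We compute it by
the rank (Mann–Whitney) identity with midranks for ties, which equals the
brute-force pairwise count P(x_R > x_L) + ½P(tie) exactly; the test suite
asserts this equivalence to 1e-12 on random tied data, and cross-checks
against scikit-learn's reference ROC implementation.

The decision time is the timestamp of the first frame of the earliest run
of two consecutive frames with AUC strictly above 0.875. Two readings of
"the first video frame after which AUC was above the criterion for two
consecutive frames" are defensible — the first frame of the qualifying
pair, or the frame after it — and we default to the first frame of the
pair, with `report_following_frame=True` exposing the other reading. The
crossing is strict (AUC exactly at the criterion does not qualify). Bins
where either choice class has fewer than two valid trials are undefined
and can neither start nor continue a qualifying run. The analysis window
used by the turning and saccade stages is twice the time for the AUC to
reach 0.95 (single-frame crossing); if 0.95 is never reached the pipeline
falls back to a configurable window and flags it.

By default the AUC pools all completed trials. The alternative of using
correct trials only is exposed as `correct_only=True`; with a generator
whose signal tracks the *chosen* side the two differ only in trial counts.

The psychometric criterion duration (display duration at 0.82 proportion
correct) is obtained by linear interpolation of the across-session mean
curve at its first upward crossing; no parametric sigmoid is imposed,
since none is warranted by a handful of duration levels. A curve that
never reaches the level is flagged instead of extrapolated.

## Turning time by bilinear changepoint regression

Each trial's heading inside the analysis window is fit with a continuous
two-segment linear model `y = b0 + b1·t + b2·max(t − c, 0)`; for each
candidate breakpoint `c` on the frame grid (at least two frames from each
window edge) the coefficients are solved by least squares, and the
candidate with minimal SSE is the turning time, ties broken toward the
earliest. Continuity at the breakpoint is enforced — two meeting lines —
and sub-frame refinement is not attempted, since the comparison statistics
are frame-resolution anyway. Masked frames are omitted from the least
squares; trials with fewer than five valid frames are flagged invalid and
excluded from timing statistics. The bilinear model nests the single line,
so its SSE never exceeds the best single-line SSE; a contrast ratio
(line SSE / bilinear SSE) below 1.05 flags "no clear turn", and flagged
trials are retained but marked. Trials sharing a complete common grid are
solved in one batched pass per candidate (identical results to the
per-trial path, asserted in tests).

Turning times are compared against the dataset decision time with a
one-sample two-sided *t* test (the decision time is a single number per
dataset); a zero-variance sample reports the exact comparison without a
*t* statistic.

## Saccade detection

Velocity is the five-video-frame smoothed differentiator
`v_n = (e_{n+2} + e_{n+1} − e_{n−1} − e_{n−2}) / (6Δt)` (62.5 ms at
80 Hz), and acceleration is the same operator applied to the velocity.
Plain central differences were rejected as too noise-sensitive at
fixational noise levels. The kernel is undefined at the two-frame margins
and anywhere its window touches a masked frame.

Candidate periods are maximal runs of frames with speed strictly above
30°/s; a period becomes a saccade iff its peak absolute acceleration
exceeds 2,000°/s² and the distance between the eye positions at its first
and last frame exceeds 0.5°. Saccade onset is the first frame of the
period; mean pupil size is averaged over the period. Events with peak
speed above 200°/s violate the linear main sequence and are excluded but
counted. Adjacent runs separated by a single sub-threshold frame are not
merged. Trials with ≥20% masked eye frames inside the analysis window are
dropped from saccade statistics (an automatic stand-in for manual
exclusion of unreliable tracking).

Detector quality control fits an ordinary least-squares line to
(amplitude, peak velocity) over retained events and reports the slope,
intercept and r; with fewer than three events the QC is skipped with a
notice.

**A frame-rate-imposed amplitude floor.** The smoothed kernel bounds what
the detector can measure: an instantaneous position step of amplitude A
yields at most ≈27·A °/s of measured peak velocity at 80 Hz, and applying
the kernel twice caps measured peak acceleration at a few hundred
(°/s²)/deg. Consequently the 2,000°/s² threshold implies that saccades
below roughly 5° of amplitude are undetectable at these settings,
whatever their true kinematics. This is a property of the thresholds and
frame rate, not of any particular implementation, and it shapes the
synthetic data (below).

The largest saccade per trial maximises |signed horizontal distance| among
retained events in the analysis window. Its signed distance is scored for
choice predictivity with the same AUC engine, its onset is compared with
the same trial's turning time by a paired two-sided *t* test, and saccade
counts on correct versus incorrect trials are compared by rank-sum.

## Bias analyses

Onset values are taken at the frame nearest t = 0 (within half a frame
period; trials with a masked onset frame are excluded). Eye values are
normalized per trial by subtracting the mean valid pre-onset value over
the 500 ms baseline. Grouping by the current trial's choice gives the
onset bias; grouping by the previous trial's choice gives the
history (stay/switch) bias, with a switch index positive when onset
heading points away from the previously chosen side; the first trial of a
session has no history label and is excluded there. The default
comparison is the two-sided Wilcoxon rank-sum test with tie correction
(the grouped distributions need not be Gaussian); an unpaired *t* test is
available via `test="t"`. No multiple-testing correction is applied
anywhere. Grouped summaries report mean ± SD per choice group at the
onset frame, at the dataset-level decision-time frame (one frame index
for all trials) and at each trial's own turning-time frame.

## The synthetic-session generator

The generator emulates the statistical structure the analyses assume, with
per-trial ground truth, and its defaults are the study conditions used by
the validation suite; they were chosen once, from the recorded behaviour
this paradigm produces, and are not tuned per test.

Per trial: the correct side is a fair coin (or, in `switch_mode=
"sequence"`, flips from the previous choice with probability
`switch_bias`); the choice matches the correct side with probability
`accuracy` (default 0.75, matching recorded accuracies of 72–79%).
Heading starts at an onset level drawn with SD 4°, whose mean is shifted
0.75° toward the eventual choice and 0.75° away from the previous choice
(onset separations of ~1.5°, the recorded scale); from stimulus onset it
drifts toward the choice at 8°/s, and from the trial's true turning time —
drawn from N(300, 110²) ms and snapped to the head-frame grid — it ramps
at 45°/s toward the signed ±30° port angle, clamped there, with 2° white
frame noise. The drift term matters: recorded heading is already ~10–15°
apart between choice groups at the decision time, *before* the mean
turning time, which a strictly flat pre-turn segment cannot produce; with
it, the criterion crossing lands near 280 ms and the analysis window near
720 ms, inside the recorded ranges. The slow ramp keeps the port plateau
outside the analysis window for almost all trials, so the trace the
bilinear fit sees is genuinely two-segment and breakpoint recovery is
well-posed by construction (a hard plateau inside the window drags the
fitted breakpoint toward the ramp's end; the validation demonstrates
this regime is avoided).

Eye traces are fixational white noise (0.1°/frame) plus injected
raised-cosine position steps: one large choice-directed saccade at
turning time + N(+40, 150²) ms, an optional counter-directed compensatory
saccade (probability 0.5), and Poisson-distributed smaller saccades of
random direction. Saccade durations are calibrated against the detector's
own kernel: for an N-frame raised-cosine step the measured peak velocity
is a fixed multiple κ(N) of the amplitude, so the generator picks the N
whose κ best matches the requested main-sequence slope (default
20 (°/s)/°, giving N = 5 frames and an effective slope κ ≈ 19.5) and
records the effective slope in the ground truth. All injected amplitudes
sit above the kernel-imposed detection floor (~5°; mean largest amplitude
7°), because retained saccades in any real session at these thresholds
necessarily satisfied the same constraint; the largest saccade outranks
the others by a fixed margin so ground-truth pairing is unambiguous.
An `oversize_fraction` injects saccades beyond 200°/s to exercise the
main-sequence exclusion.

Pose landmarks are back-computed from the intended heading (nose at a
fixed distance from a fixed neck point, rotated by θ in image
coordinates), so the heading geometry inverts them exactly (asserted to
1e-6°); pupil/eyelid ellipses are back-computed through the inverse of
the arcsin mapping. Trial slots are multiples of 100 ms so stimulus
onsets land on both the 70/80 Hz head grid and the 80 Hz eye grid. An
optional `wander_prob` adds a premature-turn-and-reorient excursion
(triangular, toward the wrong side, peaking halfway to the turning time);
its shape is our invention and it is off by default. A
`dropout_fraction` marks random frames low-likelihood to exercise the
masking path. Everything is reproducible bit-for-bit from the seed.

**What the generator does not emulate:** locomotion of the animal through
the box (the neck point is fixed; heading is the only pose signal), camera
perspective distortion, slow drifts or autocorrelated tracking noise,
vestibulo-ocular eye movements coupled to the head turn, blinks, and
pupil-size dynamics (pupil is white noise about a baseline). Passing
validation therefore shows the *analysis* is correct and well-calibrated
under the assumed signal structure, not that the assumed structure
captures every property of real recordings.

## Validation problem sizes

The validation suite runs the AUC oracle equivalence on 200 random
datasets; bilinear recovery on 500 noisy traces (2° noise, turning times
N(300, 110²) ms, median breakpoint error ≤ 1 frame); saccade
injection/recovery on a 500-trial session; the decision → turning →
saccade ordering and lag recovery across 50 replicate 600-trial sessions;
null calibration of the bias tests across 500 replicate 150-trial
sessions (replicate count matters for a rejection-rate estimate, trial
count only sets per-test power, so smaller sessions are used there); and
full-pipeline mirror symmetry on a 300-trial session.

## Known limitations

- The pixel→degree eye mapping is a model choice; absolute eye angles
  carry that model's error, though directions and timings do not.
- The decision-time rule's "first frame of the pair" reading is a
  documented choice between two defensible readings (both implemented).
- With long analysis windows and fast head ramps, a post-turn plateau
  inside the window biases the bilinear breakpoint late; the fit reports
  the contrast ratio so such trials can be recognized, but no correction
  is applied.
- The saccade detector cannot see saccades below the kernel/threshold
  amplitude floor (~5° at 80 Hz); real compensatory saccades smaller than
  that are invisible to it, exactly as they would be in a real session
  analyzed at these settings.
- Sessions are assumed pre-synchronized to a common clock; no clock
  alignment is performed.
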