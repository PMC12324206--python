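# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `kinesig`.

## Data model and file handling

Trials are `KinematicsRecording` objects: a strictly increasing time vector
(s), marker trajectories (m, ground-fixed frame, Y-up by default and
configurable per file since TRC headers do not encode axis semantics), and
joint angles (degrees). Sampling rates below 60 Hz are rejected. NaN gaps up
to 0.1 s are linearly interpolated at read time; longer gaps reject the
trial — short dropouts are routine in keypoint-based capture, long ones are
not recoverable. TRC files in mm or m are normalized to meters; MOT/STO
angle files in radians (header `inDegrees=no`) are converted to degrees.
Writers emit 10 decimal places so read–write round trips are lossless to
1e-9.

## Filtering

All event-detection signals pass through a zero-phase low-pass Butterworth
filter (order-2 sections run forward and backward, i.e. 4th order overall):
6 Hz for walking, TUG, sit-to-stand and calf-raise signals, 12 Hz for
running and jumping — standard biomechanics cutoffs for those movement
tempos. Two quantities deliberately avoid the filtered signal: the swing
ankle-elevation integral and its stance baseline use the raw trajectory,
because a zero-phase filter leaks bump area into stance and undershoots
beside it, biasing small clearances by several percent (averaging over the
swing window is itself a smoother, so no filtering is lost).

## Gait events

Heel strike is detected at local maxima of the heel's anterior position
relative to the pelvis center; toe off at local minima of the relative toe
position — the standard coordinate-based detector. The anterior axis is the
net horizontal pelvis displacement (requiring ≥ 0.2 m of genuine travel;
below that a default axis is used, since jitter-scale displacement has a
meaningless direction). Peak candidates need a prominence of 30% of the
signal's 5th–95th percentile range (scale-free, robust to body size);
candidates within 0.1 s are merged keeping the more prominent. Peak times
are refined to sub-frame precision by intersecting line fits on the two
flanks of the peak: between events the relative foot position is piecewise
linear in time, so the event is the apex of a filter-rounded asymmetric
triangle, and flank intersection locates it without the bias a symmetric
parabola fit would have on unequal slopes.

Sanity checks turn degenerate input into errors rather than silent output:
fewer than two heel strikes on a side, a stride interval without exactly one
toe off (alternation), mean swing not shorter than mean stance, or a toe
posterior of its heel along the direction of travel (which is how
time-reversed input manifests when the travel axis is inferred from the
data).

## Chair-task segmentation

The COM proxy is the mean of the four pelvis markers, which tracks
whole-body COM closely for chair rises, jumps and gait; the marker set is
configurable. A sit-to-stand repetition runs from a COM-height minimum
through the following prominent maximum to the next minimum. Interior
boundaries are exact minima between consecutive peaks. The two outer
boundaries are located by a sqrt-parabola vertex fit on the rising/falling
edge (fit over the 2–15% amplitude band): near a smooth minimum the height
is quadratic in time, so sqrt(height − baseline) is linear and its intercept
estimates the boundary without the ~0.1 s bias any fixed-threshold crossing
has at a quadratic tangency. When five repetitions are expected (5×STS), the
five most prominent rises are kept in time order. TUG onset/offset use the
declared convention of crossing 10% above the seated baseline; these rules
are conventions, not claims of equivalence with clinician chair-contact
timing — a systematic offset between the two is expected and is exactly what
the LOSO calibration absorbs.

Calf raises are counted as prominence-qualified peaks of mean heel height
over a 30 s window (shorter trials count over what exists, with a warning).

## Features

The registry ships 17 features named or defined in the clinical literature
on these activities (walking ×4, running ×2, TUG time, 5×STS time, Brooke
analog, reachable area, elbow/shoulder ROM, jump ×2, calf raise ×3), each
tagged upper- or lower-limb, and is user-extensible. Length features are
normalized by participant height. Design choices worth noting:

- **Steady-state gait window** excludes the first and last pooled stride
  (acceleration/deceleration at the field-of-view edges).
- **Swing ankle height** is the mean elevation of the ankle marker above its
  stance-phase baseline over the swing phase (toe-off → next ipsilateral
  heel strike); the per-swing peak is also computed and exported as
  `..._peak`, the mean being the default. The stance baseline is the median
  of mid-stance samples rather than the minimum, which is noise- and
  undershoot-sensitive. The integral is taken over a 2-frame-padded window
  and divided by the true swing duration, which conserves the lift area.
- **Brooke analog**: elbow flexion is read at the frame of peak shoulder
  abduction (its clinical meaning is elbow flexion *during* overhead reach),
  with a 1° floor to keep the ratio bounded; the better side is reported.
- **Reachable area** is the frontal-plane convex-hull area of all wrist
  marker positions, normalized by height² — a 2D analog of reachable
  workspace, not the 3D relative-surface-area metric.
- **Imputation**: participants without calf-raise or jump trials get zeros
  with an `imputed_<name>` flag (inability is informative); a missing trial
  for any other activity, or an extraction failure, excludes the
  participant-session with a logged reason — never a silent zero.

## TFT surrogates and calibration

Walk/run surrogate time = 10 m / measured gait speed; TUG and 5×STS
surrogates are the segmented task durations. Each TFT gets its own
ordinary-least-squares line (with intercept — a surrogate has both scale and
offset error) fit per LOSO fold on all other subjects and applied to the
held-out one; Pearson r and MAE are computed on the pooled held-out
predictions, and subjects missing either member of a pair are dropped with a
logged count. MAE is compared against published distribution-based MCIDs
(walk 0.69 s and TUG 0.92 s for myotonic dystrophy; run 2.3 s from Duchenne
muscular dystrophy; none exists for 5×STS), using strict `<`.

## Statistics

- **Balanced accuracy** = mean of per-class recalls; 0.5 for any constant
  predictor on two classes.
- **McNemar**: exact two-sided binomial (p=1/2) on the discordant counts
  when n01+n10 ≤ 25, χ² with continuity correction above; (0,0) → p = 1.
- **KS**: `scipy.stats.ks_2samp`, exact for min(n,m) ≤ 25 else asymptotic;
  ECDF differences are evaluated at all pooled points, so ties are handled.
  Note the two-sample KS test is discretely conservative: its attainable
  size at nominal 5% is ≈ 3.5% at n=30 per group (asymptotic path) and
  ≈ 2.3% at n=15 (exact path) — relevant when interpreting null rejection
  rates.
- **Bonferroni**: min(1, p × n_features); bare p-values are reported for
  exploration, never used as pass/fail surfaces.
- **ICC**: single-measure absolute agreement from the two-way mean squares,
  (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)). The "two-way
  mixed, absolute agreement, single measurement" naming straddles the
  ICC(2,1)/ICC(3,1) conventions; this formula (ICC(A,1)) is the declared
  one and is cross-checked against pingouin in the tests. Categories use
  the 0.5 / 0.75 / 0.9 cut-points.

## Classification and importance

A linear SVC per binary task (FSHD-vs-DM for disease separation; FSHD-vs-CTL
and DM-vs-CTL for importance), leave-one-subject-out: standardization
statistics come from the training subjects only; the regularization
parameter is selected per outer fold by inner stratified 3-fold CV over 7
values log-spaced 1e-3…1e3, maximizing balanced accuracy with ties broken
toward stronger regularization; only session-1 data enter classification.
Feature importance is the closed-form linear SHAP value
w_j · (x_j − mean of the standardized training background), computed on the
decision-function scale — a hinge-loss classifier has no native probability,
and a monotone link preserves the mean-|SHAP| ranking either way. Local
accuracy (base value + Σ contributions = decision score) holds to 1e-8 and
the closed form is verified against exhaustive Shapley enumeration in the
tests.

## Synthetic cohort generator

Trajectories are analytic (piecewise sinusoid/linear/ballistic), not
biomechanically simulated: the design goal is that every extracted feature
equals a planted, recorded value, which makes parameter recovery, effect
faithfulness and null calibration testable. Specifics:

- **Gait**: the pelvis translates at the planted speed; each foot is
  stationary through stance (duty factor 0.6 walk / 0.55 run) and advances
  one stride length linearly during swing, so the planted heel-strike and
  toe-off instants coincide exactly with the coordinate-based detector's
  definition; ankle lift is a half-sine of the planted clearance (mean
  2c/π over swing, recorded as the ground-truth mean swing height).
- **Chair tasks**: 5×STS is five abutting cosine rise–return cycles with the
  planted total duration; TUG's elevated span is sized so that the
  10%-threshold crossing interval equals the planted time (the ground truth
  is defined at the declared onset convention). The jump is a quiet stand,
  countermovement dip, quadratic push ending at takeoff velocity
  √(2·g·apex), and a ballistic flight to the planted apex.
- **Group effects** (multipliers on stride length, speeds, chair-rise time,
  jump height, calf-raise count; additive swing clearance; shoulder-abduction
  maximum and elbow-flexion compensation in degrees; probability of being
  unable to perform ankle tasks) encode the qualitative disease picture —
  FSHD: shorter strides, elevated swing foot lift, proximal upper-limb
  impairment; DM: slowed chair rise, reduced jump and plantarflexor
  performance, similar gait speed to FSHD. The default magnitudes are
  package constants chosen for clinical plausibility; they are **not**
  measured values.
- **Variability and noise**: between-subject lognormal spread (σ = 0.12) on
  performance parameters; i.i.d. Gaussian marker jitter (4 mm) and angle
  jitter (1°); stopwatch noise on human TFT times (SD 0.15 s, reaction-time
  scale) plus small constant offsets for chair-contact vs COM timing; an
  ordinal Brooke grade derived from the planted shoulder/elbow ratio through
  a noisy grader (lognormal σ = 0.25 on the ratio before thresholding at
  4 and 15). Sex is assigned deterministically at fixed per-group female
  fractions; ages, heights and BMIs are drawn from group-typical normals.
- **Retest**: the first `n_retest` DM participants receive a session-2 copy
  of the *same* subject with independent multiplicative day effects
  (σ = 0.05) on each performance parameter — anthropometrics fixed.
- **Determinism**: all draws descend from one seed through spawned
  substreams; identical config + seed reproduce output files byte for byte.

What the generator does **not** emulate: soft-tissue artifact, correlated
(non-white) keypoint noise, pose-estimation dropout structure, turning gait,
fatigue within a trial (except the planted calf-raise decay), or realistic
inter-feature correlations beyond those induced by shared parameters.
Passing tests therefore demonstrate that the pipeline recovers what its
input contains and that its statistics are calibrated — not that any
specific clinical effect size will be observed in recorded data.

## Numerical choices and degenerate inputs

Event ties within 0.1 s keep the more prominent candidate. A flat COM
trajectory (range < 1 mm) is a segmentation error; a degenerate wrist point
cloud yields reachable area 0 rather than a hull failure. Zero surrogate
variance in a calibration fold and classes too small for inner
stratification raise typed errors with remedies. Problem sizes in the test
suite are chosen to keep the full run in a few minutes: parameter recovery
uses a 30-participant noise-free cohort, calibration uses 20 null cohorts of
30+30, and the directional classification contrast uses an 86-participant
cohort at the study's FSHD/DM proportions.

## Known limitations

- The feature registry covers the 17 features definable from first
  principles for these activities; it does not claim equivalence with any
  particular published 34-feature panel, and is designed to be extended.
- The reachable-area analog is 2D (frontal plane), not the 3D
  relative-surface-area reachable workspace.
- TUG/5×STS onset–offset rules are declared conventions; absolute surrogate
  times differ systematically from clinician chair-contact timing and are
  only meaningful after calibration.
- SHAP importances are on the decision-function scale, not probabilities.
- The trivial 50% balanced accuracy of a constant predictor is exact only
  for two-class problems.
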