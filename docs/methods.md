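# Methods

## The problem

When two people jointly control one virtual body whose hand is the mean of
their two hands ("shared avatar"), the avatar's reaching kinematics can
improve for two very different reasons: (a) averaging two noisy signals
reduces noise, with nobody changing their behavior; or (b) the two people
genuinely change how they move in order to optimize the avatar's movement.
This package implements the full analysis that separates the two: a
synthetic dyad-reaching generator, the averaging avatar model, the
per-reach kinematic statistics, and the repeated-measures statistical
battery, run end-to-end.

## Kinematic statistics

All statistics are defined per reach, over the window from target
appearance to target touch (first sample of the hand inside the
axis-aligned target cube):

* **Reach deviation `D`** (m): hand path length minus the straight-line
  distance between the first and last sample. Zero for a straight reach;
  invariant to rigid motion and time reparameterization.
* **Mean hand jerk `J`** (m s⁻³): time-average magnitude of the numerical
  third derivative, computed as the third finite difference of position
  divided by dt³. The two boundary estimates receive 1.5 samples of extra
  weight so the average covers the whole reach; the estimator is exactly
  zero for constant-velocity and constant-acceleration motion and matches
  quadrature of the closed-form minimum-jerk profile to <0.5% at 1 kHz
  (a few percent at the simulation's native 100 Hz).
* **Reaction time `RT`** (s): first time hand speed (central differences)
  strictly exceeds 10% of its within-trial maximum, minus target onset.
  On a noiseless minimum-jerk reach this crossing sits at 8.65% of
  movement time past movement onset — a fixed offset that cancels in
  condition contrasts.
* **Task time `TT`** (s): target onset to touch.
* **Target error `TE`** (m): distance from the segmented endpoint (the
  touch sample) to the target center. Because the trial ends at cube
  entry, `TE` has a geometric floor of about half the cube edge; aim
  scatter and divergence raise it above that floor.
* **Inter-participant distance `IP`** (m): time-average distance between
  the two members' hands from the common target onset to the later touch,
  holding the earlier finisher at its final position (an
  `earlier_touch` window is available as an option). Reported overall and
  over three equal-duration phases; the overall value equals the
  duration-weighted mean of the phase values by construction.

Aggregation units follow the design: kinematic statistics are averaged per
participant, then per dyad (the avatar contributes one value per dyad;
n = dyads), while embodiment ratings stay at the participant level
(n = participants).

## The avatar model

The avatar hand is the pointwise mean of the two members' hand positions
on a common uniform time base (linear interpolation onto the intersection
of supports, anchored to the first member's sampling phase, no
extrapolation). Averaging is done in Cartesian hand space — every analyzed
quantity is a hand statistic — with equal weights; a weight parameter
exists for extensions and a least-squares estimator recovers the weight
from data (50% under equal averaging, used as a self-check).

## The synthetic dyad generator

The generator produces the study's statistical structure without any
recorded data: 10 dyads (20 participants), two conditions (solo, shared),
4 sessions per condition alternating in counter-balanced order (half the
dyads start solo), 15 reaching trials per session, sampled at 100 Hz.
Targets are cubes (default edge 0.12 m) drawn uniformly from a frontal
workspace box; both members reach from a common rest position to the same
target.

Each human reach is a straight minimum-jerk transport plus three terms:

1. **Bow**: an idiosyncratic lateral curvature, direction fixed per
   participant (scattered around a population-level direction, as
   right-handed reachers curve in broadly similar ways), amplitude
   `curvature_amp` (default 1.5 cm) jittered ±30% per trial, time profile
   sin²(πτ) so velocity is continuous at movement onset.
2. **Signal-dependent motor noise**: stationary noise built from white
   noise through three cascaded first-order low-passes (time constant
   `noise_smooth_tau` = 50 ms) — three poles, so the numerical third
   derivative is finite and jerk is not dominated by the sampling period —
   scaled by the normalized base speed profile (`noise_sd` = 2 mm at peak
   speed). The hand is therefore quiet at rest and at the endpoint.
3. **Cooperative strategy (shared condition only)**: the bow is scaled by
   (1 − `strategy_gain`) and the noise amplitude by
   (1 − `strategy_gain`/2) — partners straighten and steady their own
   commands to make the avatar's path mutually predictable — while an
   anti-correlated divergence term ±`divergence_amp`·w(τ) (default
   4.5 cm) pushes the two hands apart and endpoint aim scatter is
   multiplied by `te_inflation` (default 1.5). The divergence carries
   opposite signs for the two members, so it cancels exactly in the
   avatar; with `strategy_gain` = 1, zero divergence and zero noise the
   avatar reproduces the straight minimum-jerk path exactly, and with
   `strategy_gain` = 0, zero divergence and `te_inflation` = 1 the shared
   condition is sample-for-sample identical to solo under the same seed
   (the "averaging-only null", available as `averaging_null_config`).

The divergence weight w(τ) is a smoothstep ramp saturating at
`divergence_ramp_end` = 0.75 of movement time. A profile that keeps
growing to the end concentrates its effect in the part of the reach the
touch rule clips away (the hand enters the cube at roughly two-thirds of
movement time), so saturating before touch is what lets the between-hand
divergence appear in the second and third movement phases while endpoints
remain touchable. The ramp is monotone, so divergence still peaks late.

Timing: per-trial reaction times are Gaussian around a per-participant
mean (0.30 ± 0.05 s within, ±0.02 s between participants), with half of
the trial-level variance shared by the dyad (the same stimulus drives
both). Reach durations are drawn once per trial (uniform 0.5–0.8 s) and
shared by both members up to ±0.02 s jitter, since both members reach to
the same target. These two choices keep the between-member timing lag —
which enters IP identically in both conditions — from swamping the
condition-specific divergence signal.

**Ratings.** Agency (0–100%) and ownership (−3..+3, integer) are drawn per
participant and condition. Shared-condition agency is centered below solo
agency and above 50%, and decreases with the participant's jerk change
(shared − solo) via a linear link on the standardized metric
(`rating_link_slope`, default 6 rating points per SD, noise
`rating_noise_sd` = 10 points); shared-condition ownership increases with
the dyad's avatar reach deviation through the same standardized link
scaled to the Likert range (slope/10, noise/10), then clipped and rounded.
The rounding necessarily introduces ties, so even a noiseless link yields
a rank correlation slightly below 1.

**What the generator does not emulate**: learning or fatigue across
sessions, joint-angle kinematics and arm posture, visual feedback delays,
target-dependent movement-time scaling (Fitts-like effects), and any
specific workspace geometry of the original apparatus — the workspace box,
capture rate and trial counts are the package's own choices where the
study conditions are not public. Passing tests therefore validate the
analysis machinery and the internal logic of the averaging-vs-cooperation
argument, not any quantitative claim about real motion-capture data.

## Statistical battery

Every analysis is gated by Shapiro–Wilk at α = 0.05 (scipy's Royston
implementation): normal data take the parametric branch, non-normal data
the rank branch. Three-level within-dyad analyses additionally require
Mauchly sphericity for the parametric branch (trivially satisfied at two
levels; skipped when not assessable).

* **Wilcoxon signed-rank** (paired and one-sample): zeros dropped before
  ranking, average ranks on ties, statistic reported as W⁺. Exact
  two-sided p for up to 25 nonzero differences by convolution over sign
  assignments (tie-aware via doubled ranks); tie-corrected normal
  approximation with continuity correction above. Effect size is the
  matched-pairs rank-biserial correlation (W⁺ − W⁻)/(W⁺ + W⁻), which is
  ±1 exactly when all nonzero differences share a sign.
* **Paired t** with Cohen's d_z = mean(diff)/sd(diff) (a `dav` convention
  is available; conventions differ in the literature and reported d
  values are not always reconstructible from t and n).
* **One- and two-way repeated-measures ANOVA** for balanced complete
  within-subject designs, each effect tested against its subject-by-effect
  interaction; partial η² = SS_effect/(SS_effect + SS_error), which
  satisfies η² = F·df1/(F·df1 + df2) within a model.
* **ART (aligned rank transform)**: for each effect, the response is
  aligned — residual about the factor-cell means plus the estimated effect
  of interest — ranked as one column (average ranks), and the RM F-test
  runs on the aligned ranks of that effect's own model. With one factor
  this reduces to the RM ANOVA on ranks of the raw data. η² for ART
  effects is computed on the aligned-rank sums of squares.
* **Post hocs**: all-pairs paired t with Holm step-down (parametric
  branch) or Tukey studentized-range contrasts on the aligned ranks (rank
  branch), both using the classical balanced-design error df
  ((k−1)(n−1)). Kenward–Roger degrees of freedom are deliberately not
  reimplemented: in balanced compound-symmetric within designs they
  coincide with the classical df, and the full mixed-model machinery they
  require is out of scope; the substitution is visible in the reported
  df. Tukey effect sizes use the model-standardized difference
  t·√(2/n); Holm rows use d_z = t/√n.
* **Correlations**: Pearson when both variables pass the gate, Spearman
  otherwise (exact p by permutation enumeration for n ≤ 9 without ties,
  t approximation above).

Empirical size of the Wilcoxon, paired-t, and one-way ART tests at
α = 0.05 is checked under Gaussian and centered-exponential nulls at
n = 10 and 20; all sizes fall within the binomial 99% CI of 0.05 computed
at 2000 replicates (the estimates themselves use 20000 replicates). Under
much heavier skew (e.g. lognormal with σ = 1) the paired t becomes
genuinely conservative at n = 10 (size ≈ 0.034–0.04) — a property of the
test, not of this implementation.

## Numerical choices and degenerate inputs

* Grids must be uniform to 1 ns; alignment snaps to the first input's
  phase and never extrapolates.
* The RT threshold uses a strict `>` and the first crossing; an
  identically zero trajectory raises a degenerate-sample error.
* Trials whose hand never enters the cube raise a no-touch error; the
  pipeline excludes them, counts them in the manifest, and drops the
  partner pairing for IP.
* Constant samples, all-zero difference vectors, singular contrast
  covariances, and incomplete designs raise specific errors rather than
  returning NaN; the battery degrades gracefully where a gate is not
  assessable (too few units → parametric default; < 2 sessions → the
  session ANOVA is skipped).
* CSV round-trips write 12 significant digits; the dt⁻³ jerk estimator
  amplifies text rounding, so analyze-mode reproduction of simulated
  metrics is exact to ~10⁻⁵ relative.

## Problem sizes

The default study conditions are 10 dyads × 2 conditions × 4 sessions ×
15 trials at 100 Hz (2400 human reaches plus 600 avatar reaches per run).
Monte-Carlo demonstrations (the averaging-only null and the cooperative
sign pattern) use 100 independently seeded runs at these sizes; type-I
calibration uses 20000 replicates per cell. One full pipeline run takes
about two seconds on a single core.

## Known limitations

* The generator's cooperative strategy is one concrete mechanism that
  produces the qualitative regime (straighter/smoother avatar, inflated
  shared-condition individual errors, late-phase divergence); it is not a
  model of how real dyads negotiate a joint trajectory.
* The battery covers the analyses of this design only — no covariates, no
  unbalanced designs, no Bayesian or equivalence testing.
* Two-way ART η² values are convention-dependent (aligned-rank SS of each
  effect's own model); published η² values computed on other scales will
  not match the F-identity.
* The `d` reported with Wilcoxon results is the rank-biserial correlation;
  the `d` reported with t results is d_z. Mixed conventions in published
  tables (e.g. a paired-t d incompatible with t/√n) cannot always be
  reproduced exactly and are not asserted.
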