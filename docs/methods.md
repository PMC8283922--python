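# Methods

This note documents the statistical models, conventions and numerical
choices behind `handclin`, and what its synthetic-data tests do and do not
demonstrate about real data.

## Conventions shared by all modules

All angles are MCP-joint flexion angles: neutral = 0°, flexion positive,
extension negative. The device workspace is [−30°, +60°] from neutral;
simulated positions are saturated to it and saturation events are logged.
Signals are trial-relative (t = 0 at stimulus onset, samples at k/fs,
fs = 1000 Hz by default). Each metric carries a direction-of-better
(`lower` for AE and RMSE, `higher` for velocity, ROM and force); every
orientation-sensitive statistic (AUC, z-scores, systematic shift) reads it
from one registry instead of duplicating sign logic.

## Task protocols and metric extraction

* **Tracking trajectories** are sums of three sines around 15°
  (slow: 0.03/0.07/0.13 Hz; fast: 0.10/0.20/0.40 Hz; 30 s per trial). The
  protocol's "15° amplitude" is read as the *total* excursion split equally
  across components (5° each) so the stimulus stays inside the workspace;
  `strict_amplitude=True` gives the literal 15°-per-component reading, with
  downstream saturation. This is a declared interpretation of an ambiguous
  protocol statement.
* **Position matching** presents the 21 integer angles 10–30° once each in
  a seeded random order. AE is the mean of the 21 absolute errors.
* **Fast reaching** uses fixed start/target pairs (−10°→30° flexion,
  30°→−10° extension, 4 s window). "Mean of the three maximum velocity
  values over all 10 trials per direction" is implemented as: one peak of
  the direction-rectified, low-pass-filtered velocity per trial, then the
  mean of the three largest per-trial peaks. Rectified-toward-target speed
  is used (reported velocities are positive per direction). No
  minimum-duration criterion is applied to the peak, since the protocol
  states none. Movement-onset detection is deliberately excluded from the
  primary metrics.
* **ROM** per repetition is max(position) − min(position); the metric is the
  mean over three repetitions. AROM > PROM is logged, not rejected.
* **Force** is the mean over three trials of the per-trial peak of
  direction-rectified fingertip force.
* **Tracking error** is the RMSE between displayed and performed trajectory
  over the full 30 s (no settling window), averaged over the three trials
  per speed.

Missing trials degrade gracefully everywhere: aggregates use the available
trials and carry `n_trials`/`complete` flags; reaching requires at least
three valid trials, otherwise the metric is flagged missing.

### Signal conditioning

Velocity and force are conditioned with a first-order Butterworth low-pass
at 20 Hz. The filter realizes the exact analog transfer function
H(jf) = 1/(1 + j f/fc) applied spectrally with edge-value padding over ~20
filter time constants: unit DC gain, −3 dB at the cutoff, and the analytic
1/√(1+(f/fc)²) roll-off at every frequency, with the causal phase lag of
the analog prototype. A bilinear-transform IIR was rejected because its
frequency warping misses the first-order magnitude by 13% at 200 Hz for
fs = 1 kHz. `zero_phase=True` applies the squared magnitude with zero phase
(forward-backward equivalent) for offline analysis.

## Test-retest reliability

The measurement panel of one metric is the n×2 matrix of per-session scores
(session score = the metric's own trial aggregate). ICC(A,k) is the
absolute-agreement, average-measures form of the two-way random-effects
ANOVA, (MS_subject − MS_error)/(MS_subject + (MS_session − MS_error)/n),
with the F-based confidence interval of the single-measure form
(Satterthwaite degrees of freedom) stepped up to the k-measures scale.
The phrase "taking into account all individual trials" is honored in two
places rather than in the ICC itself (which would be ill-defined with k = 2
sessions of unequal trial counts): the *range* used to normalize SRD% and
the systematic shift is the max−min of all pooled trial-level values across
subjects and sessions, and the pooled within-cell trial SD is estimated and
reported alongside the session-level SEM. SEM defaults to √MS_error of the
session-score ANOVA (the session term is reported separately, not folded
in). SRD = 1.96·√2·SEM.

The systematic shift is 100·mean(T2 − T1)/range, sign-flipped for
higher-is-better metrics so that positive always means worse performance on
retest and the ±6.35 band applies uniformly. Degenerate panels (no variance,
zero range, constant scores) are flagged, not raised.

Known estimator property: the ICC(A,k) moment estimator is biased downward
in small samples (≈ −0.04 at true ICC 0.5 with n = 30 and k = 2, decaying
~1/n). This is inherent to the standard estimator (pingouin's implementation
is numerically identical) and is visible in the variance-component recovery
tests.

## Validity

Group comparisons (control hands pooled over both sides, affected side,
less-affected side; session 1) use the Kruskal–Wallis test with pairwise
follow-ups Bonferroni-corrected by m = 3, and the ROC AUC computed as
Mann–Whitney U/(n₁n₂) with ties counted ½, oriented through
direction-of-better. Sides are additionally compared per subject with a
paired t-test (zero-variance differences handled explicitly).

Normative modelling: per task, a linear mixed-effects model with subject
random intercept is fitted on control trial-level values (statsmodels
MixedLM, REML; fixed effects: age (centered), gender, tested hand, the
task-specific effect — direction, speed, active/passive, or the presented
angle for matching — and trial number). Model quality is summarized by
C1 = 100·mean|residual|/range and C2 = 100·SD(|residual|)/range (good:
C1 ≤ 10 and C2 ≤ 20; moderate: C1 ≤ 15 and C2 ≤ 25). These C1/C2 formulas
are a declared interpretation (the criteria characterize the mean absolute
model error and its variability) isolated in one function. Constant design
columns are dropped with a warning; if the mixed model cannot be estimated
(e.g. zero residual variance) the fixed effects fall back to OLS.

For z-scoring, fixed-effect contributions are subtracted from trial values
relative to control-mean reference covariates, the metric's own aggregate is
re-applied, and z = (adjusted − control mean)/control SD, flipped so larger
z is always worse. Adjustment is applied to motor-category metrics only by
default (they are the ones the confounds load on); a flag extends it to all
metrics. A hand is impaired when its z strictly exceeds the empirical 95th
percentile of the adjusted control hands; the quantile uses the Weibull
plotting position (i/(n+1)), whose expected exceedance for a new intact
subject equals the nominal 5% — the plain linear-interpolation quantile
over-flags (~6.4% at n = 62). Classification agreement compares these calls
with FMA < 60 and kUDT < 2; subjects missing the clinical score are excluded
from agreement but kept in % impaired.

Independence uses partial Spearman correlations on one selected metric per
task (defaults: AE, VelExt, AROM, ForceFlex, RMSESlow). Each pair is
controlled for *all remaining selected metrics* (the covariate set is not
fixed by the protocol; this choice is configurable and recorded in output
metadata); p-values use the t-approximation with n − 2 − g degrees of
freedom.

## Synthetic cohort generator

The generator is a first-class, tested model of the study's statistical
structure, not a fixture. Each stroke subject carries two latent severities
in [0, 1] — motor and proprioceptive — with uniform marginals coupled by a
Gaussian copula (ρ = 0.4). Motor metrics load on the motor severity, the
matching error on the proprioceptive one, and the tracking error on a
0.6/0.4 proprioceptive/motor mix (configurable), operationalizing the
finding that tracking error travels with proprioception rather than with
strength. The less-affected side expresses a category-specific fraction of
the affected-side severity (0.5 sensory, 0.4 motor, 0.3 sensorimotor).

Per metric, a control baseline (mean ± between-subject SD) and a severity
effect define the expected value; the effect size is solved by bisection so
that the mean over severities of the floor/cap-saturated response hits the
configured affected-side stroke target. The `paper_like` preset sets the
stroke targets to the published affected-side test-session values
(AE 14.63 ± 6.43°, VelFlex 314.94 ± 180.30°/s, VelExt 149.06 ± 146.27°/s,
AROM 43.89 ± 36.20°, PROM 83.88 ± 10.48°, ForceFlex 11.64 ± 11.55 N,
ForceExt 4.12 ± 4.52 N, RMSE slow/fast 21.09 ± 8.68 / 21.45 ± 7.80°) and
demographics (30 stroke aged 64.5 ± 14.0, 31 right-handed controls aged
66.9 ± 7.9, at most 40% of stroke subjects with intact proprioception,
enforced by re-drawing). **Control-hand baselines are synthetic
plausibility values** (e.g. AE 5 ± 1.5°, VelExt 420 ± 90°/s,
ForceFlex 28 ± 8 N, RMSESlow 8 ± 2°): the corresponding control
distributions are not part of the reproduced record, so they were chosen
once as values a clinician would accept for intact 65-year-old hands and
produce group separations near the published AUCs. Confound coefficients
follow the reported signs (age and gender depress force, gender depresses
velocity, tested hand affects motor metrics); they are centered on the
control demographic mix so configured population means are preserved.

Variance components per metric: between-subject (residual after the
severity spread), between-session (day-to-day) and trial-to-trial SDs, all
in metric units, plus an optional programmed session-2 shift (positive =
worse on retest) used by the shift-recovery tests. Matching errors are
zero-mean signed draws whose folded mean equals the subject's AE level, with
the SD scaled by the presented angle (+30% per 10° above the 20° midpoint,
normalized) — the angle-magnitude effect. Reaching per-trial peaks are
debiased by the expected top-3-of-10 order-statistic mean (computed by
numerical integration, not hard-coded) so the session aggregate lands on the
configured target.

The fast scalar mode emits per-trial responses directly; the trace mode
synthesizes raw signals consistent with the same scalar draws: bell-shaped
(Gaussian) velocity pulses with group-dependent time-to-peak
(stroke 160 ± 57 ms, control 122 ± 22 ms) and workspace-saturated integrated
position; half-cosine ROM excursions; smooth force plateaus with 0.5 s rise
and 3 s hold; and tracking responses of the form
center + gain·(target(t−lag) − center) + tremor, where gain loss (0.3·s) and
lag (0.4 s·s) grow with severity, the deterministic deviation has the
closed form Σ aᵢ²(1 + g² − 2g·cos 2πfᵢτ)/2, and white tremor makes up the
remaining requested error power (with bisection shrinking the degradation
when it already exceeds the requested RMSE). Drift is available as part of
the tremor budget and defaults to zero.

All randomness flows from one master seed through per-subject/per-session
`SeedSequence` substreams, so partial regeneration is stable.

**What passing tests show — and do not show.** The generator reproduces the
*statistical* structure the pipeline assumes: group separations, variance
components, confound loadings, the angle-magnitude effect, saturation. It
does not model biomechanics, neglect or vision deficits, non-Gaussian heavy
tails, floor-seeking behaviour of severely impaired subjects (e.g. subjects
who do not move at all scoring better on RMSE), or session-to-session
protocol deviations. Green tests therefore certify the estimators and the
pipeline plumbing, not the clinical properties of any real device.

## Problem sizes and numerical choices in the test suite

Simulation-based checks use sizes chosen to keep the whole suite fast while
leaving Monte-Carlo error well below the tested tolerances: 1,000 random
panels for the statistic oracles, 500 replicates per ICC level (n = 30 × 2
sessions × 5 trials), 200 cohorts for shift recovery and for the normative
flag-rate calibration, 5,000 replicates for the Kruskal–Wallis type-I
check, 200 replicates (120 control subjects × 6 trials) for confound-model
recovery, and 100 full cohorts for the end-to-end reproduction. The
confound-recovery design uses 120 rather than 31 subjects because the
coverage event being tested ("within 2 SE" ≈ 95.4% nominal) would otherwise
be capped below the 95% bar by the t-distribution of between-subject
effects alone, independent of estimator quality.

## Known limitations

* ICC(A,k)'s small-sample bias (above) means reliability at n ≈ 30 is
  mildly understated near ICC 0.5; confidence intervals remain calibrated.
* PROM is intrinsically ceiling-limited by the device workspace (≤ ~90°);
  with stroke PROM only ~0.6 SD below any plausible control distribution,
  its control-vs-affected AUC hovers at the 0.7 decision threshold — a
  property of the construct, not of the estimator.
* statsmodels MixedLM provides no Kenward–Roger/Satterthwaite small-sample
  correction; fixed-effect p-values use the residual-df t-approximation.
* The partial-correlation covariate set and the C1/C2 formulas are declared
  interpretations, each isolated behind one function so they can be swapped.
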