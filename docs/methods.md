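# Methods

This note documents the models, rules and numerical choices behind each
module, the assumptions of the synthetic-data generators, and the known
limitations of both.

## Discriminant analysis

**Model.** Two classes, subjects × variables matrix `X`. Scatter matrices
`S_B = Σ_c n_c (μ_c − μ)(μ_c − μ)ᵀ` and
`S_W = Σ_c Σ_{i∈c} (x_i − μ_c)(x_i − μ_c)ᵀ`; LD1 is the unit-norm
eigenvector of `pinv(S_W)·S_B` with the largest absolute eigenvalue,
oriented so that class 1 projects higher than class 2. With two classes
`S_B = const · ddᵀ` (d = μ₁ − μ₂) has rank 1, so exactly one discriminant
eigenvector exists; LD1 is therefore collinear with `pinv(S_W)·d`, which the
shuffle engine exploits as a fast path.

**Pseudo-inverse tolerance.** Singular values below `max(dim)·eps·σ_max`
are treated as zero (the MATLAB `pinv` convention), configurable via
`pinv_rcond`. This matters: numpy's default relative cutoff (1e-15) lies
*below* the numerical-zero singular values of a rank-deficient scatter
matrix (≈1e-14·σ_max), so the default would invert null-space noise and
return a direction dominated by floating-point garbage.

**LD2.** Because no second discriminant eigenvector exists, LD2 is defined
as the first principal axis of the centred data after projecting out LD1.
This choice produces the conventional two-axis display whose explained
percentages sum below 100; it is a display definition, not a second Fisher
direction.

**Explained variation and contributions.** Explained % of an axis =
variance of subject projections on it / total variance of the (z-scored)
data × 100. Note that a Fisher direction *minimises* within-class variance
along itself, so LD1's explained share of total variance is legitimately
small on weakly separated cohorts — it measures how much of the data's
spread lies along the separating axis, not the quality of separation.
A variable's contribution to an axis is `100·|w_j| / Σ_k |w_k|`;
contributions per axis sum to 100 by construction.

**Stability caveat.** Coefficient-based contribution ranks are unstable
when the variable count approaches the subject count: the smallest positive
singular values of `S_W` are then poorly estimated and their inverses
dominate `pinv(S_W)·d`. Measured on synthetic cohorts with 3 injected
d = 1.5 effects among 31 variables at 15 subjects/class, all three injected
variables reach LD1's top-10 contributions in only ~20% of runs (and an
independent scikit-learn LDA behaves no better). Practitioners should read
top-contribution lists at p ≈ n as suggestive, and rely on the shuffle null
(below) for calibration. Regularised discriminants would stabilise the
ranks but are deliberately out of scope.

**Shuffle validation.** Subjects are reassigned uniformly at random (without
replacement) to two equal classes; the subject count must therefore be even.
Per shuffle the engine recomputes `w = pinv(S_W)·d` using the identity
`S_W = S_T − (n/4)·ddᵀ` (total scatter `S_T` is shuffle-invariant), ranks
variables by |w| with ties broken by column order, and accumulates (a) each
variable's frequency of holding ranks 1–3 and (b) the frequency that the
observed top-2 (top-3) variable *sets* jointly hold ranks 1–2 (1–3). All
frequencies carry binomial Monte-Carlo standard errors, and
`shuffles_for_error(p, rel)` = `(1−p)/(p·rel²)` gives the shuffle count
needed for a relative MC error below `rel` at frequency `p` (e.g. 199,600
shuffles for p = 0.2% at 5%). Defaults use 200,000 shuffles; tests and the
acceptance script use 20,000, which resolves joint frequencies down to
~0.05% — adequate for the magnitudes the pipeline reports.

An important subtlety, found empirically: for iid null variables the
"each variable is rank 1 in 1/p of shuffles" symmetry holds only *marginally
over datasets*. Conditional on one fixed dataset, sample cross-correlations
bias the rank frequencies by far more than the shuffle-level binomial SE
(deviations of >10 SE are routine at n = 20). Symmetry checks therefore
pool shuffles across independent null cohorts.

## Pre-processing

Order: slope reduction → skew screen → per-class outlier replacement →
pooled z-scoring → correlation filter.

- **Slope reduction.** A variable measured over k ≥ 2 sessions is replaced
  by each subject's OLS slope against the 1-based session index — a
  single-number learning curve. NaN sessions are omitted (≥ 2 finite values
  required).
- **Skew screen (advisory).** A variable is flagged when its sample
  skewness exceeds a threshold (default |2.0|) *and still does* after
  removing its single most extreme point. The drop-one probe separates a
  genuinely heavy-tailed distribution from one aberrant value — the latter
  is the MAD rule's job, and plain sample skewness at n = 30 is dominated
  by single outliers. Flagged variables are reported; `preprocess`
  drops them only when `exclude_skewed=True`.
- **Outlier replacement.** Per class and variable, values beyond 3 scaled
  MADs (MAD × 1.4826, the Gaussian-consistent scale) from the class median
  are replaced by the mean of the non-flagged class members, in a single
  pass. When the MAD is zero (majority ties) any value off the median is
  flagged. Non-flagged values are never altered. At n = 15 per class this
  rule flags ≥ 1 point in ~20% of Gaussian class-variables (simulated) —
  mean interpolation is aggressive in small samples, and a one-sided
  replacement inside a correlated variable pair measurably lowers the
  pair's sample correlation.
- **Z-scoring.** Pooled over both classes (ddof = 1); zero-variance
  variables are dropped with a report entry. Idempotent to 1e-12.
- **Correlation filter.** Greedy and order-stable over the Pearson matrix:
  for each pair with |r| ≥ 0.86 the member whose tag or name matches the
  drop-priority list (default `("speed",)`) is dropped, else the second
  member. Speed variables duplicate distance variables up to session-length
  scaling, hence the default priority.

## Univariate workflow

`grubbs_test` uses the two-sided t-based closed form: `G = max|x−x̄|/s`
against `((n−1)/√n)·√(t²/(n−2+t²))`, `t = t_{1−α/(2n), n−2}`; one outlier
per call. `two_group_compare` routes by Shapiro–Wilk at α = 0.05 on each
group: both normal → two-tailed t-test, else Mann-Whitney; repeated designs
go to a between×within mixed ANOVA (pingouin), or a linear mixed model
(statsmodels `MixedLM`, subject random intercept) when values are missing.
Cohen's d is the pooled-SD standardized mean difference throughout.

## Assay scoring rules

- **Kinematics / occupancy.** Distance is the summed Euclidean step length;
  mean speed = distance / elapsed time. ROI dwell time is frame-count /
  fps over a disjoint partition of the arena, so per-ROI times sum exactly
  to n_frames/fps. An entry is a membership change between consecutive
  frames, plus one for the ROI occupied at the first frame. Frames outside
  the arena (tracking jitter) are assigned to the nearest ROI with a
  warning, within a configurable tolerance (default 1 cm).
- **Layouts.** Open field: inner square, outer band (default width 10 cm in
  a 50-cm arena — the conventional 20%-of-side band) and four corner
  squares (default 10×10 cm), corners taking precedence where they overlap
  the band so the partition stays disjoint. EPM: two open and two closed
  arms (29.5 × 8.5 cm default) around a centre square. Three-chamber: three
  equal chambers with circular cup zones of default radius 6 cm (the 8-cm
  cup's edge plus ~2 cm sniffing distance); cup zones overlap chambers and
  are scored outside the occupancy partition. Near-cup dwell uses the nose
  point; chamber dwell the body point.
- **Marble burying.** Buried flag ⇔ visible-area reduction ≥ 50% (boundary
  inclusive); per-marble buried area floored at 0 so unearthed marbles
  contribute nothing to the total.
- **Grooming bouts.** Short bout ⇔ duration < threshold; the short/long cut
  is not standardised, so it defaults to 10 s, is configurable, and is
  surfaced in every summary. Bouts straddling bin edges split
  proportionally (bin series sums exactly to total time); a bout counts in
  the bin containing its start.
- **Ladder.** Step class by rung displacement: ≤ −1 backstep (displacements
  < −1 are counted with a warning tally), 0 stationary, +1 shortstep,
  +2 longstep, ≥ +3 jump; step percentages are over the four moving
  classes. Misstep ⇔ either rung of the step is low; the rung height map
  defaults to alternating high/low by parity (even = high) and is
  configurable since the apparatus layout is not standardised here. Exits:
  closed-left intervals — before the light cue, [light, air), and ≥ air.
  Light/air ratio = light count / air count, reported missing with a flag
  when no air exits occurred.
- **Association fit.** Per group: Spearman ρ (average ranks on ties) and an
  OLS line of before-cue exits (y) on the light/air ratio (x) — this
  orientation matches the magnitude of slopes such fits report, and is
  configurable. The genotype comparison is the extra-sum-of-squares F:
  `F = ((RSS_shared − RSS_sep)/2)/(RSS_sep/(N−4))`, df = (2, N−4).
  Noise-free fits leave only float dust in the RSS; RSS below 1e-12 of the
  response's sum of squares is treated as zero (F = 0 or ∞ accordingly).
- **Y-maze.** Protocol: 4 acquisition sessions + 1 test + 5 sessions per
  reversal, 5 trials each; session 5 of a reversal is the forced session.
  A subject is excluded from reversal analysis when its test correct rate
  is *below* 80% — exactly 4/5 passes. The cumulative learning curve is the
  running correct-choice count over the 25 acquisition+test trials,
  summarised across subjects by median and quartiles.
- **Visuomotor.** A saccade is the first maximal run of consecutive
  inter-sample segments with angular speed strictly above 50°/s after the
  reference event; its onset is the run's first sample time. Landing
  position is read one sample after the run (eye settled). Pro/memory
  correctness requires landing (and touch, for tapping) within a 2°
  radius (configurable — no standard tolerance exists); anti correctness
  uses the horizontal sign only, opposite to the stimulus. Memory-task
  latencies are referenced to the central-dot offset (the go signal) by
  default; the peripheral-flash reference is available since the
  stimulus-referenced definition is ambiguous for memory trials. Deviation
  scores are `(value − control mean)/control SD`, signed.

## Synthetic data

The generators emulate a 15-vs-15 two-genotype cohort and human eye–hand
sessions; a single integer seed drives a hierarchical `SeedSequence` with
one child stream per subject or trial, so enlarging a cohort never changes
already-generated subjects.

- **Feature matrices.** Gaussian within-class noise; correlated blocks via
  the Cholesky factor of the target correlation matrix; skewed variables
  via a standardized exponentiated Gaussian `((exp(s·z)−1)/s`, then
  standardized by its lognormal moments). Class effects are additive shifts
  of `d` within-class SDs, except on skewed variables where the shift acts
  on the latent Gaussian scale (multiplicative on the raw scale) — an
  additive shift of a standardized heavy-tailed variable produces a tight
  bimodal artifact instead of a skewed distribution. Outliers (default
  rate 0.005 per subject×variable) displace values by ±8 SD, jointly
  across the members of a correlated block, the way a tracking glitch
  propagates to every measure derived from the same recording. The default
  cohort has 36 raw variables across eight assays; speed/distance pairs at
  r = 0.99 (mean speed is distance over a fixed session length, so the
  pair is nearly deterministic), one skewed learning variable (s = 2.5),
  seven 5-session learning variables, and moderate injected effects
  (|d| 0.4–0.8) on motor, learning and grooming measures. After the skew
  exclusion and correlation filtering the cohort typically retains 31
  variables; because the MAD rule and skew screen are noisy at n = 30 the
  count ranges 30–33 across seeds — that spread is a property of the
  method, not of the generator.
- **Tracking.** A waypoint walk at constant per-frame step length
  (mean speed is exact by construction); with probability equal to the
  thigmotaxis weight the next waypoint is drawn from the wall band
  (default: 20% of the smaller arena extent) within a short hop, otherwise
  uniformly from the arena. At weight 1 this concentrates ≥ 80% of frames
  in the band. No pixel-level tracking noise or body-pose dynamics are
  modelled; the nose point, when requested, rides 2.5 cm ahead of the body
  along the heading with small jitter.
- **Grooming logs.** Bout count ~ Poisson(rate × duration), starts uniform,
  durations uniform on [0.5, 1.5] × the component mean of a short/long
  mixture (defaults 4 s / 25 s at weights 0.15/0.85); overlaps are resolved
  by truncating at the next start, which preserves the Poisson count but
  shortens a minority of bouts. Rates whose expected duty cycle reaches
  0.9 are rejected as unpackable.
- **Ladder.** Per session, exit causes are multinomial with per-session
  probabilities; light onset uniform in the 9–11 s waiting window, air
  exactly 3 s later; steps draw displacements from a step mix (default
  mostly +1) until the 37th rung. The generator does not model rung-height
  preference, so with the parity height map most generated steps involve a
  low rung — misstep percentages on synthetic data are far higher than a
  real mouse's and only exercise the rule, not its typical magnitude.
- **Y-maze.** Bernoulli correctness per phase/session probability over the
  fixed protocol; forced trials are marked but scored like others.
- **Gaze streams.** 1.5 s at 120 Hz, stimulus at 200 ms (memory: 50-ms
  flash, go signal at 500 ms); exactly one injected saccade per trial as a
  linear ramp over 5 samples whose per-sample speed must exceed the
  detection threshold (the generator rejects undetectable kinematics,
  e.g. amplitude 10° over 5 samples → 240°/s). Fixation noise (SD 0.02°)
  stays an order of magnitude below threshold, so generated streams
  contain no spurious saccades — detector false-alarm behavior on real
  noisy data is *not* established by these tests, only the threshold logic.

## What passing tests do and do not show

The suite establishes arithmetic and rule correctness (exact oracles,
boundary conventions), estimator correctness against independent oracles
(generalized eigenproblem, brute-force RSS, closed forms), distributional
recovery of injected structure at stated sampling tolerances, and
end-to-end determinism. Synthetic cohorts are Gaussian with clean
correlation structure; real behavioral data carry heavier tails, batch
effects and missingness patterns the generators do not emulate, so
pipeline behavior on such data — in particular the stability of
contribution ranks — should be judged with the caveats above.
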