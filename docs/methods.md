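# Methods

## The task and the data model

The self-referential encoding task (SRET) presents valenced adjectives
(26 positive, 26 negative, three blocks, 156 trials per session) and asks
for a yes/no judgement of self-descriptiveness. The study design crossed
word valence with two light conditions (blue-enriched vs blue-depleted),
one condition per session, order counterbalanced across 33 analyzed
participants. Responses are coded 0 = "yes, describes me" (endorse) and
1 = "no" (reject); response time is recorded in seconds.

All analyses in this package operate on that trial table, and because the
original data are not deposited, the package ships a generator that
produces datasets with exactly this structure from a known truth, so every
stage of the analysis can be exercised and checked against its generating
values.

## Wiener diffusion core

Choice and RT are modelled as a two-boundary Wiener diffusion: evidence
starts at relative position `z` (0–1) between absorbing boundaries 0 and
`a`, accumulates with drift `v` and unit diffusion coefficient, and the
observed RT adds a non-decision component `t`. The upper boundary is the
rejection response, so positive drifts favour rejecting a word. The
first-passage density is evaluated by the standard pair of series
expansions of the standardized density (mirrored-Gaussian terms for small
normalized times, a trigonometric series for large ones), choosing per
evaluation whichever needs fewer terms at tolerance 1e-7. The
lower-boundary density follows from the reflection (v, z) -> (-v, 1-z).
The absorption probability has the closed form
`P(upper) = (1 - e^{-2vaz}) / (1 - e^{-2va})` (`z` at `v = 0`), used as an
independent oracle for both the density (integrated mass per boundary) and
the simulator.

Simulation is Euler–Maruyama with default step `dt = 1 ms`. Discrete-time
crossing checks give first-passage times a small positive bias of order
`sqrt(dt)` (about 10–20 ms at the default step, shrinking with `dt`); the
test suite verifies the direction and decay of this bias, and tolerance
bands that compare simulation against the analytic density include it.
Inter-trial variability parameters (sv, st, sz) are not modelled: the
four-parameter model is the object of study.

## Synthetic-data generator

The diffusion generator draws each participant's parameters from the group
truth: cell drifts from Normal(v_cell, v_sd_between) and (a, z, t) from
truncated normals (truncation by resampling, not clipping, over
a > 0.1, z in (0.05, 0.95), t in (0.1, 1.0) — clipping would put atoms on
the bounds). Defaults for the group means are the best-fit group values of
the original analysis (drift cells -0.73, -0.71, 1.13, 1.36; a = 1.42,
z = 0.49, t = 0.46). Between-participant SDs are not identifiable from
published group summaries; the defaults (v 0.25, a 0.20, z 0.04, t 0.05)
are plausible magnitudes relative to the group means and are configurable.
Hue awareness is Bernoulli(0.26) per participant and sex is assigned at
the 22:13 female:male ratio of the analyzed sample; both are carried as
covariates only. Word identity carries no effect — the generating models
depend on valence only, so the packaged lexicon is a fixed stylistic
stand-in for the published stimulus set.

The logistic generator mirrors the trial-level mixed-model analysis
instead: `logit P(reject) = b0 + b_i + b_cond 1[enriched] + b_rt RT` with
`b_i ~ Normal(0, tau00)`, defaults at the reported negative-word values
(intercept ln 12.07, condition ln 1.24, RT ln 0.68, tau00 = 1.88) and RTs
lognormal with moments matched to the observed summaries (mean 0.85 s,
SD 0.45 s).

What the generator does *not* emulate: sequential effects across trials,
word-level psycholinguistic variation, fatigue or block effects, the
inter-trial interval, and contaminant RTs (fast guesses, lapses). Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the assumed model, not robustness of the original findings
to violations of it.

## Hierarchical estimation

Model variants let drift, start point and/or non-decision time differ
across the four condition-by-valence cells (cell-means coding, no
intercept); boundary separation never varies by cell, reflecting the
persistent non-convergence of such variants on this design, and requests
to vary it raise an explicit error. Drift is estimated at the group level
per cell; a, z and t carry participant-level deviations
(`value_i = group coefficient + dev_i`, `dev_i ~ Normal(0, sigma^2)`), so
each participant has their own (a, z, t) — the structure the
posterior-predictive check uses.

Priors constrain parameters to plausible ranges: drift cells
Normal(0, 2^2); group a Normal(1.5, 0.75^2) on (0.3, 4); group z
Normal(0, 0.5^2) on the logit scale; group t Normal(0.4, 0.3^2) on
(0.05, 2); hierarchy scales Half-Normal(0.3). The posterior is explored by
adaptive Metropolis-within-Gibbs: random-walk updates per group
coefficient, componentwise updates per participant deviation, log-scale
updates for the hierarchy SDs, and likelihood-invariant recentering moves
(shift a shared group coefficient, counter-shift all its deviations) that
remove the ridge the non-centered parameterization otherwise creates.
Proposal scales adapt toward ~35% acceptance in 50-sweep batches during
burn-in only, so the post-burn-in chain is a fixed Markov kernel. Three
chains run by default; convergence is summarised by split-chain R-hat
(threshold 1.01) and autocorrelation profiles. Per-trial log likelihoods
are cached and refreshed exactly on acceptance, never incremented, so
cached and recomputed likelihoods agree bitwise.

The reference settings are 30,000 samples per chain, 5,000 burn-in,
thinning 10 (2,500 retained per chain); fits in this repository's tests
and acceptance script use a scaled-down profile (6,000 / 1,000 / thin 5,
three chains, ~1,000 retained per chain) chosen as the package's desk
profile — recovery at the full design size is unchanged, only posterior
Monte-Carlo error grows slightly.

DIC is `Dbar + pD` with `pD = Dbar - D(posterior mean)` (Spiegelhalter's
definition), lower is better; the model-selection table reports DIC, pD
and the difference from the null model, and flags (never drops)
non-converged fits.

## Posterior analysis

Two cell posteriors are called different when less than 5% of their
probability density mass overlaps. Overlap is operationalized as the
overlap coefficient of Gaussian KDEs (Silverman bandwidth, shared
512-point grid spanning both samples): for equal-variance normals it
equals `2 Phi(-|dmu|/(2 sigma))`, which the tests use as a closed-form
oracle. Whether "overlap" should instead mean a tail probability of the
difference distribution is ambiguous; the directional posterior
probability `P(a > b)` is reported alongside, but the overlap coefficient
drives the significance flag.

The posterior-predictive check simulates, per participant-cell, from the
participant's posterior-mean (a, z, t) and the group posterior-mean cell
drift — point estimates rather than full posterior draws, matching how the
simulated percentiles are defined for this design — and compares RT
quantiles at the 10/30/50/70/90th percentiles against observed quantiles
after trimming observed RTs beyond 3.29 SD of their cell mean (trimming
applies to observed data only). Cells with fewer than five retained trials
per boundary are flagged and excluded from summaries.

## Trial-level mixed logistic models

The outcome is positive self-evaluation (rejecting a negative word,
endorsing a positive one); fits are run separately per valence. The
marginal likelihood integrates the participant intercept out by adaptive
Gauss–Hermite quadrature: per participant, Newton with backtracking finds
the mode of the strictly concave integrand, the curvature rescales 15
probabilists' Hermite nodes (15 vs 25 nodes changes coefficients by less
than 1e-5 on fixtures), and L-BFGS-B maximizes over (beta, log sigma).
Standard errors come from a central-difference Hessian with steps sized
against cancellation in a log likelihood of magnitude ~1e4; p-values and
95% CIs are Wald-z, reported on the odds-ratio scale. The latent-scale
ICC is `tau00 / (tau00 + pi^2/3)` and R-squared follows the
Nakagawa latent-scale decomposition. Candidate fixed-effect structures
(main effects, two-way, and three-way interactions with sex and hue
awareness) are ranked by BIC with N = observations; because "BIC corrected
for small sample sizes" is ambiguous for clustered binary data, the table
also reports the variant with N = participants. Standardized fits z-score
continuous predictors only; binary codes are left alone.

## Descriptive summaries

The proportion table reports counts, within-cell percentages (rounded
half-up to one decimal, the table formatting convention) and RT mean (SD)
per condition-valence-response cell. Condition comparisons use paired
one-tailed t-tests on per-participant proportions, with the alternative
that blue-enriched light increases positive self-evaluation; zero-variance
difference vectors raise rather than fabricate a t statistic, except the
all-zero case which returns t = 0, p = 0.5 by convention. Normality is
left to visual inspection of the difference histogram (exported data, no
test statistic).

## Numerical choices and degenerate inputs

- Series tolerance 1e-7 for the first-passage density; log densities are
  -inf (not an error) for RT at or below non-decision time.
- Likelihood support bounds: a > 0.1, z in (0.02, 0.98), t > 0.01 and
  below each participant's minimum RT (enforced by the -inf likelihood).
- Truncated-normal sampling by resampling with an iteration guard.
- KDE overlap on degenerate (constant) draws raises; the grid spans both
  samples plus three bandwidths.
- Empty trial tables, missing columns, non-positive RTs and non-binary
  responses raise named errors at the file boundary.
- Seeds propagate explicitly: the generator, each MCMC chain
  (`seed + 1000 * chain`), and every simulation consume
  `numpy.random.default_rng` seeds derived from the caller's.

## Known limitations

- The sampler is random-walk based; for much larger designs a
  gradient-based sampler would mix faster. At this design size all split
  R-hats sit near 1.003 at the desk profile.
- Group drift is not given participant-level deviations, matching the
  hierarchy the predictive check assumes; data generated with large
  between-participant drift spread are therefore deliberately
  misspecified relative to the fitted model (recovery of group means is
  robust to the default spread).
- The Euler simulator's O(sqrt(dt)) bias slightly inflates non-decision
  time estimates recovered from simulated data (~10 ms at dt = 1 ms),
  well inside the recovery tolerances used here.
- BIC small-sample correction and the precise overlap definition are
  resolved by documented convention, as noted above.
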