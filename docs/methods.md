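# Methods

## The adaptation model

The listener is assumed to track the validity of the adjective L+H* cue —
the probability that an accented color adjective is followed by a repeated
noun — as a Bernoulli rate with a conjugate beta prior. The belief starts
at the uniform Beta(1, 1) and is updated only on trials that carry the cue:
a repeated noun increments the confirmed count `n_c`, a novel noun the
disconfirmed count `n_d`. The point estimate of validity is the posterior
mean `mu = (1 + n_c) / (2 + n_c + n_d)`.

A trial's inhibition cost is `IC = mu * PE`. `PE` encodes the long-run
surprise of the outcome given the cue, fixed per language from production
corpora: in English an L+H*-accented adjective is non-contrastive in about
4% of comparable contexts, in German about 8%, so confirmed predictive
trials carry PE = 0.04 (EN) / 0.08 (DE), disconfirmed ones the complement
0.96 / 0.92, and trials without the adjective cue PE = 0. The PE values are
configuration (`PEConfig`), not constants, so sensitivity analyses can
replace them.

Two timing choices are deliberate and worth making explicit:

* **Pre-observation belief.** The cost of trial *t* uses `mu` computed from
  trials 1..t−1; the update with trial *t*'s outcome is applied afterwards.
  A prediction must precede its own error, and the first predictive trial
  then carries the nonzero cost of the uniform prior (0.5 × PE), which is
  what the declining cost trajectories require at their left edge.
* **Carry-over.** Within one language session the belief chains across
  experiment 1 → training → experiment 2 (the phases must be passed in that
  order), so a training phase of six confirmed predictive trials moves the
  belief entering experiment 2 to mu = 13/20 = 0.65. Belief never carries
  across languages: sessions were run on different days and each language's
  trace restarts at Beta(1, 1).

A structural property used by the tests: for matched within-phase orderings
and a purely confirming training phase, the cost at the k-th disconfirmed
trial of experiment 2 is at least its experiment-1 counterpart **provided**
the ordering keeps confirmed counts within `c <= 1 + 2d` of disconfirmed
counts at each disconfirmed trial (alternating or balanced orderings do).
It is not an unconditional theorem: an ordering that front-loads two or
more confirmations before the first disconfirmation reverses the
inequality at that point (e.g. C C D gives mu = 3/4 without training
history vs 15/22 with it). The structural tests therefore use alternating
orderings, which also match the saw-tooth decline of the modeled cost
curves.

## Experimental-design generation

Phase composition is fixed: experimental phases have 48 trials — 6
cue+repeated, 6 cue+novel, 6 no-cue+repeated, 18 no-cue+novel (12 without
any L+H*, 6 with a noun L+H*) plus 12 repeated-adjective fillers — and
training has 24 (12 no-cue novel, 6 repeated-adjective with noun L+H*, 6
cue+repeated). The adjective-L+H* share is exactly 0.25 everywhere. The
published materials do not state the fillers' prosody beyond being
felicitous; splitting them 6 noun-L+H* / 6 no-L+H* preserves the 0.25 cue
share and mirrors the training phase. The inclusion filter keeps trials
whose two instructions use different color adjectives (36 of 48; 18 of 24).

Orders are pseudorandom under the constraint that no two consecutive trials
share a prosodic pattern. Because half of an experimental phase carries the
no-L+H* pattern, shuffle-and-reject is hopeless (the acceptance probability
is astronomically small); instead each position is drawn uniformly among
the remaining trials whose pattern differs from the previous trial *and*
whose removal leaves the remainder orderable — a counting feasibility check
(`max count <= ceil(m/2)`, with a parity correction when the previous
pattern holds exactly half of an odd remainder). The sampler therefore
always completes; it is not exactly uniform over valid orders but is close
at this constraint density. Orders depend on `(seed, phase)` only: the
original study presented the same trial order in both languages, so the
language argument is a label. Picture sets rotate across blocks of six
trials, a conventional Latin-square-style balance. Only the stated
adjacency constraint is enforced; nothing else about the original
pseudorandomization is published.

## Synthetic gaze generator

The generator stands in for the study's raw eye-tracking data; it emulates
the *statistical structure the analysis assumes*, not the kinematics of
gaze. Per trial it emits AOI-coded samples on a 60 Hz grid (the study's
tracker rate) from −200 to +800 ms around the second noun's onset. The
target-fixation probability is logistic in exactly the analysis predictors:
baseline intercept and within-trial time slope, a facilitation shift on
confirmed predictive trials, a weight on the trial's modeled inhibition
cost, a drift in standardized trial number, and participant random
intercepts and cue slopes. Non-target mass is split uniformly over the five
distractors plus an off-screen share; track loss marks samples lost
independently at a configurable rate, and participants exceeding a 20%
loss threshold (the study's exclusion rule) can be flagged.

Two sampling modes:

* `independent` — every sample is an independent categorical draw. This is
  exactly the data-generating process the binomial mixed-logit likelihood
  assumes, so it is the mode for calibration and recovery studies.
* `markov` — the current AOI persists and is redrawn only at switches with
  hazard `dt / dwell_mean_ms` (default mean dwell 250 ms), giving
  realistically autocorrelated fixations for robustness checks.

Defaults (logit scale) are chosen as a plausible mid-experiment
visual-world profile, not read from any figure: intercept −0.4, time slope
+0.15 per 100 ms, facilitation +0.4, inhibition weight −2.0, trial drift
−0.1 per SD, participant intercept SD 0.5 and cue-slope SD 0.3, 5% track
loss. They are acknowledged stand-ins — no published baseline fixation
dynamics exist to calibrate against — so passing tests certify the
pipeline's statistical behaviour under the assumed structure, not the
dynamics of real gaze (autocorrelation, saccade latencies, AOI geometry
are out of scope, and the per-trial binomial response is exactly true only
in independent mode).

`calibration_params()` is the configuration for error-calibration and
recovery studies: independent mode, every systematic effect zero except
those overridden, no within-window time trend, no track loss, no off-screen
mass, participant intercept SD 0.5. Under it the fitted model is the true
model, which is what a type-I-error or coverage claim requires.
`simulate_window_counts` draws the same independent-mode events aggregated
directly to in-window counts, skipping the long-format table; it exists
because recovery studies simulate hundreds of cohorts.

## Window and response definition

The analysis window is [150, 450) ms after noun onset — offset by roughly
the saccade-programming latency, covering the first ~300 ms of noun
processing. Half-open boundaries avoid double counting (the published
endpoints do not state inclusivity); at 60 Hz the window holds exactly 18
samples. The response per trial is `y/n`: target-object samples over
samples on any of the six objects. Off-screen and lost samples are outside
the six-object denominator by definition and are excluded from both counts;
trials with `n = 0` have no defined proportion and are flagged out of
modelling. Proportion-of-looks curves average the per-trial proportion per
condition and time bin (default bin = one device sample); bins with no data
are absent, not zero.

## Mixed-logit inference

Models are binomial GLMMs with a logit link and participant grouping:

* **A** — Cue × Repeated Noun × Trial Number, full factorial.
* **B** — Inhibition Cost alone.
* **C** — A's fixed effects plus Inhibition Cost.

Binary factors are sum-coded to ±0.5 (coefficients are average effects;
with this coding the Cue × Repeated coefficient equals the cell shift a
facilitation effect puts on the confirmed-predictive cell, which is what
makes the recovery study's mapping exact). Trial number is centered and
standardized; inhibition cost is centered. The default response is the
per-trial binomial count — 60 Hz samples are not pretended to be
independent observations — but a per-sample Bernoulli mode is provided and
yields identical estimates on independent-mode data, as the likelihoods
differ only by a constant.

The marginal likelihood is computed per participant by adaptive
Gauss–Hermite quadrature: the integrand is recentred at its posterior mode
(found by a batched, step-halved Newton iteration) and rescaled by the
curvature there; 7 nodes per dimension are used for up to two
random-effect dimensions and the Laplace approximation (one node) above
that. Optimization is BFGS over the joint fixed-effect / log-Cholesky
covariance vector; Wald standard errors come from the finite-difference
observed information. The log-likelihood includes the binomial normalizing
constant, so deviances are directly comparable with an external integration
of the same model (the suite checks agreement to 1e-4 on a 2-participant
toy set).

Random-effects structures start maximal and are simplified until a fit
converges without singularity (any random SD below 1e-4, or a correlation
beyond 0.99): correlations are dropped first, then slopes in increasing
order of fitted variance, then the intercept, ending at a plain GLM; every
step is logged on the fit. The default "maximal" structures are
intercept + main-effect slopes for A, intercept + cost slope for B, and
their union for C; correlations default to off (diagonal covariance), a
pragmatic convention given the small cohorts. Estimates with |β| > 15 on
the logit scale are treated as (quasi-)separation and flagged as
non-converged rather than reported. Significance uses Wald z at the usual
0.05 / 0.01 / 0.001 levels, with no multiple-testing correction; published
tables for models of this kind sometimes label the statistic *t*, but for
a logit model it is a z statistic and is reported as such.

The final random structures reported for the original study's models are
recorded in `PUBLISHED_RANDOM_STRUCTURES` and can be fitted directly
(`simplify=False`) instead of re-deriving a structure through the ladder —
useful when comparing against the deposited data.

Nested models are compared by likelihood ratio with ΔAIC/ΔBIC; the reduced
model is refitted with exactly the full model's final random structure so
the comparison is valid, and identical or non-nested specifications are
rejected. The interaction decomposition refits Predictive Cue as the sole
fixed effect on the repeated-noun and novel-noun subsets with participant
intercepts and cue slopes; with cue coded +0.5, facilitation appears as a
positive cue effect on repeated nouns and inhibition as a negative one on
novel nouns.

## Calibration and recovery studies

`parameter_recovery` simulates cohorts at the study's footprint — 17
participants × 36 included trials of one experimental phase — from
`calibration_params` with only the parameter under study nonzero, refits
the matching model (B for the cost weight; A's interaction term for
facilitation), and reports mean estimate, bias, empirical SE, 95% CI
coverage, sign-recovery and rejection rates, counting fit failures
explicitly. The test suite runs 200 null replicates (type-I error within
Monte-Carlo bounds of 0.05) and 100 replicates at a cost weight of −2
(sign recovery ≥ 95%, relative bias ≤ 25%); these replicate counts keep
the full suite at desk scale while leaving the binomial Monte-Carlo bounds
meaningful. Single-replicate reports are flagged degenerate with coverage
undefined.

## Known limitations

* The generator's effect sizes are uncalibrated stand-ins; conclusions
  about real data require refitting on real data (the study's deposited
  dataset can be swapped in through the same `GazeTable` schema).
* The quadrature engine handles one grouping factor (participant), which
  is all the analysis requires; crossed item effects are out of scope.
* Exactly reproducing the published coefficient tables requires the
  deposited data and is not attempted here; the pipeline reproduces the
  analysis machinery and its qualitative result patterns.
* The design sampler is near-uniform, not exactly uniform, over valid
  orders (see above); composition and constraints are exact for every
  seed.
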