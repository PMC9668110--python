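# Methods

## The task

One session is 60 one-shot Ultimatum Game trials in which the participant is
always the responder. Each trial a (nominally different, anonymous) proposer
splits a 20-token endowment; the responder accepts (both sides are paid) or
rejects (both get nothing). Offers are controlled: trials 1–20 (baseline)
draw from the medium distribution N(8, 1.5) tokens, trials 21–40
(conditioning) from the low distribution N(4, 1.5), trials 41–60 (post)
from the medium distribution again. After each offer, with probability 0.67,
the responder rates their emotional reaction on a 1–9 scale. The package's
generator draws real-valued offers per block, rounds them
half-away-from-zero to integer tokens (symmetric around the block means,
which sit either on integers or half-integers) and clips to
[offer_min, offer_max] = [0, endowment]. Rating prompts are independent
Bernoulli(0.67) per trial rather than a fixed subset; the design only
specifies a percentage. The source material is internally inconsistent about
that percentage (67% in the text, 60% in a figure caption); 0.67 is the
default and the field is configurable.

## The candidate models

All six models share the inequity-averse utility of an offer s given the
current internal norm x,

    U(s) = s − α·max(x − s, 0) − β·max(s − x, 0),

with envy α ∈ [0, 10] (aversion to offers below the norm) and guilt
β ∈ [0, 10] (aversion to offers above it), and the logistic choice rule
P(accept) = 1/(1 + e^(−γU)) with inverse temperature γ. The models differ in
the norm dynamics:

- **FS** (non-learning): x is constant — 10 tokens (an equal split) in
  `FS_fixed`, a fitted constant in `FS_free`.
- **BO** (Bayesian observer): offers are treated as draws from a Gaussian
  with unknown mean and variance under a conjugate Normal–Inverse-χ² prior
  with hyperparameters (k, ν, μ̂, σ̂²), initialized at k₀ = 4, ν₀ = 10,
  σ̂₀² = 4 and μ̂₀ = 10 (`BO_fixed`) or fitted μ̂₀ ∈ [0, 20] (`BO_free`).
  After each offer: k and ν increment by 1, μ̂ moves toward the offer with
  weight 1/kₜ, and νₜσ̂ₜ² = νₜ₋₁σ̂ₜ₋₁² + (kₜ₋₁/kₜ)(sₜ − μ̂ₜ₋₁)². The
  prevailing norm at trial t is the prior mean μ̂ₜ₋₁; only the mean
  recursion enters the likelihood (σ̂² never does), so the likelihood code
  iterates μ̂ alone and the full state object is exposed for inspection.
- **RW** (delta rule): xₜ = xₜ₋₁ + ε(sₜ − xₜ₋₁) with learning rate
  ε ∈ [0, 1]; x₀ = 10 (`RW_fixed`) or fitted (`RW_free`).

Norm updates happen on every trial, after the choice, and depend on the
offer only — rejecting an offer does not stop it from moving the norm.
Emotion ratings never enter the likelihood.

Free-parameter counts: FS_fixed/BO_fixed 3 (α, β, γ); FS_free/BO_free 4
(+ initial norm); RW_fixed 4 (+ ε); RW_free 5.

### The γ bound

The γ box defaults to [0, 10] rather than [0, 1]: cohort-level fitted
temperature moments of 1.78 ± 1.58 are impossible under a unit bound, so the
wider box is the only one consistent with the parameter regime the models
are meant to occupy. It is a config field (`OptimizerConfig.gamma_bounds`).

## Likelihood and fitting

The per-participant negative log-likelihood is −Σₜ log P(choiceₜ) with the
acceptance probability clamped into [1e−12, 1 − 1e−12] before the log —
standard likelihood hygiene so saturated choices stay finite. Probabilities
returned by `p_accept` carry the same clamp.

Fitting is bounded multi-start local search per participant and model:
L-BFGS-B (ftol 1e−8, numeric gradients) from (i) the bound midpoints,
(ii) 10 uniform random restarts within the bounds, and (iii) the best 4 of
512 cheap seeded random probe evaluations of the objective. The probe stage
exists because the free-initial-norm models have a kinked, multimodal
likelihood in the norm parameter (the norm is the location of the utility
kink), which can trap a small plain multi-start below the global optimum;
probing the box densely first is far cheaper than more local runs. All
counts are configurable (`OptimizerConfig`). When a `*_free` model is fitted
by `fit_cohort` together with its `*_fixed` sibling, the sibling's optimum
(with initial norm 10) is added as one more start, which guarantees the
nested-model dominance LL(free) ≥ LL(fixed) up to optimizer tolerance.

Scores: BIC = k·ln n − 2LL and AIC = 2k − 2LL with n the participant's
number of choice trials (60 by default). Cohort-level comparison sums
per-participant scores; the winner is the argmin of the summed BIC (and of
the summed AIC, reported separately — a disagreement is flagged, never
resolved silently; a per-participant winner count is supplementary output).
Convergence flags are reported, never coerced; a flat likelihood at γ → 0 is
a valid fit, not an error.

## Synthetic cohorts

`simulate_cohort` emulates the study conditions: 30 responders, each with an
independently sampled 60-trial schedule (offers were generated per
participant, not shared) and parameters drawn from independent truncated
Gaussians at the fitted-moment defaults — α 2.58 ± 2.53, β 0.17 ± 0.32,
γ 1.78 ± 1.58 (truncated to each parameter's box), ε 0.16 ± 0.28 on [0, 1].
Only sample moments are available, so the truncated Gaussian is a modeling
choice, not an estimate of the population law. Free-initial-norm variants
sample the initial norm from a truncated Gaussian at 10 ± 2.5 tokens on
[0, 20] (no moment is reported for it; centered on the equal split). Choices
are Bernoulli draws from the model's acceptance probability; the pre-update
norm is logged per trial so recovery studies can verify trajectory
consistency exactly.

Ratings are generated by a deliberately simple synthetic rule —
clip(round(1.0 + 0.6·offer + N(0, 1)), 1, 9) on prompted trials — that makes
ratings increase with offer size on a 1–9 scale. It exists solely to
exercise the rating analysis; nothing about real children's emotional
reports (asymmetry, anchoring, drift) is modeled, and a null pre/post rating
contrast in synthetic data says nothing about real cohorts.

What passing tests on these cohorts do show: the pipeline's estimator finds
optima at least as good as a brute-force grid, recovers generating
parameters and the generating model at study size, and the generative
models produce the qualitative conditioning signature (lower medium-offer
rejection post-conditioning). What they cannot show: that any of the six
models describes real children, or that real effect sizes match the
synthetic ones.

## Model-free statistics

- Rejection rates are per-participant percentages within block (or
  block × offer size); empty cells are absent, never 0/0.
- The pre/post contrast is a classical paired t-test on per-participant
  rates, reported post minus baseline so adaptation yields a negative t.
  Cohen's d is reported as a magnitude, d = |t|/√n, with a 95% CI from
  noncentral-t inversion. (For one printed reference contrast the source
  reports d = 0.68 where t = 3.58, n = 30 gives 0.654; the package follows
  the formula, which matches the other three printed effect sizes.)
- Benjamini–Hochberg: ascending sort, ranks 1..m, critical values
  (rank/m)·q with q = 0.05 default, cutoff = largest p strictly smaller than
  its critical value, significance = p ≤ cutoff. The significant set is
  always a prefix of the rank order and monotone in q.
- The offer-size regression is a mixed-effects logistic regression of
  rejection on offer size with per-participant random intercepts and random
  offer slopes, fitted by the variational Bayes mixed GLM with a
  deterministic start vector (the library default start is drawn from the
  global RNG, which would break run-to-run determinism). If the mixed fit
  fails it falls back — with a logged warning — to a pooled logistic with
  participant-clustered standard errors. The predictor is the negated offer,
  so the coefficient is log-odds of rejection per token decrease and the
  odds ratio is ≥ 1 for offer-monotone responders; this coding is embedded
  in the result object. The exact random-effects structure of the original
  analysis is ambiguous from its description; the structure above is this
  package's stated default, not an inference about the original.
- Sliding rejection curves use a trailing window (default 5 trials; the
  window ends at trial t, defined for t ≥ window), averaged across
  participants, in percent.
- The rating contrast applies the paired t-test to per-participant block
  mean ratings; participants lacking ratings in either block are excluded
  and the exclusion count logged.

## Numerical and interface choices

- All randomness flows through `numpy.random.Generator` objects seeded from
  explicit integers; cohort simulation spawns per-participant substreams
  from a `SeedSequence`, so results are invariant to participant count
  changes only in the obvious prefix sense and runs are exactly
  reproducible. CLI outputs embed a SHA-256 config fingerprint.
- Optimizer ties are broken by first-found (strict improvement required to
  replace the incumbent).
- Degenerate inputs: zero-variance paired differences give t = 0 when the
  mean difference is zero and an explicit NaN-with-warning otherwise;
  single-outcome choice data raise a separation error in the regression;
  empty choice sequences are input errors.
- Trial indices are 1-based throughout, matching the task's "trials 1 to
  20" block language.
- Problem sizes in the validation suite: grid dominance uses 5 synthetic
  participants × 6 models against an 11-point-per-parameter grid; recovery
  uses 10 replicate cohorts of 30 × 60 trials (learning-rate recovery with
  ε ~ U[0.05, 0.6], γ ~ U[1, 5], α ~ U[0.5, 4], β = 0; model recovery with
  the default cohort sampler); determinism uses a 4-participant pipeline run
  twice. These sizes mirror the study scale where a study quantity is being
  checked and are kept modest elsewhere.

## Known limitations

- No hierarchical/group-level estimation (participants are fitted
  independently, as in the original analysis) and no random-effects
  Bayesian model selection; summed BIC/AIC is the selection rule.
- No proposer model, reaction times, or age/sex covariate analyses.
- The Bayesian observer's learning schedule is fixed by its hyperparameter
  recursion (effective learning rate 1/kₜ); individual differences in
  adaptation speed are expressible only by the RW models.
- Model recovery at the default sampler is imperfect by construction: many
  sampled agents have ε near 0 (RW collapses to FS) or low γ (choices near
  chance), in which case parsimony can legitimately favor a 3-parameter
  model on a given cohort. The recovery criterion is therefore a majority
  over replicates, not per-cohort certainty.
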