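# Methods

## Setting and estimand

A single-arm trial with a dichotomous endpoint is augmented with external
patient-level data on the same treatment (the motivating source is an
expanded-access program running concurrently with the trial). The estimand
is the response rate `θ` in the *trial* population. Borrowing must therefore
guard against two distinct distortions: external patients who differ from
trial patients in measured characteristics, and residual outcome drift that
the covariates do not explain (site effects, assessment differences,
unmeasured prognosis).

## Two-stage model

**Stage 1.** Trial membership `z` is modelled by unpenalised logistic
regression on the covariates, fitted by IRLS (statsmodels GLM, binomial
family, iteration cap 100, deviance tolerance 1e-8). The fitted probability
`λ_i` feeds one of three weighting schemes; the default gives every trial
patient weight 1 and external patients the capped odds `min{1, λ/(1−λ)}`,
which targets the trial-population estimand and guarantees no external
patient outweighs a trial patient. The intercept-bearing MLE satisfies
`Σλ_i = N₀` and `mean(λ_i) = N₀/N`; both identities are asserted in the test
suite on every converged fit. Under quasi-separation (a covariate level
present only externally) the separated coefficients diverge, the affected
fitted probabilities go numerically to 0, and the capped weight is exactly
the intended limit 0 — the fit is returned with per-subject separation
flags and a warning rather than an error, because this "automatic
exclusion" is desired behaviour. Weights above 1 are never produced by the
default scheme; the reciprocal schemes (`ate`, `att_external`) clamp `λ` at
1e-12 and raise a non-overlap error rather than emit infinite weights.

**Stage 2.** The external log-likelihood is scaled per patient by `w_i` and
globally by a power `δ ∈ [0,1]` with a normalising constant `C(δ)` keeping
the joint posterior proper. With a uniform prior on `θ`, `C(δ)` is the Beta
function `B(δ·a_e+1, δ·b_e+1)` of the weighted counts, the marginal
posterior of `δ` is a ratio of Beta functions times the `δ` prior, and
`θ|δ` is exactly Beta. The implementation keeps every Beta-function
evaluation in log space (`scipy.special.betaln`); the weighted counts reach
hundreds and raw Beta functions underflow.

A note on the prior on `δ`: the marginal density is implemented as

    log B(δ·a_e + a_0 + 1, δ·b_e + b_0 + 1) − log C(δ) + log BetaPdf(δ; α_δ, β_δ)

i.e. the `θ`-integral always carries "+1" exponents (the uniform `θ` prior)
and a non-uniform `δ` prior enters only through its density factor. This is
the only self-consistent arrangement: it makes the marginal of `δ`, the
conditional of `θ`, and the prior specification agree with each other for
every `(α_δ, β_δ)`, and it reduces to the familiar pure Beta-ratio form in
the default uniform case. The default prior on `δ` is uniform.

## Sampling

`δ` is drawn by rejection sampling: uniform proposals on [0,1], acceptance
probability `exp(logπ̃(δ) − log M)` with the envelope `M` located on a
2048-point grid plus bounded local refinement (golden-section via
`scipy.optimize.minimize_scalar`). Proposals come in batches of 10,000; the
accepted subset is the posterior sample, the acceptance rate is reported,
and a `min_draws` argument tops up with further batches when a concentrated
posterior accepts few proposals (up to 100 batches, then a hard error).
Because accepted draws are iid, no convergence diagnostics are needed.
`θ` is then drawn once per accepted `δ` from its exact conditional Beta.
Degenerate input `a_e + b_e = 0` (no external data or all weights zero)
short-circuits to direct draws from the `δ` prior. Priors with
`α_δ < 1` or `β_δ < 1` make the density unbounded at an endpoint; the
envelope search detects this and raises a degenerate-posterior error rather
than sampling from a broken envelope.

Fixed-`δ` comparators (ignore `δ=0`, pooling `δ=1`) use exact Beta
posteriors and exact Beta quantiles for their intervals; estimated-`δ`
models use empirical equal-tailed 2.5%/97.5% quantiles of the draws
(linear-interpolation convention). All seeds flow through
`numpy.random.SeedSequence` spawning, so every nested component has an
independent, reproducible stream.

## Synthetic data

### Simulation cohorts

`generate_dataset` draws trial covariates iid Normal(μ₀, σ₀²) per
coordinate and external covariates from a per-patient two-component
mixture: with probability ψ the patient is "trial-like" (same Normal),
otherwise shifted to Normal(μₑ, σₑ²). Outcomes are Bernoulli with
`logit p = β₀ + β·x + η·I(z=1)`. The drift `η` attaches to the internal arm
as a deliberate convention (a `drift_target` switch flips it): what matters
for the operating characteristics is the *contrast* between sources, and
the truth is always the population trial-arm rate of the simulated
configuration, estimated as the mean empirical trial rate over 1000
auxiliary datasets on a dedicated RNG stream.

Defaults are the study's base case: N₀ = Nₑ = 400, K = 5 covariates with
coefficients 0.1, β₀ = 0, σ₀ = σₑ = 1, ψ = 0.5. The scenario grid sweeps
η ∈ [−0.5, 0.5] (drift scenario, null covariate effects) or
μₑ ∈ [−0.5, 0.5] (mixture scenarios) over 11 equally spaced points;
settings change the sample-size ratio (Nₑ = 2000 or 200), the covariate
count (K = 10), or shrink both arms to 100. The "superfluous covariates"
scenario zeroes the first j coefficients and rescales the rest so Σβ is
unchanged, isolating the effect of allocation-only covariates.

The type-I error of a method at a grid point is the fraction of replicates
whose equal-tailed 95% interval excludes the population trial rate
(closed endpoints). RMSE is reported with a delta-method Monte-Carlo
standard error so that comparisons against published or expected values can
be judged against simulation noise. Methods failing in more than 5% of a
grid point's replicates have that cell suppressed (with an accounting
record) instead of biasing the summary with selective successes.

At these sample sizes the simulated RMSE baselines land near the binomial
sampling error of the estimators (e.g. trial-only ≈ 0.024 at N₀ = 400 with
posterior-mean shrinkage). Published figures for comparable designs sit
somewhat above that; since replicate counts and incidental variance sources
in such studies are rarely fully specified, the harness reports its own
metric plus MC-SE rather than forcing agreement.

### Case fixture

The real case cohort is under restricted access and cannot ship.
`generate_case_fixture` builds a synthetic cohort with the published
structure: 132 trial + 241 external patients; age Normal(50, 15) vs
Normal(53, 13); 39% female in both; melanoma-stage and ECOG category
frequencies as published, with ECOG grades 2–3 (12.4% + 0.4%) and
unresectable stage III (4.6%) occurring only externally. Outcomes follow a
logistic model in stage and ECOG,
`logit p = 0.517 − 0.25·I(M1c) − 0.5·I(unresectable III) − 0.15·I(ECOG 1) −
0.6·I(ECOG 2) − 1.0·I(ECOG 3)`, whose intercept was solved once against the
category mix to give expected response rates 57.0% (trial) and 54.1%
(external). Only the marginals are published, so this joint law is a
modelling choice; the fixture reproduces the *qualitative* case phenomena
(automatic zero-weighting of trial-ineligible externals, partial borrowing)
but not the real data's joint covariate-outcome dependence. Passing tests
on the fixture therefore validate the pipeline's mechanics, not the
published real-data estimates (posterior mean 56.4%, interval
(49.4%, 63.3%), ≈ 67 borrowed patients), which require the restricted data.

## Bootstrap design uncertainty

The two-stage construction ignores estimation noise in the propensity
model. `bootstrap_design_uncertainty` quantifies it: resample the combined
cohort (stratified by source, so neither cohort can vanish from a
resample), refit the membership model, apply the refitted coefficients to
the *original* cohort, recompute the posterior, and report the spread of
the posterior means of `θ` and `δ` across resamples (default 30). With
resampling disabled the run reuses the original fitted probabilities and is
an exact no-op relative to the base analysis — the natural correctness
anchor for the machinery.

## Known limitations

- Binary endpoints only; the conjugacy that makes sampling exact does not
  carry to survival or continuous outcomes.
- The weight cap at 1, while desirable for a regulator, means the weights
  cannot fully correct measured confounding in either direction.
- First-stage uncertainty is assessed (bootstrap) but not propagated into
  the posterior.
- The propensity model is as good as its covariates: allocation-only
  covariates dilute the weights (quantified by the superfluous-covariates
  scenario), and unmeasured outcome-relevant differences are handled only
  through `δ`.
- The external-comparator registry (`register_comparator`) lets published
  stratification-based borrowing methods be benchmarked in the same
  harness, but none is bundled.
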