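# Methods

## Models

### Within-study layer (all models)

Each study *i* contributes observed log hazard ratios on the surrogate and
final outcome with known standard errors and within-study correlation:

    (Y1i, Y2i) ~ N((μ1i, μ2i), Σi),
    Σi = [[σ1i², ρwi σ1i σ2i], [ρwi σ1i σ2i, σ2i²]].

For RCTs μji = δji (the true effects). When ρwi is unreported it receives
an independent Uniform(0, 1) prior per study; alternatively all ρwi can be
pinned to a single externally estimated value (0.52 in the mCRC case
study's sensitivity analysis) via `PriorConfig.with_rho_w_fixed`.

### Daniels & Hughes (fixed effects)

δ1i ~ N(0, 10⁴) independently; δ2i | δ1i ~ N(λ0 + λ1 δ1i, ψ2²); priors
λ0, λ1 ~ N(0, 10⁴) and ψ2 ~ Uniform(0, 2) (sensitivity: Uniform(0, 100)).
Because the model conditions on noisy surrogate effects without a
between-study distribution for δ1, the posterior of λ1 attenuates towards
zero when within-study error on the surrogate is comparable to the
between-study spread — a property of the model, not of the sampler (we
verified the sampler against full numerical integration of the
marginalized three-parameter posterior on small datasets). Recovery and
coverage checks are therefore run in a regime where within-study SEs are
small relative to heterogeneity; see "Synthetic data" below.

### BRMA, product normal formulation

δ1i ~ N(d1, ψ1²), δ2i | δ1i ~ N(λ0 + λ1 δ1i, ψ2²) with ψ1² = τ1²,
λ1 = ρ τ2/τ1, ψ2² = τ2² − λ1²τ1²; priors d1, λ0 ~ N(0, 10⁴),
τ1, τ2 ~ Uniform(0, 2) (sensitivity: Uniform(0, 100)), ρ ~ Uniform(−1, 1).
λ1, ψ2², R² = ρ² and the marginal final-outcome mean are derived per draw,
so the product-normal identities hold exactly in every posterior sample.
The derived quantity reported as `d2` is λ0 + λ1 d1, the marginal mean of
the final-outcome effect implied by the conditional parameterisation; it
is labelled derived because it is a function of sampled parameters, not a
sampled parameter itself. `transform_brma_params` computes ψ2² as
τ2²(1 − ρ²), algebraically identical to τ2² − λ1²τ1² but exactly zero in
floating point at ρ = ±1.

### Bias-adjusted BRMA

The between-studies layer is unchanged. For cRWE studies
μji = δji + αji with αji ~ N(αj, σαj²); for matched sRWE studies
μji = δji + βji with βji ~ N(βj, σβj²), j = 1, 2. Bias means get
N(0, 10⁴) priors. Priors for the bias SDs are not pinned down by
convention; we default to Uniform(0, 2) on each SD for consistency with
the other SD priors and expose them in `PriorConfig`. The model requires
at least one non-RCT study; an all-RCT input is redirected to the base
model.

## Inference

No probabilistic-programming backend is used: the models are conditionally
conjugate almost everywhere, so a dedicated Gibbs sampler is both simpler
and faster.

* (δ1i, δ2i): exact bivariate-normal full conditionals (natural-parameter
  form), vectorised across studies.
* (λ0, λ1) in the fixed-effects model, and d1, λ0 in BRMA: exact normal
  full conditionals.
* ψ2 (fixed-effects model) and the bias SDs: under a Uniform(0, U) prior
  on an SD with n normal residuals, the precision has a truncated gamma
  full conditional, sampled by inverse CDF (exact); for groups with a
  single study a slice update is used instead.
* τ1, τ2, ρ: univariate slice sampling (stepping-out/shrinkage) on their
  bounded supports; the between-model log density is evaluated from
  sufficient statistics, so each evaluation is O(1).
* unknown ρwi: independence Metropolis with Uniform(0, 1) proposals
  (two sweeps per iteration); when a study's Y2 is missing its ρwi drops
  out of the likelihood and keeps its prior.

Chains are seeded through `numpy.random.SeedSequence`, so every fit is
exactly reproducible from `MCMCSettings.seed`. Defaults are 150,000
iterations with 50,000 burn-in and two chains; tests use far shorter
chains. Convergence is summarised by split-R̂ < 1.05 and bulk ESS > 400
per reported scalar (via `arviz`); violations raise a
`ConvergenceWarning` and set `converged=False` rather than failing
silently. Numerical floors: ψ2² ≥ 1e−12 inside density evaluations,
SDs ≥ 1e−5 where they enter as precisions.

Point estimates are posterior means except for the variance-type
parameters ψ2² and R², which are reported as medians (their posteriors
are skewed); `summarize_posterior(style="auto")` codifies the
mean-vs-median choice as |mean − median| > 0.1 × IQR. Credible intervals
are equal-tailed 2.5%/97.5% empirical quantiles throughout (a
highest-density convention would be the main alternative; equal tails
match how such intervals are usually reported).

## Cross-validation

One study's Y2 at a time is flagged missing; the fit then uses only the
marginal N(μ1i, σ1i²) likelihood for that study. The predicted mean is
the posterior mean of that study's δ2; the predictive variance is
σ2i² + var(δ2 draws), and two intervals are emitted: equal-tailed
quantiles of predictive draws (δ2 draws plus simulated N(0, σ2i²)
observation noise) and the normal approximation mean ± 1.96·√variance.
The width ratio uses the normal-approximation width over the observed
Wald width 2·1.96·σ2i, which makes the ≥ 1 invariant exact. Per-study
refits use seed = base seed + study index.

## Matching

Distances are computed and compared at full precision; only display
rounds to 3 decimals (when working from a transcribed 3-decimal matrix,
the transcribed values are compared directly). The threshold comparison
is inclusive (≤): nothing in the bundled case-study matrix sits exactly
on a threshold, so the choice is observationally irrelevant there, but
it must be fixed. Greedy selection takes the globally smallest remaining
entry; ties break lexicographically by (row id, column id). Both the
derived threshold (max between-arm distance of a reference design) and a
manual override are supported, the override taking precedence — matching
the practice of applying a rounded 0.030 when the RCT-derived maximum
was 0.027.

## Pseudo-IPD reconstruction

Within each risk-table interval the number censored is iterated until the
implied number at risk at the next boundary matches the printed count;
censoring times are spread uniformly within the interval, and event
counts at each digitized coordinate are the rounded solutions of the
product-limit drop equations. Infeasible guesses (more censoring than the
observed drops allow) back the search off; if no feasible pattern exists
the interval is reported in a `ReconstructionError`. Without a risk
table, a single interval is used and the censoring count is iterated
until implied total events match the reported total (constant censoring
rate over follow-up). Patients still at risk at the last coordinate are
censored there. Digitized coordinates are monotonicity-repaired
(cumulative minimum, clipped to [0, 1]) first; repairs larger than 0.02
absolute survival trigger a warning since they indicate digitization
problems. Kaplan–Meier estimation and the Cox fit go through `lifelines`;
the Cox model uses a single binary arm covariate and Efron tie handling
(reconstruction places many events at shared coordinates; `lifelines`
implements Efron only, and no Breslow option is exposed).

## Synthetic data

`simulate_meta_dataset` draws true effects from the BRMA between-studies
model, adds design-specific bias (zero for RCTs), and adds
bivariate-normal within-study error with SEs sampled uniformly on a
configurable range. Exactly one of (τ2, ρ) or (λ1, ψ2) is specified; the
other is derived, so the two parameterisations always agree. Each study
consumes an independent seed substream, so enlarging one design group
never changes another group's draws.

Defaults emulate the mCRC evidence base: 7 RCTs, 4 cRWE, 2 sRWE;
d1 = −0.36, τ1 = 0.20, τ2 = 0.16, ρ = 0.74, λ0 = 0.05; SEs uniform on
(0.10, 0.35); ρw = 0.52. What the generator does *not* emulate: real
confounding mechanisms (bias enters only as additive study-level terms),
non-proportional hazards, non-normal random effects, and correlation
between a study's size and its effect. Passing tests therefore show that
the estimators recover the generating process they assume, not that the
assumptions hold in any particular application.

Parameter-recovery and coverage tests run at n = 30 studies with
generating λ0 = 0, λ1 = 0.7, ψ2 = 0.1, τ1 = 0.25 and within-study SEs
uniform on (0.02, 0.05) — deliberately small relative to τ1 so that
credible-interval coverage probes sampler calibration; in noise-dominated
regimes the fixed-effects model attenuates (see above) and coverage of a
fixed generating value is not the right diagnostic. Replicate fits use
3,000 iterations (1,000 burn-in), which matched longer runs in these
checks. Survival fixtures use exponential event times with exponential
plus administrative censoring.

## Known limitations

* The fixed-effects model's attenuation under heavy within-study error
  means its λ1 is conservative exactly when the evidence base is weak.
* Aggregate matching cannot adjust for within-study confounding; the bias
  model absorbs systematic design effects only as additive shifts.
* The reconstruction assumes uniform censoring within risk-table
  intervals (constant rate overall when only totals are known); heavily
  informative censoring will degrade the approximation.
* Slice-based updates for (τ1, τ2, ρ) mix slowly when the number of
  studies is very small and SDs are near their prior bounds; the
  diagnostics flag this, and longer chains are the remedy.
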