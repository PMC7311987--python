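# Methods

This note records the modelling assumptions, default parameter choices
and numerical decisions behind `sf6duq`, and what the synthetic-data
experiments do and do not demonstrate.

## State space and predictors

An SF-6D state is one level per dimension — physical functioning (6
levels), role limitation (4), social functioning (5), pain (6), mental
health (5), vitality (5) — giving 6·4·5·6·5·5 = 18,000 states, coded as
6-digit strings (`111111` full health, `645655` the pits state). The
predictor vector of a state has 26 binary entries: 25 level dummies
I_δλ (λ ≥ 2, dimension-major and level-ascending: PF2…PF6, RL2…RL4,
SF2…SF5, PAIN2…PAIN6, MH2…MH5, VT2…VT5) plus MOST, which is 1 when any
dimension is at a most-severe level (PF 4–6, RL 3–4, SF 4–5, pain 5–6,
MH 4–5, VT 4–5). The dummy ordering is a package convention; nothing in
the model depends on it, but it fixes the coefficient layout
(intercept + 26 terms = 27) used by every artifact. Only this 26-term
specification is supported; alternative interaction sets are out of
scope.

## Generative model for synthetic studies

No individual-level SF-6D valuation data are publicly deposited, so all
fitting experiments run on synthetic studies drawn from the model the
estimators assume:

    y_ij = μ + θ′I(x_ij) + α_j + δ_i + ε_ij

with respondent effects α_j ~ N(0, σ_α²), state-level misspecification
effects δ_i ~ N(0, σ_δ²) and noise ε_ij ~ N(0, σ_ε²). Defaults:

- **μ = 1, θ**: utility decrements increasing in severity within each
  dimension (e.g. PF6 −0.117, PAIN6 −0.171, MOST −0.061), chosen so
  noise-free utilities span roughly 0.30–1.0, the range typical of
  published SF-6D value sets. Mean state valuations in real studies sit
  mostly between ~0.39 and 1.0; the default truth reproduces that span.
- **σ_α = 0.10, σ_ε = 0.20**: adjusted SG scores are noisy; an
  observation SD of ~0.22 and a modest respondent-level component are in
  line with the residual spread seen in published valuation-study fits.
- **σ_δ = 0** by default (the additive model is exactly right);
  scenarios that study misspecification set σ_δ = 0.04, i.e. state-level
  systematic errors of a few utility points, large enough to matter
  relative to coefficient SEs (~0.02) without dominating the data.

Study designs are presets: UK-like (249 pool states, 611 respondents, 6
valuations each, missingness 148/3666 ≈ 4% completely at random, for an
expected ~3518 records) and HK-like (197 states, 582 respondents, 8
each, 60/4656 missing). States are allocated to respondents uniformly
without replacement, matching the random-allocation assumption of the
random-effects model; the pits state is always included in the pool, as
valuation designs anchor the severe end. Missingness is completely at
random because only missing counts, not a mechanism, are reported for
such studies. Adjusted SG scores are not truncated (worse-than-dead
values below 0 are legitimate); an optional clamp to [−1, 1] exists.

Measurement samples (one self-reported state per subject) are
multinomial draws over all 18,000 states. The default prevalence vector
is a mixture of three severity classes (healthy/moderate/poor, weights
0.6/0.3/0.1, within-dimension level probabilities decaying geometrically
with class-specific tilts 1.5/0.6/0.15). The mixture induces the
positive cross-dimension correlation seen in self-reported data and
concentrates a 4,596-subject sample on ~1,400 distinct states with mean
utility ≈ 0.86, a realistic general-population profile.

What the generator does **not** emulate: interviewer and ordering
effects, the "ping pong" SG elicitation procedure, non-normal or
heteroscedastic SG noise, informative missingness, and respondent
covariates. Passing tests therefore demonstrate correctness of the
estimators under their assumed model, not robustness to the ways real
valuation data violate it.

## Random-effects estimation

`RandomEffectsModel` maximises the exact marginal Gaussian likelihood.
Within a respondent the covariance is compound-symmetric, so the GLS
normal equations, quadratic form and log-determinant reduce to closed
forms in per-respondent cross-products (Sherman–Morrison); the fixed
effects are profiled out and a Nelder–Mead search runs over
(log σ_α², log σ_ε²). ML (not REML) is used so the reported coefficient
covariance — the inverse GLS information at the estimates — is exactly
the object the PSA samples from. That covariance is conditional on the
fitted variance components (the standard mixed-model convention);
uncertainty in σ̂² is not propagated. A 200-replicate calibration at the
UK-like design shows ±1.96 SE coverage of ~95%, so the conditioning
costs little at this size.

Numerical choices: the residual variance is floored at 1e-12 so the
noiseless (perfect-interpolation) limit stays finite; a fitted σ_α²
below 1e-10·σ_ε² is reported as exactly 0 (boundary); unidentified
design columns (levels never observed in the pool) are detected by
pivoted QR, dropped with a warning, and reported as coefficient 0 with
SE 0; when every respondent contributes one record, σ_α² and σ_ε² are
not separately identified and σ_α² is pinned at 0 with a warning.

Predictions: utility = coef·[1, I(x)], SE = √(z′V̂z). Full health
`111111` is *anchored* at (1, 0) in all reported tables, as value-set
tables display it, even though the fitted intercept need not be exactly
1; the raw prediction is available via `anchored=False`.

## Probabilistic sensitivity analysis

Coefficient draws are multivariate normal, factored through a symmetric
eigendecomposition with eigenvalues in [−1e-10·max, 0) clipped to zero
(numerical PSD repair); materially negative eigenvalues raise. B
defaults to 10,000. Per-state intervals are percentile (2.5/97.5), the
PSA convention, rather than normal approximations; for a linear
predictor the Monte-Carlo SD converges to the delta-method SE (verified
to <2% relative error at B = 1e5). The SD over draws uses divisor B−1.

## Bayesian hierarchical model

Priors: coefficients N(0, 10⁶); σ_δ², σ_α² InverseGamma(0.001, 0.001).
The residual variance σ_ε² receives the same inverse-gamma prior —
required for a complete Gibbs scheme. Every full conditional is
conjugate; the sampler is blocked (all 27 fixed effects drawn jointly
per sweep, which mixes far better than scalar updates under correlated
dummies), with scalar normal conditionals for each α_j and δ_i and
inverse-gamma conditionals for the variances. Defaults are two chains,
10,000 burn-in and 10,000 kept iterations, no thinning; tests and the
acceptance script run 1,000 + 2,000 per chain, which already yields
R̂ < 1.02 on every monitored parameter at the UK-like design — the
blocked sampler mixes quickly, so the reduced runs are a problem-size
choice, not an approximation of a different posterior.

Chains start overdispersed: coefficients at OLS plus chain-scaled
noise, variances scattered over two orders of magnitude. Convergence is
the classical split-chain potential scale reduction factor per scalar
parameter (floored at 1; a degenerate constant chain raises), with
R̂ ≤ 1.1 operationalising "converged"; the implementation is
cross-checked against arviz's rank-normalised R̂ in the tests.

δ effects exist only for states valued in the data. For a valued state
the posterior utility uses that state's fitted δ_i draws by default
(`use_fitted_delta=False` integrates δ out instead); for an unvalued
state a fresh δ ~ N(0, σ_δ² draw) is attached per retained draw. Any
variance component can be pinned (`fixed_variances=`), which both
enables the conjugate-reduction oracle tests and provides the δ-free
comparison model.

## Population mean utility and the variance decomposition

With counts over self-reported states and a symmetric Dirichlet prior
(α₀ = 1/18000 per state — one pseudo-count in total, negligible next to
the data but keeping the posterior proper over the full space), the
posterior of the prevalence vector is Dirichlet(α₀ + counts). The mean
utility f̄ = Σ p_i u_i is propagated by nested Monte Carlo: for each
value-set draw, n_p_draws (default 100) prevalence vectors are drawn and
f̄ formed; the sampling component is the mean of within-value-set
variances and the value-set component the variance of within-value-set
means, summing (law of total variance) to the total.

Numerical choice: states never observed in the sample are represented by
one aggregate Dirichlet category carrying mass α₀·(18000 − k), valued at
the draw's mean utility over those states. The neglected within-rest
composition variance is O(α₀) of an already ~2·10⁻⁴ posterior share —
far below Monte-Carlo error — while cutting the sampled dimension from
18,000 to the observed support. With α₀ = 0 the computation is exact.

Two parallel routes exist deliberately: the empirical plug-in route
(`psa_population_mean`: usual SE = sample SD/√n at the point-estimate
value set, value-set SE = SD of the sample mean over coefficient draws)
and the Dirichlet route (`posterior_mean_utility`, serving both PSA and
Bayesian value-set draws). Under a fixed value set the Dirichlet
posterior variance of f̄ is SD²/(n+1), so the two routes agree to O(1/n)
and the reported `underestimation_pct = 100·(1 − se_sampling/se_total)`
is comparable across them.

## Intervals and coverage

Two kinds of per-state intervals coexist in the summary tables:

- `*_lower/upper`: parameter (value-set) uncertainty only — percentile
  bounds for PSA/Bayes, normal bounds for the analytic method.
- `*_cover_lower/upper`: used for coverage of *observed* state means;
  the method's parameter SD is combined in quadrature with the sampling
  SE of the observed mean. The naive method carries no parameter
  uncertainty, so its coverage interval uses the sampling SE alone and
  is nested inside the others by construction; coverage is then weakly
  increasing from naive to PSA to Bayes, strictly so when
  misspecification is present.

This combined definition is a package choice: published comparisons of
"with and without parameter uncertainty" intervals do not state one
consistent construction (reported mean widths for the same comparison
differ between sources), so no printed width or coverage percentage is
asserted — only the ordering, which is the substantive claim.

## Problem sizes

Defaults follow the documented designs (B = 10,000 coefficient draws;
10,000 + 10,000 Gibbs iterations; 10,000 × 100 nested draws). The test
suite and acceptance script use scaled-down sizes chosen so every check
retains comfortable Monte-Carlo margins: 200 recovery replicates,
B = 1e5 for the PSA/analytic comparison (MC error ~0.2% against a 2%
bound), 2 × (1,000 + 2,000) Gibbs sweeps, and 1,500–2,000 × 100 nested
population draws (the additivity identity is algebraic up to
degrees-of-freedom corrections, so it holds to ≪3% at any decent size).

## Known limitations

- The value set is linear in fixed dummies; mean models, nonparametric
  Bayesian models and respondent covariates are out of scope.
- Variance-component uncertainty is not propagated into the PSA draws.
- The Gibbs sampler assumes Gaussian SG noise; heavy-tailed elicitation
  error would widen true posteriors beyond what is modelled.
- Out-of-pool Bayesian prediction marginalises δ with fresh draws; if
  misspecification is spatially structured across the state space this
  understates local bias.
- The synthetic generator is the same family the estimators assume, so
  the experiments validate implementation and calibration, not model
  adequacy on real valuation data.
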