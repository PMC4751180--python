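# Methods

## Generating model

Each cohort is a mixture of two latent subpopulations. A logistic model
decides lifetime risk: subject i with allele count x_i ∈ {0,1,2}
(binomial(2, p), p = 0.25) and background score b_i ~ N(0, 37,500) is at
risk with probability expit(c + β_OR·x_i + β_bg,OR·b_i). The cure
fraction is the marginal probability of *not* being at risk; the
intercept c is solved so the marginal expectation hits the requested cure
fraction exactly (3-point genotype sum × 80-node Gauss–Hermite quadrature
over the background, bracketed root find, tolerance ~1e-12). Note the
at-risk orientation: c → +∞ corresponds to cure fraction 0; at cure
fraction 0 the logistic component is dropped and everyone is at risk.

At-risk subjects get an age of onset from a Weibull accelerated failure
time model: T = λ·exp(a_SNP·x + a_bg·b)·V with V a standard
Weibull(k) variate, k = λ = 20 (baseline median onset
20·(ln 2)^(1/20) ≈ 19.64 years). Because a Weibull AFT is also a
proportional-hazards model, a = −β_HR/k converts the log hazard ratio to
the log acceleration factor, and the identity a·k + β_HR = 0 holds
exactly in every resolved effect set. Censoring is uniform on ages
15–25, drawn independently for every subject (non-informative); a cured
subject's observation is its censoring age, and an at-risk subject whose
onset exceeds its censoring age is censored, never truncated.

The background score is simulated in its normal limit rather than as a
sum of 100,000 binomial SNPs; one score per subject feeds both linear
predictors with separate coefficients.

## Heritability parameterization

Effects are specified as heritabilities and converted to coefficients by
inverting

    h² = β²·Var(X) / (β²·Var(X) + β_bg²·Var(X_bg) + Var(ε))

with Var(X) = 2p(1−p) = 0.375 and Var(X_bg) = 37,500. Var(ε) is the
standard error variance of each scale: π²/3 (standard logistic
distribution) for the risk component and π²/6 (standard minimum
extreme-value distribution, the Weibull error on the k·log-time scale)
for the onset component, so the survival coefficient solved from h² is
directly a log hazard ratio. The background coefficient is solved first,
then the SNP coefficient with the background variance component in its
denominator — which is why a 50% background heritability raises the
OR/HR implied by a 1% SNP heritability (1.347→1.523 and 1.234→1.347).
Both conversions are exact algebraic inversions, verified in the tests by
round-tripping h² → β → h² to 1e-10.

## Analysis models

All estimators see only (genotype, observed time, event); the background
score and the latent truth columns are never used, mimicking a single-SNP
GWA analysis.

**Logistic regression** — Newton–Raphson/IRLS with step-halving on the
Bernoulli likelihood; accepts fractional responses in [0,1], which the EM
M-step needs. Complete separation or a constant response is flagged as
non-convergence (coefficient cap |β| ≤ 30), never raised.

**Cox PH** — Newton–Raphson on the one-dimensional weighted Breslow
partial likelihood with suffix-sum risk sets; simulated times are
continuous so ties have probability 0 and Breslow coincides with Efron
(relevant when comparing against software whose tie default differs).
Monotone likelihoods (all events at a covariate extreme) are flagged.
Zero-weight subjects drop out of the risk sets.

**Mixture-cure Cox (EM)** — initialization: logistic fit on the naive
event indicator, Cox fit with unit weights, Breslow baseline at those
values. E-step: an event subject is at risk with certainty; a censored
subject's weight is π·S/(1−π+π·S) with π its logistic at-risk probability
and S = S₀(t)^exp(β·x). M-steps: fractional-response logistic on the
weights, weighted Cox, Breslow baseline at the new values. The baseline
survival is forced to 0 beyond the last event time (zero-tail
constraint), without which late censored subjects would never be pulled
toward the cured class and the cure fraction would be unidentified.
Convergence: maximum absolute change of (intercept, log-OR, log-HR)
below 1e-6, capped at 500 iterations. The observed-data log likelihood
is tracked on demand and is non-decreasing up to 1e-8 per step (the
slack absorbs the semiparametric baseline update). Cohorts with no
events or no censored subjects raise an identifiability error — the cure
fraction is then at a boundary and the logistic part is undefined.

Standard errors for both cure-model coefficients come from a
nonparametric bootstrap (default B = 100; the acceptance runs use B = 50):
resample subjects with replacement, rerun the EM, take the standard
deviation of the converged replicate estimates; non-converged replicates
are dropped and counted. P-values are two-sided normal Wald throughout.
The bootstrap was chosen because the estimation approach this follows
does not prescribe a variance estimator; B is exposed so sensitivity can
be checked.

## Monte Carlo engine

A cell = one design. Per-replicate seeds are spawned from the cell seed
via `numpy.random.SeedSequence([seed, rep])`, and per-cell seeds from the
grid seed likewise, so results are bit-identical for any worker count
(joblib parallelism over cells). Rejection rates are the fraction of
two-sided Wald p-values below α = 0.1 (the study's threshold, chosen over
0.05 for more reliable type-1 estimates) among fits with a finite
p-value; medians of exponentiated estimates are taken over all converged
fits (so bias summaries do not require a bootstrap). Convergence counts
are reported per cell. The two grids are the 152-cell traditional sweep
(cure fraction 0–0.90 step 0.05 × each SNP h² ∈ {0, 1%} × background
∈ {0, 50%}) and the 20-cell cure sweep (SNP h² jointly 0 or 1% ×
background × cure fraction {0.1, 0.3, 0.5, 0.7, 0.9}).

## Problem sizes

The reference replication count is 10,000 per cell; the bundled analysis
drivers and the test suite run reduced sizes chosen so the Monte Carlo
error is small relative to the effects being demonstrated: 1,000
replicates of n = 500 for traditional type-1/power checks (3 binomial SEs
≈ 0.028 around α = 0.1), 250 replicates of n = 200 with B = 50 for the
cure-model type-1 check (≈ 0.057), 400–1,000 replicates for bias medians
(the Monte Carlo SE of a median log-estimate is ≈ 1.25·σ/√reps, well
under the 5% bias band tested). Full-scale runs are a matter of raising
`--n-reps`.

## What the generator does and does not emulate

It captures the essential structure of survival GWA data under a cure
process: a latent never-affected class, genetic effects on two scales,
polygenic confounding through an omitted covariate, and non-informative
right-censoring over an interval covering the onset distribution. It does
not simulate linkage disequilibrium, per-SNP background genotypes,
informative censoring, family relatedness, or non-Weibull onset
distributions — so passing tests demonstrate the estimators' behavior
under this model, not robustness to those violations. One documented
quirk: with shape = scale = 20 the baseline onset variance is ≈ 1.46
years²; descriptions of this setup sometimes quote 1.56, but the
implemented parameters are the ones that give the 19.6-year median.

## Numerical choices and edge cases

- Coefficient cap ±30 doubles as the separation / monotone-likelihood
  detector in both inner fitters.
- Cox Newton steps are clipped to ±5 to avoid overshooting from poor
  starts; the 1-D Breslow log partial likelihood is concave so the
  iteration is otherwise safe.
- E-step denominators are floored at 1e-300; weights are clipped to
  [0, 1].
- Degenerate designs (cure fraction 1, n < 2, h² ≥ 1) are rejected at
  construction; grid cells that fail at run time are logged and reported
  as rows with an `error` column rather than aborting the grid.
- Cohort files are TSV with a mandatory header; missing onset is the
  literal `NA`; parse errors name the offending line.
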