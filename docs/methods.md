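# Methods

## Model

`allomix` models the diameter at breast height of tree *j* in genotype
group *i* as

    y_ij = f(beta + B u_i; LH_ij, LCD_ij, P1_ij) + eps_ij

with a nonlinear mean function `f`, fixed effects `beta`, and a
genotype-level random-effect vector `u_i ~ N(0, Psi)` perturbing a chosen
subset of the coefficients (selection matrix `B`). Residuals are
independent Gaussian with a variance function:
`var(eps) = sigma^2 x^(2 gamma)` (power), `sigma^2 exp(2 gamma x)`
(exponential) or `sigma^2` (constant), where `x` is LH or LCD. No
within-group autocorrelation is modelled (the within-group correlation
matrix is the identity); a hook for richer structures exists but is
deliberately unimplemented.

Four mean families are provided — logistic, exponential (decaying form, its
coefficients free to fit negative), power, and a Richards-type saturating
form without a shape exponent — exactly as used in the DBH-allometry
literature this package serves. Only the power family carries
planting-density dummy extensions, one per coefficient slot
(`on_a`, `on_b`, `on_c`); the `on_b` variant (dummy on the height exponent)
is the default pipeline model. The density dummy encodes planting density
only: high-density spacing = 1, everything else = 0; fertilization
treatments are intentionally not modelled.

Assumptions worth stating explicitly:

- genotype effects are exchangeable draws from one common `Psi`,
  independent of the covariates;
- residuals are Gaussian and independent across trees given the genotype;
- the model is a single cross-section — repeated measurements of the same
  trees across survey years are not represented;
- groups are single-level (genotype); crossed or nested (genotype-in-plot)
  effects are out of scope.

## Estimation

Maximum likelihood (not REML — keeping likelihood-ratio tests on fixed
effects valid) via an alternating scheme in the Lindstrom–Bates style:

1. **PNLS step.** Given `(Psi/sigma^2, gamma)`, minimize
   `sum_ij ((y - f)/w)^2 + sum_i |L^-1 u_i|^2` jointly over
   `(beta, u_1..u_M)` by Gauss–Newton with step halving (up to 12
   halvings; at most 60 iterations; relative objective tolerance 1e-10),
   where `w` are the variance-function SD multipliers and `L` the Cholesky
   factor of `D = Psi/sigma^2`.
2. **LME step.** Linearize `f` at the current `(beta, u)`; the working
   response `y* = y - f + X beta + Z u` follows a linear mixed model.
   Maximize its marginal likelihood over `(D, gamma)` — `beta` by GLS and
   `sigma^2` in closed form are profiled out — with Nelder–Mead over the
   log-Cholesky parameterization of `D` (guaranteeing a symmetric
   positive semi-definite `Psi`) plus `gamma`.

Alternation stops when the relative log-likelihood change is below 1e-8
*and* the maximum parameter change below 1e-6, with a cap of 200 outer
iterations; three consecutive log-likelihood stalls below tolerance are
also accepted as convergence (the parameters are then wobbling below the
likelihood's resolution). The reported log-likelihood is the working
model's marginal likelihood at convergence — the standard approximation
for this estimator class; a dual-route test checks every fitted component
(fixed effects, sigma, gamma, log-likelihood) against the field's
reference NLME implementation on the small fixture, at 0.2-0.5% relative
tolerance.

Numerical guards: log-Cholesky diagonals are clipped to [-13, 8] (so `Psi`
can collapse to an effective zero without singular algebra), `gamma` to
[-5, 5]; a near-singular `Psi` at convergence is reported with a warning
rather than an error. Degenerate zero-residual fixed-effect fits evaluate
the Gaussian likelihood at a variance floor of 1e-12.

Starting values are deterministic and data-driven: power-family
coefficients from OLS on the log-linearized model (LCD clipped to >= 0.05 m,
the smallest crown on record, to avoid log 0), logistic/Richards scale from
1.05 x max(DBH) with rate coefficients scaled by the covariate means so the
exponential terms start unsaturated; mixed fits start from the
corresponding fixed-effects fit, `u = 0`, `Psi` diagonal at (10% of each
targeted coefficient)^2 and `gamma = 0.5`. Fixed-effect fits use
trust-region least squares with analytic Jacobians and up to 5 seeded,
jittered restarts.

Model complexity: `k` counts mean coefficients + 1 residual scale +
q(q+1)/2 covariance components + 1 per variance-function parameter;
`AIC = 2k - 2 lnL`, `BIC = k ln(n) - 2 lnL` with `n` = number of trees.
This convention exactly reproduces the AIC/BIC arithmetic of the published
model tables the acceptance script recomputes. Random-effect subsets are
ranked by AIC, ties broken by BIC then by smaller `q`.

## Calibration (EBLUP)

Random effects of a genotype are predicted from a calibration subsample by
iterating the empirical BLUP update from `u* = 0` (max-norm tolerance
1e-6, cap 50; a fixed-pass mode — e.g. exactly three passes — is
available). `R_i` is the fitted variance function evaluated at the
calibration trees' own covariates; the linear solve uses a symmetric
(Cholesky) factorization, never an explicit inverse. `Psi = 0` or an empty
calibration set yields `u = 0` (the population prediction), and genotypes
unseen in training are predicted at `u = 0` with a logged notice — this is
precisely the intended use-case. Property tests verify the iterate
coincides with the joint penalized least-squares optimum found by a
generic optimizer on small instances.

## Sampling strategies and validation

Calibration subsamples per genotype: `smallest` / `largest` k trees by DBH
(stable sort, ties by record order), `medium` (uniform among trees
strictly between the group's 20th and 80th DBH percentiles, linear
interpolation percentiles; all eligible returned with a warning if fewer
than k), and `random`. k is clipped to the group size. Evaluation
excludes the calibration trees by default (no self-scoring); an
"all trees" scope is provided because either convention is defensible.
Stochastic schemes are averaged over 10 seeded repeats by default.

Leave-one-genotype-out cross-validation refits the model per fold
(warm-started from a single global fit, which only affects the optimizer
path), calibrates the held-out genotype on k random trees (fold seed =
base seed + fold index), and pools residuals across folds. A fast mode
keeps the global variance components and refits only the fixed effects per
fold, for large simulation studies.

## Synthetic stands

The generator emulates the structure the analysis assumes, with defaults
matching the study conditions: 78 genotypes x 37 trees (2,886 trees,
within 0.5% of the original 2,899), LH from a truncated normal on
[1.3, 10.6] m whose *truncated* moments are solved to hit mean 3.97 m and
SD 1.78 m, LCD = 0.7 + 0.3 LH + N(0, 0.45²) clipped to [0.05, 6.0] m
(calibration constants, giving a realistic height–crown correlation but
understating the field LCD spread — see limitations), one high-density
block of round(n/3) trees within each genotype (each genotype is planted
in every plot; per-tree Bernoulli assignment is available), random effects
on (b1, b2) from the published Psi, and residuals from the published power
variance function (sigma = 0.3482, gamma = 0.8415). Field H and CD are
emitted through noisy linear links tuned to R² ≈ 0.92 (H~LH) and ≈ 0.76
(CD~LCD). Trees drawing DBH <= 0.1 cm have the residual redrawn
(rejection, max 100 attempts) rather than clipped, so no point mass
distorts the variance-function estimate.

What passing tests on these stands do **not** show about real data: the
generator has no spatial structure, no competition, no measurement error
in LH/LCD, no repeated measures across years, a narrower LCD marginal than
the field table, and its residuals are exactly Gaussian with the assumed
variance law — so parameter-recovery results certify the estimator, not
the model's adequacy for any particular forest.

Known statistical limits at study scale (measured with both this
implementation and an independent reference estimator): the sampling SD of
the density-shift coefficient `b2` (≈ 0.010) and the crown exponent `c1`
(≈ 0.018) are comparable to 5% of their true magnitudes, because `b2` is
identified mainly through 78 genotype-level draws of `u3`. Recovery is
therefore asserted on the fixed-effect vector (relative L2 error), on the
precisely identified `a1`, `b1`, and on `gamma`; per-coefficient checks on
`b2`/`c1` at the same tightness would flip on the luck of the seed.

## Defaults that matter

| parameter | default | units | why |
|---|---|---|---|
| `min_trees` | 30 | trees | genotypes with fewer sampled trees carry too little information and are excluded |
| `height_floor` | 1.3 | m | breast height; trees below it have no DBH. "Both heights below floor" (AND) is the default reading; OR is a switch |
| variance covariate | LH | — | residual spread grows with tree size; height is the better-measured size proxy |
| `gamma` start | 0.5 | — | mild heteroscedasticity; far from both boundary behaviors |
| EBLUP `tol`, `max_iter` | 1e-6, 50 | — | the update is a contraction in practice; 50 is a generous cap |
| strategy `k` range | 1–10 | trees | the operational question is how few field trees suffice |
| `repeats` | 10 | — | enough to average Monte-Carlo noise in the stochastic schemes |

## Open choices made here

- Height filter runs before the genotype-count filter, so the 30-tree
  threshold applies to surviving trees.
- "Both LH and H below 1.3 m" is implemented as logical AND by default
  (the stricter, literal reading), with OR available.
- In-sample fit statistics of a mixed fit are computed at the predicted
  random effects (subject-specific fitted values).
- The AIC formula uses 2k − 2lnL; the k-counting convention is unit-tested
  against the published tables.
- LOOCV refits per fold by default; the leakage-prone fast mode is opt-in.
- EBLUP iterates to convergence rather than a fixed number of passes.
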