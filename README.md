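# allomix

Genotype-aware nonlinear mixed-effects allometry: predicting individual-tree
**diameter at breast height (DBH, cm)** from LiDAR-derived **tree height
(LH, m)** and **crown diameter (LCD, m)**.

## Who this is for

Forest biometricians and remote-sensing analysts working in genetically
heterogeneous plantations (clonal trials, breeding populations), where
trees of the same size class grow differently because of their genotype.
Conventional LiDAR→DBH regressions assume a homogeneous population;
`allomix` treats genotype as the grouping factor of a nonlinear
mixed-effects (NLME) model, so a handful of field-measured trees per
genotype "localizes" the model to that genotype.

## The model

The mean function is a power allometry with a planting-density dummy
`P₁ ∈ {0, 1}` shifting the height exponent:

```
DBH_ij = a1 · LH_ij^(b1 + u2,i + (b2 + u3,i)·P1_ij) · LCD_ij^c1 + ε_ij
```

for tree *j* of genotype *i*, where

- `(a1, b1, b2, c1)` are fixed effects,
- `uᵢ = (u2,i, u3,i) ~ N(0, Ψ)` are genotype random effects with
  unstructured covariance Ψ,
- `ε_ij ~ N(0, σ² · LH_ij^(2γ))` — a power variance function capturing the
  residual spread growing with tree size (exponential and constant
  variants are also available).

Estimation is maximum likelihood by alternating penalized nonlinear least
squares in `(β, uᵢ)` with a profiled linear mixed-effects step on the
linearized model for `(Ψ, σ, γ)` (Lindstrom–Bates style), with Ψ kept
positive semi-definite through a log-Cholesky parameterization. Fit quality
is reported with the field's standard bundle — mean error, error variance,
TRE = 100·Σe²/Σy², R², RMSE = √(ē² + σ̂²) — plus AIC = 2k − 2lnL and
BIC = k·ln(n) − 2lnL with `k` counting *all* estimated quantities.

New genotypes are localized by **EBLUP calibration**: given a few measured
trees, the genotype's random effects are predicted by iterating

```
ûᵢ = Ψ Zᵢᵀ (R̂ᵢ + Zᵢ Ψ Zᵢᵀ)⁻¹ [yᵢ − f(β̂, u*) + Zᵢ u*]
```

to a fixed point, where `Zᵢ` is the Jacobian of the mean with respect to the
random effects. Four calibration-sampling schemes (smallest / largest /
medium / random trees per genotype, k = 1…10) and leave-one-genotype-out
cross-validation quantify how many calibration trees are worth measuring.

Because raw survey data of this kind are rarely shareable, the package
ships a synthetic-stand generator (`simulate_stand`) with genotype
structure, realistic covariate marginals and known ground truth, used by
the tests for parameter-recovery checks, plus the published final model as
a ready-to-use preset (`published_catalpa_fit`).

## Worked example

```python
import allomix as am

data = am.make_fixture("small")                      # 10 genotypes x 30 trees
model = am.GenotypeMixedModel(
    data, am.ModelForm("power", "on_b"),
    random_effects=("b1", "b2"), variance="power")
result = model.fit()
print(result.summary())

baseline = am.population_baseline(result, data)
curves = am.evaluate_strategies(result, data, kinds=("random",),
                                k_range=[1, 2, 5], seed=0)
print(f"population-level RMSE: {baseline.rmse:.4f}")
print(curves[["kind", "k", "rmse", "r2", "tre"]].to_string(index=False))
```

prints

```
Genotype mixed-effects model: power-dummy-on_b
  random effects on: b1, b2 (q=2)
  variance function: power in lh
  n = 300, genotypes = 10, converged = True, outer iterations = 5
  Fixed effects:
      a1 =  0.8793
      b1 =  1.1848
      b2 = -0.1504
      c1 =  0.2763
  Psi (random-effect covariance):
    [ 8.0901e-03  -8.1692e-03]
    [-8.1692e-03   1.4469e-02]
  sigma = 0.3263  gamma = 0.8920
  RMSE = 1.1394  R2 = 0.9000  TRE = 3.1906
  logLik = -447.7007  k = 9  AIC = 913.4013  BIC = 946.7354

population-level RMSE: 1.5060
  kind  k     rmse       r2      tre
random  1 1.469009 0.831704 5.347305
random  2 1.431296 0.843733 5.001053
random  5 1.340521 0.860575 4.416735
```

The fixture is generated from the published final model, and the fit
recovers its parameters (a1 = 0.8403, b1 = 1.1829, b2 = −0.1427,
c1 = 0.2726, σ = 0.3482, γ = 0.8415) within sampling noise. The negative
`b2` means high-density planting flattens the height–diameter allometry;
the strongly negative Ψ off-diagonal says genotypes with a steeper base
exponent tend to react more to density. Calibrating with just two random
trees per genotype already cuts the population-level prediction RMSE from
1.51 to 1.43 cm, with diminishing returns thereafter.

A `allomix` console command exposes the same pipeline
(`allomix simulate / fit / calibrate / evaluate / loocv`); see
`allomix --help`.

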