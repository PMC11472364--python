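# robustcox

Robust and penalised Cox-model variable selection for censored survival
data, with a simulator for contaminated survival datasets and a
benchmarking framework for selection and estimation performance.

Survival times are long-tailed, and a handful of individuals with
anomalously long observed times can wreck penalised variable selection
in the Cox proportional-hazards model. This package is aimed at
biostatisticians who want to (a) fit classical penalised Cox models
(lasso, elastic net, MCP, SCAD, snet, mnet, adaptive variants), (b) fit
a robust penalised *weighted* proportional-hazards estimator that
jointly learns per-observation weights and flags outlying survival
times, (c) screen ultrahigh-dimensional covariates by sure independence
screening before fitting, and (d) benchmark all of these on simulated
data with known ground truth.

## The model

The Cox model has hazard h(t | x) = h0(t) exp(x'β). All estimators act
on the observation-weighted negative log partial likelihood (Breslow
ties), with weights w_i ∈ (0, 1]:

```
ℓ(β, w) = −(1/n) Σ_i δ_i [ x_i'β + log w_i − log Σ_{j ∈ R_i} w_j exp(x_j'β) ]
```

where R_i = {j : t_j ≥ t_i} is the risk set and δ_i the event
indicator. The penalised Cox family minimises ℓ(β, 1) + P_λ(β) with
P_λ a lasso, elastic-net, MCP, SCAD, snet, mnet or adaptive penalty.
The robust weighted estimator jointly minimises

```
ℓ(β, w) + λ₁ Σ_i |log w_i| / |log w̃_i| + P_{λ₂,γ}(‖β‖)
```

over (β, w), where ‖β_j‖ = |β_j| / |β̃_j| scales each coordinate by an
initial estimate, and the weight penalty anchors w at 1. Observations
whose survival times are inconsistent with the fitted model get small
weights; weights below a threshold flag outliers. Sure independence
screening ranks covariates by the absolute coefficient of
single-covariate Cox fits (with a conditional augmentation round for
variables whose marginal signal cancels through correlated partners)
and keeps the top d = ⌊n / log n⌋ before the penalised fit.

The simulator draws block-correlated standardised normal covariates,
event times from a Cox model with Weibull baseline hazard
H0(t) = (t/scale)^shape (defaults shape 5, scale 0.5), contaminates a
chosen fraction of individuals by adding the median event time to their
true survival time, and applies independent Uniform[0, 10] censoring.

## Worked example

```python
import numpy as np
import robustcox as rc

cfg = rc.ScenarioConfig.preset("design1", seed=1)   # n=300, p=30, 5% outliers
ds = rc.generate_dataset(cfg)                        # true beta = (1, 2, -1, 0, ...)

lasso = rc.fit_and_refit(ds, rc.PenaltySpec("lasso"), K=10, seed=1)
print(sorted(int(j) + 1 for j in lasso.selected))
# [1, 2, 3, 8, 11, 12, 15, 20, 21, 24, 29]
print(np.round(lasso.beta_hat[:3], 3))
# [ 0.415  0.991 -0.355]

(l1, l2), _ = rc.tune_pawph(ds, "mcp", K=5, seed=1)
fit = rc.fit_pawph(ds, rc.PawphConfig(penalty_family="mcp",
                                      lambda1=l1, lambda2=l2))
print(sorted(int(j) + 1 for j in fit.selected))
# [1, 2, 3]
print(np.round(fit.beta_hat[:3], 3))
# [ 0.531  1.115 -0.442]

out = ds.outlier_flags.astype(bool)
print(fit.w_hat[out].mean(), fit.w_hat[~out].mean())
# 0.965 1.0
```

With 5% contaminated survival times the CV-tuned lasso selects eight
spurious variables alongside the three true ones, while the robust
weighted MCP fit selects exactly variables 1–3, estimates their
coefficients with less attenuation, and gives the contaminated
individuals systematically smaller weights (0.965 vs 1.0 on average
here; under heavier contamination the separation is much larger and
weights below 0.5 are flagged as outliers).

The same operations are available from the shell:

```
robustcox simulate --scenario S3 --n 300 --p 30 --outlier-prop 0.05 --seed 1 --out data.csv
robustcox fit --method pawph_mcp --data data.csv --seed 1 --out fit.json
robustcox benchmark --config bench.json --out results/
```

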