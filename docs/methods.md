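# Methods

## Weighted partial likelihood

All estimators are built on the observation-weighted negative log
partial likelihood, normalised by n, with the Breslow convention for
tied event times (all events sharing a time use the same risk-set
denominator). Weights enter both the event term (`+ log w_i`) and the
risk sums (`w_j exp(x_j'β)`), which makes the likelihood invariant to a
global positive rescaling of w; this invariance is broken deliberately
by the weight penalty of the robust estimator (below). Risk sums are
computed by reverse cumulative accumulation over time-sorted
observations after a log-sum-exp shift, O(n log n); the test suite
keeps an O(n²) double-loop evaluation as the oracle. Censored
individuals contribute only through risk sets. Ties are measure-zero
in the simulator's continuous times but can arise from rounded CSV
input, hence the Breslow grouping. Efron ties, stratification and left
truncation are out of scope.

## Penalties

Families: lasso, ridge (λ/2·β²), elastic net λ[α‖β‖₁ + (1−α)/2‖β‖₂²]
with default α = 0.5, MCP (concavity γ > 1, default 3), SCAD (γ > 2,
default 3.7, the standard recommendation), and snet/mnet, which replace
the ℓ1 part of the elastic net (a lasso at αλ) with SCAD/MCP at αλ —
that reading of the SCAD/MCP-plus-ridge hybrids is a convention of this
package. Adaptive variants divide each coordinate's magnitude by a
pilot scale s_j = max(|β̃_j|, 10⁻⁴); the floor keeps coordinates with a
null pilot estimate finitely penalised. The per-coordinate penalty
level of the MCP/SCAD displays is the global λ (adaptivity enters only
through the magnitude scaling).

Every family is piecewise quadratic in |β|, so the scalar proximal
operator is solved exactly by enumerating per-piece stationary points
clipped to their pieces — valid for any step size, including steps for
which the textbook firm/SCAD threshold formulas are no longer the
minimiser. A numba-compiled copy of the same operator drives the
coordinate-descent inner loop; the tests assert both agree to 1e-12 and
match 1-D numeric minimisation to 1e-6.

## Penalised Cox solver

Path fitting uses the usual quadratic approximation: at the current
linear predictor, the likelihood is replaced by a weighted
least-squares surrogate with the per-observation gradient and positive
diagonal curvature, coordinates are updated cyclically with the exact
prox (full sweeps alternating with active-set sweeps), and the
surrogate is re-formed until the coefficients settle. Each outer step
is safeguarded by backtracking on the true penalised objective, so the
objective never increases; when no fraction of the step improves the
objective, the current iterate is kept. Tolerance is 1e-7 on the
maximum coefficient change, with at most 1000 inner sweeps per λ.
Covariates are standardised internally (coefficients reported on the
original scale); the adaptive scales carry over by the per-column
standard deviation so the scaled magnitudes are unchanged. The λ grid
is 50 log-spaced values from the null-model λ_max (scaled by the ℓ1
fraction for the composite families) down to 0.01·λ_max, fitted with
warm starts. Nonconvex families accept the local solution reached from
the warm start; no global guarantee is claimed.

Tuning is K-fold (default 10) cross-validation with the
Verweij–van Houwelingen cross-validated partial likelihood — the
full-data log partial likelihood at the leave-fold-out coefficients
minus the training-data value — which stays stable when folds contain
few events. λ* maximises the mean score, with ties resolved toward the
larger (more parsimonious) λ, and the refit is the full-data path
evaluated at λ*. Folds are re-randomised (bounded retries) if a
training set has no events. Pilot estimator for the adaptive families:
a ridge Cox fit at λ_ridge = 0.01, solved by Newton's method with the
exact Hessian for p ≤ 200 and by coordinate descent above that.

## Robust weighted estimation

The robust estimator minimises ℓ(β, w) + λ₁ Σ|log w_i|/|log w̃_i| +
P_{λ₂,γ}(‖β‖) jointly over β and w. Design choices where the objective
alone does not fix an algorithm:

- w is constrained to (0, 1] with w_min = 10⁻³. The weight penalty is
  symmetric in log w, but downweighting is the method's purpose, and
  the upper bound at 1 pins the scale that the likelihood leaves
  unidentified. |log w̃_i| is clamped below at 10⁻⁶ so that w̃_i = 1
  does not divide by zero.
- Initial estimates: β̃ is the ridge Cox pilot; w̃_i =
  exp(−|r_i|/mad(r)) clipped to [w_min, 1], with r the pilot's
  martingale residuals and mad the scaled median absolute deviation —
  observations with large residuals start mildly downweighted. If the
  pilot fails, β̃ = 0 and w̃ just below 1, with a warning.
- Optimisation is alternating block minimisation. The β block runs the
  penalised coordinate-descent solver at fixed w (without internal
  standardisation, so the traced objective is the joint objective up to
  the constant weight-penalty term). The w block makes one cyclic pass
  of exact 1-D minimisations of the joint objective over each
  log w_i ∈ [log w_min, 0]; the slice is convex there (the only kink is
  at the w = 1 boundary), so bounded golden-section search against both
  endpoints is exact to ~1e-6, and an update is accepted only if it
  lowers the objective. Both blocks are descent steps, so the outer
  objective trace is non-increasing — asserted in the tests, along
  with agreement of the w block with an exhaustive coordinate-wise grid
  oracle and of the β block with an independent optimiser.
- Outer loop: at most 25 alternations, stopping when the relative
  objective change falls below 1e-6. λ₁ = ∞ pins w ≡ 1 and reduces the
  fit exactly to the penalised Cox fit (asserted).
- Outliers are flagged where ŵ_i < 0.5 by default (configurable; the
  choice of 0.5 is a reporting convention, the weights themselves are
  the primary output).
- Tuning: 2-D grid search over (λ₁, λ₂), scored by the cross-validated
  partial likelihood evaluated at w = 1 on the held-out construction —
  weights are treated as training-set nuisance parameters. Default
  grids are data-driven and log-spaced: λ₂ spans [0.05, 1]×λ_max of the
  adaptively scaled penalty; λ₁ spans [0.01, 1]× the smallest value
  that pins every weight at 1 (computed from the pilot's martingale
  residuals against the penalty slope at w = 1), 10×10 by default.

## Screening

Marginal utilities are |β̂_j| from single-covariate Cox fits on
standardised columns, solved for all p columns simultaneously by a
damped vectorised Newton iteration with exact per-column gradients and
Hessians (steps clipped at 2, |β| at 50; non-converged columns get
utility 0 with a warning). The screen keeps the top d = ⌊n/log n⌋
utilities, ties broken toward the lower index.

Purely marginal ranking fails structurally when a variable's marginal
association cancels through correlated partners: in the
block-correlation scenarios, a variable inside the 0.7 block whose two
partners carry opposing coefficients has a population marginal
association smaller than the 0.1 background association shared by
every noise variable, so no marginal statistic can rank it into the
kept set. The default screen therefore adds one conditional
augmentation round — keep the top ⌈d/2⌉ marginal variables, fit a
ridge Cox model on them, and fill the remaining slots by the largest
conditional utilities computed with that fit as an offset — a light
form of iterated screening matching the behaviour of the screening
implementations used in practice. `iterate=False` restores the vanilla
marginal screen. The downstream fit is the cross-validated penalised
Cox fit (default lasso) on the kept columns, mapped back to the full
coordinate vector.

## Simulator

The generator composes covariates → event times → contamination →
censoring, each stage on its own sub-stream of one master seed, so
datasets are bit-reproducible and stages are individually replayable.

- Covariates: i.i.d. rows from N(0, R). The scenario correlation R has
  unit diagonal, 0.9 within the first triplet, 0.7 within the second,
  zero between the first triplet and variable 4, and 0.1 everywhere
  else; positive definiteness is verified by Cholesky factorisation.
  The sparse three-variable design uses an identity correlation (its
  source design's matrix is not specified here; the identity fallback
  is this package's documented assumption).
- Coefficients: six preset scenario vectors (nonzero entries at
  positions 1–6 and p) and the sparse design (1, 2, −1, 0, …, 0).
- Event times: inverse-transform draws under S(t|x) =
  exp(−(t/scale)^shape · e^{x'β}), computed in log space so large
  linear predictors cannot overflow. The Weibull convention here is
  shape = 5, scale = 0.5 with H0(t) = (t/scale)^shape; both parameters
  are exposed so the transposed reading is one configuration edit away.
- Contamination acts on true event times before censoring: exactly
  ⌈proportion·n⌉ individuals, drawn uniformly from all n, get the
  median of the uncontaminated event times added to their time (the
  ceiling is taken after rounding the product to 12 decimals to guard
  binary-float artifacts such as 0.2·300 = 60.000000000000007).
  Contaminated individuals may subsequently be censored.
- Censoring: independent Uniform[0, 10] by default; observed time is
  the minimum, status indicates the event. With the default Weibull
  baseline the event rate is high (~90% events in the scenario
  configurations), matching the simulated designs.

What the generator does *not* emulate: real covariate distributions
(heavy tails, discreteness, missingness), informative censoring,
non-linear or time-varying effects, and cellwise (covariate)
contamination — outliers live purely in the survival times. Passing
tests therefore demonstrate correct behaviour under rowwise
response-outlier contamination with elliptical covariates, not
robustness to arbitrary real-data pathologies.

## Benchmarking

Selection metrics per repeat: TP, FP, FN, F1 = 2TP/(2TP+FP+FN) (zero
when undefined), model size = TP + FP, and exact match (selected set
equals the true active set); "selected" means β̂_j ≠ 0 exactly after
the refit — no magnitude threshold. Estimation metrics per coefficient
across m repeats: mean estimate, mean absolute error, mean squared
error; the long-format summary emits both the bias (EST − β) and the
per-repeat errors so either aggregation of a "difference" heatmap can
be reproduced. The runner derives one 31-bit seed per (cell, repeat)
from the master seed, records failed repeats explicitly (excluded from
aggregates with a count), caches completed cells to CSV for
resumability, and is bit-deterministic for a fixed configuration.

## Problem sizes used by the test suite

The heavy behavioural checks run at reduced scale as this package's
standard study conditions: the robustness study uses 50 repeats of
Scenario 3 (n = 300, p = 30, 10% outliers) with the lasso tuned by
5-fold CV over 25 λ values and the robust fits tuned over a 2×3
(λ₁, λ₂) sub-grid with 3-fold CV; the screening study uses 25 repeats
of Scenario 3 at p = 1000 (screening step only); selection-consistency
and null-selection checks use 12–15 repeats. Thresholds (≥90% of
repeats, majority of repeats) are the behavioural claims themselves and
are not scaled.

## Known limitations

- Nonconvex penalties yield local minima; results depend on the warm
  start (documented, not worked around).
- The alternating robust fit has no global-optimality guarantee; the
  original algorithm for the weight block is not specified by the
  method's source, and this package's block scheme is a documented
  substitute validated against numeric oracles, not a reconstruction.
- The elastic-net mixing α of comparison implementations is unknown;
  results that depend on it should be read qualitatively.
- Prediction-ability evaluation, the six externally specified
  high-dimensional screening cases, and random survival forests are
  out of scope.
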