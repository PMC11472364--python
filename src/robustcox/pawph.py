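"""Robust penalised weighted proportional-hazards estimation.

Jointly estimates coefficients beta and per-observation weights
w_i in (0, 1] by minimising

    -(1/n) sum_i d_i [ x_i'b + log w_i - log sum_{j in R_i} w_j e^{x_j'b} ]
    + lambda1 * sum_i |log w_i| / |log wtilde_i|
    + P_{lambda2(,gamma)}(beta),

where the coefficient penalty P is an adaptively scaled lasso, MCP or
SCAD with coordinate magnitudes |b_j| / |btilde_j|, and wtilde, btilde
are initial estimates. The weight penalty anchors w at 1 (log w = 0),
which breaks the partial likelihood's invariance to a global weight
rescaling and makes the weights identified; observations whose survival
times are inconsistent with the fitted model receive small weights and
are flagged as outliers.

Optimisation is alternating block minimisation: the beta block is the
penalised coordinate-descent solver at fixed weights, and the weight
block cyclically minimises the exact objective over each log w_i in
[log w_min, 0] by golden-section search (the slice is convex there, with
the only kink at the w = 1 boundary). Both blocks only accept descent
steps, so the outer objective trace is non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .coxcore import (
    build_risk_structure,
    fit_ridge_newton,
    martingale_residuals,
    neg_log_partial_likelihood,
)
from .penalties import PenaltySpec, adaptive_scales_from, penalty_value
from .pencox import make_folds, solve_penalized, default_lambda_grid

__all__ = [
    "PawphConfig",
    "PawphFit",
    "pawph_objective",
    "initialize",
    "update_beta",
    "update_weights",
    "fit_pawph",
    "tune_pawph",
    "default_tuning_grids",
]

_LOGW_CLAMP = 1e-6  # lower clamp on |log wtilde| to avoid division by zero


@dataclass
class PawphConfig:
    """Configuration of the robust weighted fit.

    lambda1 penalises |log w| (observation weights; +inf pins w = 1),
    lambda2 and gamma parameterise the coefficient penalty. w_tilde and
    beta_tilde are the initial estimates; left as None they are computed
    by :func:`initialize`. w_min is the lower clamp of the weights and
    w_flag_threshold the cut below which an observation is flagged as an
    outlier.
    """

    penalty_family: str = "lasso"
    lambda1: float = 0.1
    lambda2: float = 0.1
    gamma: Optional[float] = None
    w_tilde: Optional[np.ndarray] = None
    beta_tilde: Optional[np.ndarray] = None
    w_min: float = 1e-3
    w_flag_threshold: float = 0.5
    max_outer_iter: int = 25
    tol: float = 1e-6
    scale_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.penalty_family not in ("lasso", "mcp", "scad"):
            raise ValueError("penalty_family must be lasso, mcp or scad")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be non-negative")
        if not 0 < self.w_min < 1:
            raise ValueError("w_min must be in (0, 1)")

    def penalty_spec(self) -> PenaltySpec:
        if self.beta_tilde is None:
            raise ValueError("beta_tilde not set; call initialize first")
        return PenaltySpec(
            family=self.penalty_family,
            lam=self.lambda2,
            gamma=self.gamma,
            adaptive_scales=adaptive_scales_from(self.beta_tilde, self.scale_floor),
        )

    def log_w_tilde_abs(self, n: int) -> np.ndarray:
        if self.w_tilde is None:
            raise ValueError("w_tilde not set; call initialize first")
        return np.maximum(np.abs(np.log(self.w_tilde)), _LOGW_CLAMP)


@dataclass
class PawphFit:
    beta_hat: np.ndarray
    w_hat: np.ndarray
    selected: np.ndarray
    outlier_flags: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    config: PawphConfig


def _check_w(w, n):
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0) or np.any(w > 1):
        raise ValueError("weights must lie in (0, 1]")
    return w


def pawph_objective(beta, w, config: PawphConfig, dataset) -> float:
    """The joint objective at (beta, w); weight penalty vanishes at w=1."""
    w = _check_w(w, dataset.n)
    nll = neg_log_partial_likelihood(beta, w, dataset)
    c = config.log_w_tilde_abs(dataset.n)
    wpen = config.lambda1 * float(np.sum(np.abs(np.log(w)) / c))
    if not np.isfinite(wpen):  # lambda1 = inf with w = 1 exactly
        wpen = 0.0 if np.all(w == 1.0) else np.inf
    return nll + wpen + penalty_value(config.penalty_spec(), beta)


def initialize(dataset, family: str = "lasso", *, w_min: float = 1e-3,
               ridge_lam: float = 0.01):
    """Initial estimates (beta_tilde, w_tilde).

    beta_tilde is a ridge-penalised Cox pilot fit with unit weights;
    w_tilde_i = exp(-|r_i| / mad(r)) clipped to [w_min, 1], where r are
    the pilot fit's martingale residuals — observations with large
    residuals start mildly downweighted.
    """
    n, p = dataset.n, dataset.p
    try:
        if p <= 200:
            beta_tilde = fit_ridge_newton(dataset, lam=ridge_lam)
        else:  # dense Hessian too large; coordinate descent instead
            beta_tilde, _, _ = solve_penalized(
                dataset.X, dataset.time, dataset.status,
                PenaltySpec(family="ridge", lam=ridge_lam), tol=1e-6,
            )
        if not np.all(np.isfinite(beta_tilde)):
            raise FloatingPointError("non-finite pilot")
    except Exception:  # pragma: no cover - defensive fallback
        warnings.warn("pilot ridge fit failed; using null initialisation")
        beta_tilde = np.zeros(p)
    r = martingale_residuals(beta_tilde, np.ones(n), dataset)
    mad = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    scale = mad if mad > 1e-8 else max(float(np.std(r)), 1e-8)
    w_tilde = np.clip(np.exp(-np.abs(r) / scale), w_min, 1.0)
    return beta_tilde, w_tilde


def update_beta(beta, w, config: PawphConfig, dataset, risk=None, tol=None):
    """Beta-block minimisation at fixed weights: penalised coordinate
    descent on the weighted partial likelihood (descent step)."""
    spec = config.penalty_spec()
    beta_new, _, _ = solve_penalized(
        dataset.X, dataset.time, dataset.status, spec,
        w=np.asarray(w, float), beta0=beta, risk=risk,
        tol=config.tol if tol is None else tol,
    )
    return beta_new


def update_weights(beta, w, config: PawphConfig, dataset, risk=None):
    """Weight-block minimisation at fixed beta.

    One cyclic pass over observations; each log w_i is minimised over
    [log w_min, 0] on its exact objective slice (convex there) by
    golden-section search against both endpoints, and an update is kept
    only if it lowers the objective.
    """
    from ._kernels import weight_sweep

    n = dataset.n
    w = _check_w(w, n).copy()
    if np.isinf(config.lambda1):
        return np.ones(n)
    if risk is None:
        risk = build_risk_structure(dataset.time, dataset.status)
    c = config.log_w_tilde_abs(n)
    phi = dataset.X @ np.asarray(beta, float)
    m = float(np.max(phi))  # w <= 1 so psi <= max(phi)
    v = np.log(w)
    r = np.exp(phi - m + v)  # scaled relative hazards
    order = risk.order
    # scaled risk sums per tie group, restricted to groups with events
    r_s = r[order]
    rev = np.cumsum(r_s[::-1])[::-1]
    ev_groups = np.flatnonzero(risk.group_events > 0)
    ev_start = risk.group_start[ev_groups]
    ev_d = risk.group_events[ev_groups].astype(float)
    s_ev = rev[ev_start].copy()
    pos_of = np.empty(n, dtype=int)
    pos_of[order] = np.arange(n)
    # events whose risk set contains i: tie-group start <= position of i
    kcount = np.searchsorted(ev_start, pos_of, side="right").astype(np.int64)
    weight_sweep(
        v, r, phi - m, np.asarray(dataset.status, float), c, s_ev, ev_d,
        kcount, float(config.lambda1), float(np.log(config.w_min)), float(n),
    )
    return np.exp(v)


def fit_pawph(dataset, config: PawphConfig) -> PawphFit:
    """Alternate beta- and weight-block minimisation from the initial
    estimates until the relative objective change falls below tol.
    Outliers are the observations with w_hat below the flag threshold."""
    import copy

    config = copy.copy(config)
    if config.beta_tilde is None or config.w_tilde is None:
        beta_tilde, w_tilde = initialize(
            dataset, config.penalty_family, w_min=config.w_min
        )
        if config.beta_tilde is None:
            config.beta_tilde = beta_tilde
        if config.w_tilde is None:
            config.w_tilde = w_tilde
    risk = build_risk_structure(dataset.time, dataset.status)
    pinned = np.isinf(config.lambda1)
    beta = np.asarray(config.beta_tilde, float).copy()
    w = np.ones(dataset.n) if pinned else np.asarray(config.w_tilde, float).copy()
    trace = [pawph_objective(beta, w, config, dataset)]
    converged = False
    for _ in range(config.max_outer_iter):
        beta = update_beta(beta, w, config, dataset, risk=risk)
        if not pinned:
            w = update_weights(beta, w, config, dataset, risk=risk)
        obj = pawph_objective(beta, w, config, dataset)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= config.tol * max(1.0, abs(prev)):
            converged = True
            break
    return PawphFit(
        beta_hat=beta,
        w_hat=w,
        selected=np.flatnonzero(beta),
        outlier_flags=(w < config.w_flag_threshold).astype(int),
        objective_trace=np.asarray(trace),
        converged=converged,
        config=config,
    )


def default_tuning_grids(dataset, family: str = "lasso", n1: int = 10, n2: int = 10):
    """Data-driven log-spaced tuning grids.

    lambda2 spans [0.05, 1] x the null-model lambda_max of the adaptively
    scaled penalty; lambda1 spans [0.01, 1] x the smallest value that
    pins every weight at 1 (the largest per-observation score against
    the weight penalty's slope at w = 1).
    """
    beta_tilde, w_tilde = initialize(dataset, family)
    scales = adaptive_scales_from(beta_tilde)
    spec = PenaltySpec(family=family, lam=1.0, adaptive_scales=scales)
    lam2_max = default_lambda_grid(
        dataset.X, dataset.time, dataset.status, spec, n_lambda=2
    )[0]
    r = martingale_residuals(beta_tilde, np.ones(dataset.n), dataset)
    c = np.maximum(np.abs(np.log(w_tilde)), _LOGW_CLAMP)
    lam1_max = float(np.max(np.abs(r) * c)) / dataset.n
    lam1_max = max(lam1_max, 1e-8)
    grid1 = np.geomspace(lam1_max, 0.01 * lam1_max, n1)
    grid2 = np.geomspace(lam2_max, 0.05 * lam2_max, n2)
    return grid1, grid2


def tune_pawph(
    dataset,
    family: str = "lasso",
    grid1=None,
    grid2=None,
    K: int = 10,
    seed: int = 0,
    *,
    gamma: Optional[float] = None,
    config_kwargs: Optional[dict] = None,
):
    """2-D grid search over (lambda1, lambda2) scored by the
    cross-validated partial likelihood evaluated at w = 1 on the held-out
    construction (weights are training-set nuisance parameters).
    Returns ((lambda1*, lambda2*), score_matrix)."""
    from .datagen import SurvivalDataset

    if grid1 is None or grid2 is None:
        g1, g2 = default_tuning_grids(dataset, family)
        grid1 = g1 if grid1 is None else grid1
        grid2 = g2 if grid2 is None else grid2
    grid1 = np.atleast_1d(np.asarray(grid1, float))
    grid2 = np.atleast_1d(np.asarray(grid2, float))
    X, time, status = dataset.X, dataset.time, dataset.status
    n = dataset.n
    assign = make_folds(n, status, K, seed)
    kwargs = dict(config_kwargs or {})
    scores = np.zeros((len(grid1), len(grid2)))
    for k in range(K):
        tr = assign != k
        sub = SurvivalDataset(X=X[tr], time=time[tr], status=status[tr])
        bt, wt = initialize(sub, family)
        for a, lam1 in enumerate(grid1):
            for b, lam2 in enumerate(grid2):
                cfg = PawphConfig(
                    penalty_family=family, lambda1=float(lam1),
                    lambda2=float(lam2), gamma=gamma,
                    beta_tilde=bt, w_tilde=wt, **kwargs,
                )
                fit = fit_pawph(sub, cfg)
                beta = fit.beta_hat
                full = -n * neg_log_partial_likelihood(beta, np.ones(n), dataset)
                trn = -int(tr.sum()) * neg_log_partial_likelihood(
                    beta, np.ones(int(tr.sum())), X=X[tr], time=time[tr],
                    status=status[tr],
                )
                scores[a, b] += full - trn
    best = np.unravel_index(int(np.argmax(scores)), scores.shape)
    return (float(grid1[best[0]]), float(grid2[best[1]])), scores / K
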