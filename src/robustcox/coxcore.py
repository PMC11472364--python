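"""Weighted Cox partial-likelihood machinery.

The central quantity is the observation-weighted negative log partial
likelihood

    l(b, w) = -(1/n) sum_i d_i [ x_i'b + log w_i
                                 - log sum_{j in R_i} w_j exp(x_j'b) ],

with risk sets R_i = {j : t_j >= t_i} and the Breslow convention under
ties (all events sharing a time use the same risk-set denominator).
Weights w_i in (0, 1] downweight individual observations; w = 1
recovers the ordinary partial likelihood. The objective is invariant
under a global positive rescaling of w, since the log w_i term and the
risk-sum term cancel.

Risk sums are computed by reverse cumulative (log-sum-exp) accumulation
over time-sorted observations, O(n log n) after sorting; an O(n^2)
brute-force path is kept in the test suite as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RiskStructure",
    "UnpenalizedFit",
    "build_risk_structure",
    "neg_log_partial_likelihood",
    "gradient_beta",
    "fit_unpenalized",
]


class NoEventsError(ValueError):
    """Partial likelihood is undefined without any observed events."""


def _check_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError("weight vector has wrong length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w


@dataclass
class RiskStructure:
    """Time ordering, Breslow tie groups and risk-set bookkeeping.

    ``order`` sorts observations by ascending observed time;
    ``group_start[g]``/``group_size[g]`` delimit tie group g within the
    sorted order, ``group_events[g]`` counts its events, and
    ``group_of[k]`` maps sorted position k to its tie group. ``risk_sets``
    materialises R_i (original indices) for each event, in event-time
    order; ``event_order`` lists event indices sorted by time.
    """

    order: np.ndarray
    group_start: np.ndarray
    group_size: np.ndarray
    group_events: np.ndarray
    group_of: np.ndarray
    status_sorted: np.ndarray
    n: int
    time: np.ndarray
    status: np.ndarray

    @property
    def event_order(self) -> np.ndarray:
        return self.order[self.status_sorted == 1]

    @property
    def risk_sets(self) -> list:
        out = []
        for i in self.event_order:
            out.append(np.flatnonzero(self.time >= self.time[i]))
        return out

    @property
    def tie_groups(self) -> list:
        return [
            self.order[s : s + m]
            for s, m in zip(self.group_start, self.group_size)
        ]


def build_risk_structure(time, status) -> RiskStructure:
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    if np.any(~np.isfinite(time)) or np.any(time < 0):
        raise ValueError("times must be finite and non-negative")
    if status.sum() == 0:
        raise NoEventsError("no events: partial likelihood undefined")
    n = len(time)
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = t_s[1:] > t_s[:-1]
    group_of = np.cumsum(new_group) - 1
    group_start = np.flatnonzero(new_group)
    group_size = np.diff(np.append(group_start, n))
    status_sorted = status[order]
    group_events = np.zeros(len(group_start), dtype=int)
    np.add.at(group_events, group_of, status_sorted)
    return RiskStructure(
        order=order,
        group_start=group_start,
        group_size=group_size,
        group_events=group_events,
        group_of=group_of,
        status_sorted=status_sorted,
        n=n,
        time=time,
        status=status,
    )


def _resolve(dataset, X, time, status):
    if dataset is not None:
        return dataset.X, dataset.time, dataset.status
    return X, time, status


def neg_log_partial_likelihood(
    beta,
    w,
    dataset=None,
    *,
    X=None,
    time=None,
    status=None,
    risk: Optional[RiskStructure] = None,
) -> float:
    """Weighted negative log partial likelihood (Breslow ties), normalised
    by n. Stabilised via log-sum-exp over the time-sorted observations."""
    X, time, status = _resolve(dataset, X, time, status)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    w = _check_weights(np.ones(n) if w is None else w, n)
    if risk is None:
        risk = build_risk_structure(time, status)
    psi = X @ np.asarray(beta, dtype=float) + np.log(w)
    psi_s = psi[risk.order]
    # rev_lse[k] = log sum_{j>=k} exp(psi_s[j])
    rev_lse = np.logaddexp.accumulate(psi_s[::-1])[::-1]
    denom = rev_lse[risk.group_start]  # per tie group (risk set = times >= t)
    ev = risk.status_sorted == 1
    loglik = float(np.sum(psi_s[ev] - denom[risk.group_of[ev]]))
    return -loglik / n


def _event_weight_terms(psi, risk):
    """Per-observation relative-hazard accumulators.

    Returns (r, A, B) in a common scaled unit: r_i = exp(psi_i - m),
    A_i = sum over event groups g with t_g <= t_i of d_g / s_g and
    B_i likewise with 1/s_g^2, where s_g is the scaled risk sum of group
    g. Then r*A is the expected event count for each observation
    (delta - r*A is the martingale residual) and r*A - r^2*B the diagonal
    of the Hessian in the linear predictor, both times n absorbed by the
    caller.
    """
    m = float(np.max(psi))
    psi_s = psi[risk.order]
    r_s = np.exp(psi_s - m)
    # scaled risk sum for each tie group: sum of r over sorted tail
    rev = np.cumsum(r_s[::-1])[::-1]
    s_g = rev[risk.group_start]
    d_g = risk.group_events
    inv = np.where(d_g > 0, 1.0 / s_g, 0.0)
    A_g = np.cumsum(d_g * inv)
    B_g = np.cumsum(d_g * inv * inv)
    A_s = A_g[risk.group_of]
    B_s = B_g[risk.group_of]
    r = np.empty_like(r_s)
    A = np.empty_like(A_s)
    B = np.empty_like(B_s)
    r[risk.order] = r_s
    A[risk.order] = A_s
    B[risk.order] = B_s
    return r, A, B


def gradient_beta(
    beta,
    w,
    dataset=None,
    *,
    X=None,
    time=None,
    status=None,
    risk: Optional[RiskStructure] = None,
) -> np.ndarray:
    """Exact gradient of the weighted negative log partial likelihood."""
    X, time, status = _resolve(dataset, X, time, status)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    w = _check_weights(np.ones(n) if w is None else w, n)
    if risk is None:
        risk = build_risk_structure(time, status)
    psi = X @ np.asarray(beta, dtype=float) + np.log(w)
    r, A, _ = _event_weight_terms(psi, risk)
    score = np.asarray(status, float) - r * A  # martingale residuals
    return -(X.T @ score) / n


def linear_predictor_derivatives(psi, risk, n):
    """Gradient and positive diagonal curvature of the normalised negative
    log partial likelihood with respect to the linear predictor psi
    (already including log-weights). Used by the penalised solvers."""
    r, A, B = _event_weight_terms(psi, risk)
    g = -(risk.status - r * A) / n
    d = (r * A - r * r * B) / n
    return g, np.maximum(d, 0.0)


def martingale_residuals(beta, w, dataset, risk: Optional[RiskStructure] = None):
    """delta_i - What_i: observed minus expected events under the fit."""
    if risk is None:
        risk = build_risk_structure(dataset.time, dataset.status)
    n = dataset.n
    w = _check_weights(np.ones(n) if w is None else w, n)
    psi = dataset.X @ np.asarray(beta, float) + np.log(w)
    r, A, _ = _event_weight_terms(psi, risk)
    return np.asarray(dataset.status, float) - r * A


@dataclass
class UnpenalizedFit:
    beta: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float
    message: str = ""


def fit_unpenalized(
    dataset=None,
    w=None,
    *,
    X=None,
    time=None,
    status=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> UnpenalizedFit:
    """Newton's method on the weighted partial likelihood (no penalty).

    Intended for small p (pilot fits and oracles); uses the exact Hessian
    and step-halving on the objective. Non-convergence and separation are
    reported through the ``converged`` flag and message, not hidden.
    """
    X, time, status = _resolve(dataset, X, time, status)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("fit_unpenalized requires n > p")
    risk = build_risk_structure(time, status)
    w = _check_weights(np.ones(n) if w is None else w, n)
    logw = np.log(w)
    beta = np.zeros(p)

    def objective(b):
        return neg_log_partial_likelihood(
            b, w, X=X, time=time, status=status, risk=risk
        )

    obj = objective(beta)
    message = ""
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        psi = X @ beta + logw
        r, A, B = _event_weight_terms(psi, risk)
        score = np.asarray(status, float) - r * A
        grad = -(X.T @ score) / n
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol:
            converged = True
            break
        H = _full_hessian(X, psi, risk) / n
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular Hessian (rank-deficient design or separation)"
            )
        # step-halving line search on the objective
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            cobj = objective(cand)
            if cobj <= obj + 1e-12:
                beta, obj = cand, cobj
                break
            scale *= 0.5
        else:
            message = "line search failed; possible separation"
            break
    psi = X @ beta + logw
    r, A, _ = _event_weight_terms(psi, risk)
    grad = -(X.T @ (np.asarray(status, float) - r * A)) / n
    gnorm = float(np.max(np.abs(grad)))
    if not converged and not message:
        message = "maximum iterations reached"
    return UnpenalizedFit(
        beta=beta, converged=converged, n_iter=it, grad_norm=gnorm, message=message
    )


def _full_hessian(X, psi, risk) -> np.ndarray:
    """Exact (unnormalised) Hessian of -log PL in beta, accumulated over
    tie groups from the largest time downward (memory O(p^2))."""
    p = X.shape[1]
    order = risk.order
    X_s = X[order]
    psi_s = psi[order]
    m = float(np.max(psi_s))
    r_s = np.exp(psi_s - m)
    H = np.zeros((p, p))
    S = 0.0
    Sx = np.zeros(p)
    Sxx = np.zeros((p, p))
    n_groups = len(risk.group_start)
    for g in range(n_groups - 1, -1, -1):
        start = risk.group_start[g]
        stop = start + risk.group_size[g]
        for pos in range(start, stop):
            r = r_s[pos]
            x = X_s[pos]
            S += r
            Sx += r * x
            Sxx += np.outer(r * x, x)
        d_g = risk.group_events[g]
        if d_g > 0:
            mu = Sx / S
            H += d_g * (Sxx / S - np.outer(mu, mu))
    return H


def fit_ridge_newton(
    dataset=None,
    lam: float = 0.01,
    w=None,
    *,
    X=None,
    time=None,
    status=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Ridge-penalised weighted Cox fit (nll + lam/2 * ||beta||^2) by
    Newton's method with step-halving; used as the pilot estimator for
    adaptive penalties and robust-weight initialisation. Suitable for
    moderate p (dense Hessian solve)."""
    X, time, status = _resolve(dataset, X, time, status)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    risk = build_risk_structure(time, status)
    w = _check_weights(np.ones(n) if w is None else w, n)
    logw = np.log(w)
    beta = np.zeros(p)

    def objective(b):
        return neg_log_partial_likelihood(
            b, w, X=X, time=time, status=status, risk=risk
        ) + 0.5 * lam * float(b @ b)

    obj = objective(beta)
    for _ in range(max_iter):
        psi = X @ beta + logw
        r, A, _ = _event_weight_terms(psi, risk)
        grad = -(X.T @ (np.asarray(status, float) - r * A)) / n + lam * beta
        if float(np.max(np.abs(grad))) < tol:
            break
        H = _full_hessian(X, psi, risk) / n + lam * np.eye(p)
        step = np.linalg.solve(H, grad)
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            cobj = objective(cand)
            if cobj <= obj + 1e-12:
                beta, obj = cand, cobj
                break
            scale *= 0.5
        else:
            break
    return beta
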