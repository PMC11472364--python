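"""Penalty families and their scalar proximal operators.

Families: lasso (l1), ridge, elastic net, MCP, SCAD, snet (SCAD + ridge),
mnet (MCP + ridge), and adaptive variants where each coordinate's
magnitude is measured relative to an initial estimate,
||b_j|| = |b_j| / s_j with s_j = max(|btilde_j|, floor).

MCP (concavity gamma > 1):

    M(u) = lam*u - u^2/(2*gamma)        for u <= gamma*lam
         = gamma*lam^2 / 2              for u >  gamma*lam

SCAD (gamma > 2):

    S(u) = lam*u                                    for u <= lam
         = -(u^2 - 2*gamma*lam*u + lam^2)
            / (2*(gamma-1))                         for lam < u <= gamma*lam
         = lam^2*(gamma^2 - 1) / (2*(gamma-1))      for u >  gamma*lam

Elastic net is lam*[alpha*u + (1-alpha)/2 * u^2]; snet/mnet replace the
l1 part (a lasso at alpha*lam) with SCAD/MCP at alpha*lam and keep the
ridge term.

Every family is piecewise quadratic in u = |b|, so the proximal operator
argmin_b (b-z)^2/(2*step) + f(|b|) is solved exactly by enumerating the
per-piece stationary points (clipped to the piece) and taking the best —
valid for any positive step, including steps where the usual firm/SCAD
threshold formulas no longer apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PenaltySpec",
    "penalty_value",
    "prox",
    "adaptive_scales_from",
    "FAMILIES",
]

FAMILIES = (
    "lasso",
    "ridge",
    "elasticnet",
    "mcp",
    "scad",
    "snet",
    "mnet",
    "adaptive_lasso",
    "adaptive_elasticnet",
)

_DEFAULT_GAMMA = {"mcp": 3.0, "scad": 3.7, "mnet": 3.0, "snet": 3.7}


@dataclass
class PenaltySpec:
    """A penalty family with its tuning parameters.

    lam is the regularisation strength (lambda_2n in the robust weighted
    objective), gamma the concavity of MCP/SCAD (defaults 3 and 3.7),
    alpha_mix the elastic-net l1 fraction, and adaptive_scales the
    per-coordinate scale factors |btilde_j| for adaptive families (also
    honoured by any family, giving e.g. the adaptively scaled MCP/SCAD
    used by the robust weighted estimators).
    """

    family: str
    lam: float = 0.0
    gamma: Optional[float] = None
    alpha_mix: float = 0.5
    adaptive_scales: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.gamma is None:
            self.gamma = _DEFAULT_GAMMA.get(self.family)
        if self.family in ("mcp", "mnet") and not self.gamma > 1:
            raise ValueError("MCP requires gamma > 1")
        if self.family in ("scad", "snet") and not self.gamma > 2:
            raise ValueError("SCAD requires gamma > 2")
        if not 0 < self.alpha_mix <= 1:
            raise ValueError("alpha_mix must be in (0, 1]")
        if self.family.startswith("adaptive") and self.adaptive_scales is None:
            raise ValueError(f"{self.family} requires adaptive_scales")
        if self.adaptive_scales is not None:
            self.adaptive_scales = np.asarray(self.adaptive_scales, dtype=float)
            if np.any(self.adaptive_scales <= 0):
                raise ValueError("adaptive_scales must be positive")

    @property
    def base_family(self) -> str:
        return self.family.replace("adaptive_", "")

    def scale(self, j: int) -> float:
        if self.adaptive_scales is None:
            return 1.0
        return float(self.adaptive_scales[j])

    def with_lam(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(
            family=self.family,
            lam=lam,
            gamma=self.gamma,
            alpha_mix=self.alpha_mix,
            adaptive_scales=self.adaptive_scales,
        )

    @property
    def l1_fraction(self) -> float:
        """Fraction of lam acting through the (possibly nonconvex)
        sparsity-inducing part; used for the null-model lambda_max."""
        if self.base_family in ("elasticnet", "snet", "mnet"):
            return self.alpha_mix
        if self.base_family == "ridge":
            return 0.0
        return 1.0


# --- scalar penalty functions on u = scaled magnitude >= 0 ----------------


def _mcp_scalar(u: float, lam: float, gamma: float) -> float:
    if u <= gamma * lam:
        return lam * u - u * u / (2.0 * gamma)
    return 0.5 * gamma * lam * lam


def _scad_scalar(u: float, lam: float, gamma: float) -> float:
    if u <= lam:
        return lam * u
    if u <= gamma * lam:
        return -(u * u - 2.0 * gamma * lam * u + lam * lam) / (2.0 * (gamma - 1.0))
    return lam * lam * (gamma * gamma - 1.0) / (2.0 * (gamma - 1.0))


def penalty_scalar(spec: PenaltySpec, u: float) -> float:
    """Penalty contribution of one coordinate at scaled magnitude u >= 0."""
    lam, g, a = spec.lam, spec.gamma, spec.alpha_mix
    fam = spec.base_family
    if fam == "lasso":
        return lam * u
    if fam == "ridge":
        return 0.5 * lam * u * u
    if fam == "elasticnet":
        return lam * (a * u + 0.5 * (1.0 - a) * u * u)
    if fam == "mcp":
        return _mcp_scalar(u, lam, g)
    if fam == "scad":
        return _scad_scalar(u, lam, g)
    if fam == "mnet":
        return _mcp_scalar(u, a * lam, g) + 0.5 * lam * (1.0 - a) * u * u
    if fam == "snet":
        return _scad_scalar(u, a * lam, g) + 0.5 * lam * (1.0 - a) * u * u
    raise AssertionError(fam)


def penalty_value(spec: PenaltySpec, beta) -> float:
    """P(beta) = sum_j f(|beta_j| / s_j)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    total = 0.0
    for j, b in enumerate(beta):
        total += penalty_scalar(spec, abs(b) / spec.scale(j))
    return total


def adaptive_scales_from(initial_beta, floor: float = 1e-4) -> np.ndarray:
    """Per-coordinate scales s_j = max(|btilde_j|, floor); the floor keeps
    coordinates with a null pilot estimate finitely penalised."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.maximum(np.abs(np.asarray(initial_beta, dtype=float)), floor)


# --- proximal operators ----------------------------------------------------


def _pieces(spec: PenaltySpec):
    """Quadratic pieces (lo, hi, a, b) of f(u) = a*u^2 + b*u + c on
    [lo, hi] (c omitted; evaluated through penalty_scalar)."""
    lam, g, al = spec.lam, spec.gamma, spec.alpha_mix
    fam = spec.base_family
    inf = math.inf
    if fam == "lasso":
        return [(0.0, inf, 0.0, lam)]
    if fam == "ridge":
        return [(0.0, inf, 0.5 * lam, 0.0)]
    if fam == "elasticnet":
        return [(0.0, inf, 0.5 * lam * (1.0 - al), lam * al)]
    ridge_a = 0.0
    if fam in ("snet", "mnet"):
        ridge_a = 0.5 * lam * (1.0 - al)
        lam = al * lam
    if fam in ("mcp", "mnet"):
        return [
            (0.0, g * lam, ridge_a - 1.0 / (2.0 * g), lam),
            (g * lam, inf, ridge_a, 0.0),
        ]
    # scad / snet
    return [
        (0.0, lam, ridge_a, lam),
        (lam, g * lam, ridge_a - 1.0 / (2.0 * (g - 1.0)), g * lam / (g - 1.0)),
        (g * lam, inf, ridge_a, 0.0),
    ]


def _prox_unscaled(spec: PenaltySpec, z: float, step: float) -> float:
    """argmin_b (b - z)^2/(2*step) + f(|b|), exact, for any step > 0.

    By symmetry solve on b >= 0 with |z|: on each quadratic piece of f the
    objective is quadratic, so its minimiser is the stationary point
    clipped to the piece (or the better endpoint when curvature is not
    positive); the global solution is the best candidate over pieces.
    """
    az = abs(z)
    sign = 1.0 if z >= 0 else -1.0
    best_b, best_h = 0.0, 0.5 * az * az / step + penalty_scalar(spec, 0.0)
    for lo, hi, a, b in _pieces(spec):
        curv = 1.0 / step + 2.0 * a
        cands = []
        if curv > 0:
            cands.append(min(max((az / step - b) / curv, lo), hi if hi != math.inf else max(az, lo)))
        cands.append(lo)
        if hi != math.inf:
            cands.append(hi)
        else:
            cands.append(max(az, lo))
        for u in cands:
            if u < lo - 1e-15 or (hi != math.inf and u > hi + 1e-15):
                continue
            h = 0.5 * (u - az) ** 2 / step + penalty_scalar(spec, u)
            if h < best_h - 1e-15 or (abs(h - best_h) <= 1e-15 and u < best_b):
                best_b, best_h = u, h
    return sign * best_b


def prox(spec: PenaltySpec, z: float, step: float, j: int = 0) -> float:
    """Scalar proximal operator argmin_b (b-z)^2/(2*step) + f(|b|/s_j).

    With an adaptive scale s, substitute b = s*u to reduce to the
    unscaled problem at (z/s, step/s^2).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    s = spec.scale(j)
    if s == 1.0:
        return _prox_unscaled(spec, float(z), float(step))
    return s * _prox_unscaled(spec, float(z) / s, float(step) / (s * s))
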