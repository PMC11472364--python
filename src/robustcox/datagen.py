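"""Censored survival-data simulator.

Generates datasets from a Cox proportional-hazards model with a Weibull
baseline hazard, block-correlated multivariate-normal covariates, uniform
right censoring, and optional contamination of event times ("outliers":
individuals whose true survival time is shifted upward by the median
survival time of the sample).

The pipeline order is: covariates -> event times -> contamination ->
censoring, so a contaminated individual may subsequently be censored.
Each stage draws from its own seeded sub-stream so components are
individually reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationSpec",
    "ScenarioConfig",
    "SurvivalDataset",
    "OUTLIER_GRID",
    "SCENARIO_IDS",
    "build_correlation_matrix",
    "scenario_coefficients",
    "draw_covariates",
    "draw_event_times",
    "contaminate",
    "apply_censoring",
    "generate_dataset",
]

# Outlier proportions used throughout the benchmark designs.
OUTLIER_GRID = (0.0, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2)

# Coefficient table for the six block-correlation scenarios: positions 1..6,
# then zeros, with a final nonzero coefficient at position p.
_SCENARIO_HEAD = {
    "S1": ([10.0, -3.0, 3.0, -10.0, -3.0, 3.0], 5.0),
    "S2": ([10.0, 0.0, 3.0, -10.0, -3.0, 0.0], 5.0),
    "S3": ([2.0, -3.0, 3.0, -2.0, -3.0, 3.0], 2.0),
    "S4": ([0.0, 0.0, 3.0, 0.0, -3.0, 0.0], 5.0),
    "S5": ([10.0, 0.0, 0.0, 10.0, 0.0, 0.0], 5.0),
    "S6": ([2.0, 0.0, 0.0, -2.0, 0.0, 0.0], 2.0),
}

SCENARIO_IDS = tuple(_SCENARIO_HEAD) + ("design1",)


class InvalidSpecError(ValueError):
    """A simulation specification violates its preconditions."""


# ---------------------------------------------------------------------------
# correlation structure


@dataclass
class CorrelationSpec:
    """Covariate correlation structure.

    kind
        ``scenario_block``: the six-scenario structure — two correlated
        triplets (r=0.9 among variables 1-3, r=0.7 among variables 4-6),
        zero correlation between variables 1-3 and variable 4, and a
        constant background correlation of 0.1 everywhere else.
        ``design1``: identity (the low-dimensional robust-benchmark design).
        ``identity``: identity. ``custom``: user-supplied matrix.
    """

    kind: str = "scenario_block"
    p: int = 30
    custom_matrix: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("scenario_block", "design1", "identity", "custom"):
            raise InvalidSpecError(f"unknown correlation kind {self.kind!r}")
        if self.p < 1:
            raise InvalidSpecError("p must be positive")
        if self.kind == "custom" and self.custom_matrix is None:
            raise InvalidSpecError("custom kind requires custom_matrix")


def build_correlation_matrix(spec: CorrelationSpec) -> np.ndarray:
    """Construct the p x p Pearson correlation matrix for *spec*.

    The result is symmetric with unit diagonal; positive definiteness is
    verified by Cholesky factorisation and a failure raises
    ``numpy.linalg.LinAlgError``.
    """
    p = spec.p
    if spec.kind in ("identity", "design1"):
        return np.eye(p)
    if spec.kind == "custom":
        R = np.asarray(spec.custom_matrix, dtype=float)
        if R.shape != (p, p):
            raise InvalidSpecError(f"custom matrix must be {p}x{p}")
        if not np.allclose(R, R.T):
            raise InvalidSpecError("custom matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise InvalidSpecError("custom matrix must have unit diagonal")
        np.linalg.cholesky(R)  # raises LinAlgError if not PD
        return R
    # scenario_block
    if p < 6:
        raise InvalidSpecError("scenario_block requires p >= 6")
    R = np.full((p, p), 0.1)
    R[:3, :3] = 0.9
    R[3:6, 3:6] = 0.7
    R[:3, 3] = 0.0
    R[3, :3] = 0.0
    np.fill_diagonal(R, 1.0)
    np.linalg.cholesky(R)
    return R


def scenario_coefficients(scenario_id: str, p: int) -> np.ndarray:
    """Log-hazard-ratio coefficient vector for a named scenario.

    S1–S6 place their six leading coefficients at positions 1..6 and a final
    nonzero coefficient at position p (zeros in between); ``design1`` is
    (1, 2, -1, 0, ..., 0).
    """
    if scenario_id == "design1":
        if p < 3:
            raise InvalidSpecError("design1 requires p >= 3")
        beta = np.zeros(p)
        beta[:3] = [1.0, 2.0, -1.0]
        return beta
    if scenario_id not in _SCENARIO_HEAD:
        raise InvalidSpecError(f"unknown scenario {scenario_id!r}")
    if p < 7:
        raise InvalidSpecError("scenarios S1-S6 require p >= 7")
    head, last = _SCENARIO_HEAD[scenario_id]
    beta = np.zeros(p)
    beta[:6] = head
    beta[-1] = last
    return beta


# ---------------------------------------------------------------------------
# configuration and dataset containers


@dataclass
class ScenarioConfig:
    """One simulation design: sample size, coefficients, correlation,
    contamination, censoring window and Weibull baseline-hazard parameters."""

    scenario_id: str = "custom"
    n: int = 300
    p: int = 30
    beta: Optional[np.ndarray] = None
    correlation: Optional[CorrelationSpec] = None
    outlier_proportion: float = 0.0
    censor_low: float = 0.0
    censor_high: float = 10.0
    weibull_shape: float = 5.0
    weibull_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1:
            raise InvalidSpecError("n and p must be positive")
        if not 0.0 <= self.outlier_proportion <= 1.0:
            raise InvalidSpecError("outlier_proportion must be in [0, 1]")
        if not self.censor_low < self.censor_high:
            raise InvalidSpecError("censor_low must be below censor_high")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise InvalidSpecError("Weibull parameters must be positive")
        if self.beta is None:
            if self.scenario_id in SCENARIO_IDS:
                self.beta = scenario_coefficients(self.scenario_id, self.p)
            else:
                raise InvalidSpecError("custom scenario requires an explicit beta")
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != self.p:
            raise InvalidSpecError("len(beta) must equal p")
        if self.correlation is None:
            kind = "scenario_block" if self.scenario_id in _SCENARIO_HEAD else (
                "design1" if self.scenario_id == "design1" else "identity"
            )
            self.correlation = CorrelationSpec(kind=kind, p=self.p)
        if self.correlation.p != self.p:
            raise InvalidSpecError("correlation.p must equal p")

    @classmethod
    def preset(cls, scenario_id: str, **overrides) -> "ScenarioConfig":
        """Named preset; ``design1`` defaults to n=300, p=30, 5% outliers."""
        defaults = {"scenario_id": scenario_id}
        if scenario_id == "design1":
            defaults["outlier_proportion"] = 0.05
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = {
            "scenario_id": self.scenario_id,
            "n": self.n,
            "p": self.p,
            "beta": [float(b) for b in self.beta],
            "correlation": {"kind": self.correlation.kind, "p": self.correlation.p},
            "outlier_proportion": self.outlier_proportion,
            "censor_low": self.censor_low,
            "censor_high": self.censor_high,
            "weibull_shape": self.weibull_shape,
            "weibull_scale": self.weibull_scale,
            "seed": self.seed,
        }
        if self.correlation.custom_matrix is not None:
            d["correlation"]["custom_matrix"] = np.asarray(
                self.correlation.custom_matrix
            ).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        corr = d.pop("correlation", None)
        if corr is not None:
            cm = corr.get("custom_matrix")
            d["correlation"] = CorrelationSpec(
                kind=corr["kind"],
                p=corr["p"],
                custom_matrix=None if cm is None else np.asarray(cm, float),
            )
        if d.get("beta") is not None:
            d["beta"] = np.asarray(d["beta"], float)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "ScenarioConfig":
        """Load a config from JSON or YAML (by extension)."""
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class SurvivalDataset:
    """Right-censored survival data: covariates X, observed time
    min(T, C), event status (1=event, 0=censored), plus optional ground
    truth for simulated data (contamination flags and the true beta)."""

    X: np.ndarray
    time: np.ndarray
    status: np.ndarray
    outlier_flags: Optional[np.ndarray] = None
    true_beta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = self.X.shape[0]
        if len(self.time) != n or len(self.status) != n:
            raise ValueError("time/status length must match rows of X")
        if np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("times must be finite and non-negative")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0/1")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if self.outlier_flags is not None:
            self.outlier_flags = np.asarray(self.outlier_flags, dtype=int)
            if len(self.outlier_flags) != n:
                raise ValueError("outlier_flags length must be n")
        if self.true_beta is not None:
            self.true_beta = np.asarray(self.true_beta, dtype=float)
            if len(self.true_beta) != self.X.shape[1]:
                raise ValueError("true_beta length must be p")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset_columns(self, cols) -> "SurvivalDataset":
        cols = np.asarray(cols, dtype=int)
        return SurvivalDataset(
            X=self.X[:, cols],
            time=self.time,
            status=self.status,
            outlier_flags=self.outlier_flags,
            true_beta=None if self.true_beta is None else self.true_beta[cols],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.time, "status": self.status}
        if self.outlier_flags is not None:
            cols["outlier"] = self.outlier_flags
        for j in range(self.p):
            cols[f"x{j + 1}"] = self.X[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalDataset":
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.startswith("x")]
        xcols.sort(key=lambda c: int(c[1:]))
        flags = df["outlier"].to_numpy() if "outlier" in df.columns else None
        return cls(
            X=df[xcols].to_numpy(float),
            time=df["time"].to_numpy(float),
            status=df["status"].to_numpy(int),
            outlier_flags=flags,
        )


# ---------------------------------------------------------------------------
# generation stages


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_covariates(n: int, correlation_matrix: np.ndarray, seed) -> np.ndarray:
    """n i.i.d. draws from N(0, R): standardised covariates with the given
    correlation matrix (raises LinAlgError if R is not positive definite)."""
    R = np.asarray(correlation_matrix, dtype=float)
    L = np.linalg.cholesky(R)
    rng = _as_rng(seed)
    Z = rng.standard_normal((n, R.shape[0]))
    return Z @ L.T


def draw_event_times(
    X: np.ndarray,
    beta: np.ndarray,
    weibull_shape: float,
    weibull_scale: float,
    seed,
) -> np.ndarray:
    """Event times under the Cox model with a Weibull baseline hazard.

    With cumulative baseline hazard H0(t) = (t/scale)^shape, survival is
    S(t|x) = exp(-H0(t) e^{x'b}); inverse-transform sampling gives
    T = scale * exp((log E - x'b)/shape) for E ~ Exp(1), computed in log
    space so that large linear predictors do not overflow.
    """
    if weibull_shape <= 0 or weibull_scale <= 0:
        raise InvalidSpecError("Weibull parameters must be positive")
    eta = np.asarray(X, float) @ np.asarray(beta, float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    rng = _as_rng(seed)
    E = rng.standard_exponential(len(eta))
    log_t = math.log(weibull_scale) + (np.log(E) - eta) / weibull_shape
    return np.exp(log_t)


def contaminate(event_times: np.ndarray, proportion: float, seed):
    """Shift ceil(proportion * n) randomly selected individuals' event times
    upward by the median of the uncontaminated times; returns
    (contaminated_times, outlier_flags)."""
    if not 0.0 <= proportion <= 1.0:
        raise InvalidSpecError("proportion must be in [0, 1]")
    times = np.asarray(event_times, dtype=float).copy()
    n = len(times)
    flags = np.zeros(n, dtype=int)
    # round before ceil: guards binary-float artifacts such as
    # 0.2 * 300 = 60.000000000000007
    k = int(math.ceil(round(proportion * n, 12)))
    if k == 0:
        return times, flags
    rng = _as_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    times[idx] += np.median(event_times)
    flags[idx] = 1
    return times, flags


def apply_censoring(event_times: np.ndarray, censor_low: float, censor_high: float, seed):
    """Independent Uniform(censor_low, censor_high) censoring; returns
    (observed time, status) with status = 1{T <= C}."""
    if not censor_low < censor_high:
        raise InvalidSpecError("censor_low must be below censor_high")
    T = np.asarray(event_times, dtype=float)
    rng = _as_rng(seed)
    C = rng.uniform(censor_low, censor_high, size=len(T))
    status = (T <= C).astype(int)
    return np.minimum(T, C), status


def generate_dataset(config: ScenarioConfig) -> SurvivalDataset:
    """Run the full pipeline (covariates -> event times -> contamination ->
    censoring) from one master seed split into per-stage sub-streams."""
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)]
    R = build_correlation_matrix(config.correlation)
    X = draw_covariates(config.n, R, streams[0])
    T = draw_event_times(
        X, config.beta, config.weibull_shape, config.weibull_scale, streams[1]
    )
    T, flags = contaminate(T, config.outlier_proportion, streams[2])
    time, status = apply_censoring(T, config.censor_low, config.censor_high, streams[3])
    return SurvivalDataset(
        X=X, time=time, status=status, outlier_flags=flags, true_beta=config.beta.copy()
    )
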