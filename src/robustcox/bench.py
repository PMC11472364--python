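"""Selection/estimation metrics and benchmark orchestration.

Selection metrics per repeat: TP, FP, FN, F1, model size (= TP + FP)
and exact_match (the selected set equals the true active set).
Estimation metrics per coefficient across m repeats:

    EST_j = mean_r betahat_jr
    MAE_j = mean_r |betahat_jr - beta_j|
    MSE_j = mean_r (betahat_jr - beta_j)^2

The runner crosses methods x scenarios x outlier proportions x repeats,
derives one seed per (cell, repeat) from the master seed, records
per-repeat metrics and coefficients, and aggregates (mean TP/FP/F1,
mean model size, probability the true model is selected, per-coefficient
EST/MAE/MSE). Failed repeats are recorded and excluded from aggregates
with a count, never silently dropped. Cells can be cached to disk so a
benchmark is resumable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .coxcore import fit_ridge_newton
from .datagen import OUTLIER_GRID, ScenarioConfig, generate_dataset
from .penalties import PenaltySpec, adaptive_scales_from
from .pencox import fit_and_refit, solve_penalized
from .pawph import PawphConfig, fit_pawph, tune_pawph
from .sis import sis_fit

__all__ = [
    "SelectionMetrics",
    "EstimationMetrics",
    "BenchmarkConfig",
    "BenchmarkResult",
    "selection_metrics",
    "estimation_metrics",
    "run_benchmark",
    "summarize",
    "METHOD_ALIASES",
    "fit_method",
]


@dataclass
class SelectionMetrics:
    tp: int
    fp: int
    fn: int
    f1: float
    model_size: int
    exact_match: int


def selection_metrics(selected, true_set, p: int) -> SelectionMetrics:
    """TP/FP/FN/F1, model size and exact-match indicator for one repeat.

    Index sets are 0-based subsets of 0..p-1; F1 = 2TP/(2TP+FP+FN), set
    to 0 when the denominator vanishes.
    """
    sel = set(int(j) for j in selected)
    true = set(int(j) for j in true_set)
    if any(j < 0 or j >= p for j in sel | true):
        raise ValueError("indices out of range")
    tp = len(sel & true)
    fp = len(sel - true)
    fn = len(true - sel)
    denom = 2 * tp + fp + fn
    f1 = 2.0 * tp / denom if denom > 0 else 0.0
    return SelectionMetrics(
        tp=tp, fp=fp, fn=fn, f1=f1, model_size=tp + fp,
        exact_match=int(fp == 0 and fn == 0),
    )


@dataclass
class EstimationMetrics:
    est: np.ndarray
    mae: np.ndarray
    mse: np.ndarray


def estimation_metrics(beta_hats, true_beta) -> EstimationMetrics:
    """Per-coefficient mean estimate, mean absolute error and mean
    squared error across the rows (repeats) of beta_hats."""
    B = np.atleast_2d(np.asarray(beta_hats, float))
    beta = np.asarray(true_beta, float)
    if B.shape[1] != len(beta):
        raise ValueError("beta_hats and true_beta disagree on p")
    dev = B - beta[None, :]
    return EstimationMetrics(
        est=B.mean(axis=0),
        mae=np.abs(dev).mean(axis=0),
        mse=(dev ** 2).mean(axis=0),
    )


# ---------------------------------------------------------------------------
# method registry

METHOD_ALIASES = {
    "#1": "lasso", "#2": "elasticnet", "#3": "mcp", "#4": "scad",
    "#5": "alasso", "#6": "aenet", "#7": "snet", "#8": "mnet",
    "#9": "pawph", "#10": "pawph_mcp", "#11": "pawph_scad", "#12": "sis",
}

_PLAIN_FAMILIES = {
    "lasso": "lasso", "elasticnet": "elasticnet", "mcp": "mcp",
    "scad": "scad", "snet": "snet", "mnet": "mnet",
}
_ADAPTIVE_FAMILIES = {"alasso": "adaptive_lasso", "aenet": "adaptive_elasticnet"}
_PAWPH_FAMILIES = {"pawph": "lasso", "pawph_mcp": "mcp", "pawph_scad": "scad"}


def resolve_method(name: str) -> str:
    name = METHOD_ALIASES.get(name, name)
    if name not in set(_PLAIN_FAMILIES) | set(_ADAPTIVE_FAMILIES) | set(
        _PAWPH_FAMILIES
    ) | {"sis"}:
        raise ValueError(f"unknown method {name!r}")
    return name


def _ridge_pilot_scales(dataset, ridge_lam: float = 0.01):
    if dataset.p <= 200:
        beta = fit_ridge_newton(dataset, lam=ridge_lam)
    else:
        beta, _, _ = solve_penalized(
            dataset.X, dataset.time, dataset.status,
            PenaltySpec(family="ridge", lam=ridge_lam), tol=1e-6,
        )
    return adaptive_scales_from(beta)


def fit_method(name: str, dataset, seed: int = 0, **opts) -> dict:
    """Fit one registry method; returns a dict with ``beta_hat``,
    ``selected`` and method-specific extras (``w_hat``/``outlier_flags``
    for the robust weighted fits)."""
    name = resolve_method(name)
    K = opts.pop("K", 10)
    if name in _PLAIN_FAMILIES:
        spec = PenaltySpec(
            family=_PLAIN_FAMILIES[name],
            gamma=opts.pop("gamma", None),
            alpha_mix=opts.pop("alpha_mix", 0.5),
        )
        fit = fit_and_refit(dataset, spec, K=K, seed=seed, **opts)
        return {"beta_hat": fit.beta_hat, "selected": fit.selected,
                "lambda_star": fit.lambda_star}
    if name in _ADAPTIVE_FAMILIES:
        scales = _ridge_pilot_scales(dataset)
        spec = PenaltySpec(
            family=_ADAPTIVE_FAMILIES[name],
            alpha_mix=opts.pop("alpha_mix", 0.5),
            adaptive_scales=scales,
        )
        fit = fit_and_refit(dataset, spec, K=K, seed=seed, **opts)
        return {"beta_hat": fit.beta_hat, "selected": fit.selected,
                "lambda_star": fit.lambda_star}
    if name in _PAWPH_FAMILIES:
        family = _PAWPH_FAMILIES[name]
        gamma = opts.pop("gamma", None)
        (lam1, lam2), _ = tune_pawph(
            dataset, family=family,
            grid1=opts.pop("grid1", None), grid2=opts.pop("grid2", None),
            K=K, seed=seed, gamma=gamma,
        )
        fit = fit_pawph(dataset, PawphConfig(
            penalty_family=family, lambda1=lam1, lambda2=lam2, gamma=gamma,
        ))
        return {"beta_hat": fit.beta_hat, "selected": fit.selected,
                "w_hat": fit.w_hat, "outlier_flags": fit.outlier_flags,
                "lambda1": lam1, "lambda2": lam2}
    # sis
    spec = None
    downstream = opts.pop("downstream", "lasso")
    if downstream is not None:
        spec = PenaltySpec(family=downstream)
    fit = sis_fit(dataset, d=opts.pop("d", None), penalty_spec=spec,
                  K=K, seed=seed, **opts)
    return {"beta_hat": fit.beta_hat, "selected": fit.selected,
            "lambda_star": fit.lambda_star}


# ---------------------------------------------------------------------------
# benchmark runner


@dataclass
class BenchmarkConfig:
    methods: list
    scenarios: list  # ScenarioConfig instances
    outlier_grid: tuple = OUTLIER_GRID
    repeats: int = 10
    master_seed: int = 0
    method_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")
        self.methods = [resolve_method(m) for m in self.methods]


@dataclass
class BenchmarkResult:
    raw: pd.DataFrame  # one row per (method, scenario, proportion, repeat)
    summary: pd.DataFrame  # aggregates per cell
    config: BenchmarkConfig


def repeat_seed(master_seed: int, cell_index: int, r: int) -> int:
    """Deterministic per-repeat seed derived from the master seed."""
    ss = np.random.SeedSequence((int(master_seed), int(cell_index), int(r)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_benchmark(config: BenchmarkConfig, out_dir=None) -> BenchmarkResult:
    """Run the full grid; per-cell CSV caching under out_dir makes the
    run resumable. Deterministic for a fixed (config, master_seed)."""
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    rows = []
    cell_index = 0
    for scen in config.scenarios:
        for prop in config.outlier_grid:
            for method in config.methods:
                cell_rows = _run_cell(
                    config, scen, float(prop), method, cell_index, out_path
                )
                rows.extend(cell_rows)
                cell_index += 1
    raw = pd.DataFrame(rows)
    summary = _aggregate(raw)
    return BenchmarkResult(raw=raw, summary=summary, config=config)


def _cell_tag(scen, prop, method):
    return f"{method}_{scen.scenario_id}_p{prop:g}"


def _run_cell(config, scen, prop, method, cell_index, out_path):
    cache = None
    if out_path is not None:
        cache = out_path / f"cell_{_cell_tag(scen, prop, method)}.csv"
        if cache.exists():
            return pd.read_csv(cache).to_dict("records")
    rows = []
    opts = dict(config.method_options.get(method, {}))
    for r in range(config.repeats):
        seed = repeat_seed(config.master_seed, cell_index, r)
        cfg = ScenarioConfig.from_dict(
            {**scen.to_dict(), "outlier_proportion": prop, "seed": seed}
        )
        ds = generate_dataset(cfg)
        true_set = np.flatnonzero(ds.true_beta)
        row = {
            "method": method, "scenario": scen.scenario_id,
            "outlier_proportion": prop, "repeat": r, "seed": seed,
            "failed": 0,
        }
        try:
            fit = fit_method(method, ds, seed=seed, **opts)
            m = selection_metrics(fit["selected"], true_set, ds.p)
            row.update(tp=m.tp, fp=m.fp, fn=m.fn, f1=m.f1,
                       model_size=m.model_size, exact_match=m.exact_match)
            for j, b in enumerate(fit["beta_hat"]):
                row[f"b{j + 1}"] = float(b)
        except Exception as exc:  # failed repeat: recorded, not dropped
            row["failed"] = 1
            row["error"] = str(exc)
        rows.append(row)
    if cache is not None:
        pd.DataFrame(rows).to_csv(cache, index=False)
    return rows


def _aggregate(raw: pd.DataFrame) -> pd.DataFrame:
    keys = ["method", "scenario", "outlier_proportion"]
    out = []
    for key, grp in raw.groupby(keys, sort=True):
        ok = grp[grp["failed"] == 0]
        rec = dict(zip(keys, key))
        rec["n_repeats"] = len(grp)
        rec["n_failed"] = int(grp["failed"].sum())
        if len(ok):
            rec.update(
                mean_tp=ok["tp"].mean(), mean_fp=ok["fp"].mean(),
                mean_f1=ok["f1"].mean(), mean_model_size=ok["model_size"].mean(),
                prob_true_model=ok["exact_match"].mean(),
            )
        out.append(rec)
    return pd.DataFrame(out)


def coefficient_metrics(raw: pd.DataFrame, true_beta) -> pd.DataFrame:
    """Long-format per-variable EST/MAE/MSE (and bias EST - beta) per
    cell, recomputed from the per-repeat coefficient records."""
    p = len(true_beta)
    bcols = [f"b{j + 1}" for j in range(p)]
    keys = ["method", "scenario", "outlier_proportion"]
    rows = []
    for key, grp in raw.groupby(keys, sort=True):
        ok = grp[grp["failed"] == 0]
        if not len(ok):
            continue
        em = estimation_metrics(ok[bcols].to_numpy(float), true_beta)
        for j in range(p):
            rows.append({
                **dict(zip(keys, key)), "variable": j + 1,
                "true_beta": float(true_beta[j]),
                "est": em.est[j], "bias": em.est[j] - float(true_beta[j]),
                "mae": em.mae[j], "mse": em.mse[j],
            })
    return pd.DataFrame(rows)


def summarize(result: BenchmarkResult, out_dir) -> dict:
    """Write raw.csv (per repeat), summary.csv (per-cell aggregates),
    coefficients.csv (long-format per-variable metrics, heatmap-ready)
    and manifest.json (config echo)."""
    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    files = {}
    raw_f = out_path / "raw.csv"
    result.raw.to_csv(raw_f, index=False)
    files["raw"] = str(raw_f)
    sum_f = out_path / "summary.csv"
    result.summary.to_csv(sum_f, index=False)
    files["summary"] = str(sum_f)
    frames = []
    for scen in result.config.scenarios:
        sub = result.raw[result.raw["scenario"] == scen.scenario_id]
        if len(sub):
            frames.append(coefficient_metrics(sub, scen.beta))
    if frames:
        coef_f = out_path / "coefficients.csv"
        pd.concat(frames, ignore_index=True).to_csv(coef_f, index=False)
        files["coefficients"] = str(coef_f)
    manifest = {
        "methods": list(result.config.methods),
        "scenarios": [s.to_dict() for s in result.config.scenarios],
        "outlier_grid": list(result.config.outlier_grid),
        "repeats": result.config.repeats,
        "master_seed": result.config.master_seed,
    }
    man_f = out_path / "manifest.json"
    man_f.write_text(json.dumps(manifest, indent=2))
    files["manifest"] = str(man_f)
    return files
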