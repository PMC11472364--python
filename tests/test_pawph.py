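"""Robust weighted estimation: objective, block updates, alternation."""

import numpy as np
import pytest

from robustcox import (
    PawphConfig,
    PenaltySpec,
    ScenarioConfig,
    fit_pawph,
    generate_dataset,
    initialize,
    neg_log_partial_likelihood,
    pawph_objective,
    tune_pawph,
    update_beta,
    update_weights,
)
from robustcox.coxcore import build_risk_structure
from robustcox.penalties import penalty_value
from robustcox.pencox import solve_penalized

from conftest import random_survival_arrays
from test_coxcore import brute_force_nll


def toy_config(n, p, rng, family="lasso", lam1=0.05, lam2=0.1):
    w_tilde = rng.uniform(0.3, 0.95, n)
    beta_tilde = rng.standard_normal(p)
    return PawphConfig(
        penalty_family=family, lambda1=lam1, lambda2=lam2,
        w_tilde=w_tilde, beta_tilde=beta_tilde,
    )


def toy_dataset(rng, n=10, p=2):
    from robustcox import SurvivalDataset

    X, time, status = random_survival_arrays(rng, n=n, p=p)
    return SurvivalDataset(X=X, time=time, status=status)


class TestObjective:
    def test_matches_term_by_term_summation(self, rng):
        ds = toy_dataset(rng, n=5, p=2)
        cfg = toy_config(5, 2, rng)
        for _ in range(5):
            beta = rng.standard_normal(2)
            w = rng.uniform(0.1, 1.0, 5)
            expect = brute_force_nll(beta, w, ds.X, ds.time, ds.status)
            expect += cfg.lambda1 * np.sum(
                np.abs(np.log(w)) / np.abs(np.log(cfg.w_tilde))
            )
            expect += penalty_value(cfg.penalty_spec(), beta)
            assert pawph_objective(beta, w, cfg, ds) == pytest.approx(
                expect, abs=1e-12
            )

    def test_unit_weights_drop_weight_penalty(self, rng):
        ds = toy_dataset(rng, n=8, p=2)
        cfg = toy_config(8, 2, rng, lam1=100.0)
        beta = rng.standard_normal(2)
        w1 = np.ones(8)
        expect = neg_log_partial_likelihood(beta, w1, ds) + penalty_value(
            cfg.penalty_spec(), beta
        )
        assert pawph_objective(beta, w1, cfg, ds) == pytest.approx(expect)

    def test_null_composition(self, rng):
        ds = toy_dataset(rng, n=9, p=2)
        cfg = toy_config(9, 2, rng, lam2=0.3)
        cfg.beta_tilde = np.ones(2)
        rs = build_risk_structure(ds.time, ds.status)
        expect = sum(
            np.log(len(s)) for s in rs.risk_sets
        ) / ds.n
        assert pawph_objective(np.zeros(2), np.ones(9), cfg, ds) == pytest.approx(
            expect
        )

    def test_weights_outside_unit_interval_rejected(self, rng):
        ds = toy_dataset(rng, n=6, p=2)
        cfg = toy_config(6, 2, rng)
        with pytest.raises(ValueError):
            pawph_objective(np.zeros(2), np.full(6, 1.2), cfg, ds)


class TestBetaUpdate:
    def test_unit_weight_reduction_to_penalized_cox(self, rng):
        ds = toy_dataset(rng, n=40, p=3)
        cfg = toy_config(40, 3, rng, lam2=0.05)
        beta0 = np.zeros(3)
        via_pawph = update_beta(beta0, np.ones(40), cfg, ds)
        direct, _, _ = solve_penalized(
            ds.X, ds.time, ds.status, cfg.penalty_spec(), w=np.ones(40),
            beta0=beta0, tol=cfg.tol,
        )
        assert np.array_equal(via_pawph, direct)

    def test_descent(self, rng):
        ds = toy_dataset(rng, n=30, p=3)
        cfg = toy_config(30, 3, rng)
        w = rng.uniform(0.3, 1.0, 30)
        beta = rng.standard_normal(3) * 0.3
        before = pawph_objective(beta, w, cfg, ds)
        after = pawph_objective(update_beta(beta, w, cfg, ds), w, cfg, ds)
        assert after <= before + 1e-10

    def test_matches_independent_optimizer(self, rng):
        from scipy.optimize import minimize

        ds = toy_dataset(rng, n=20, p=3)
        cfg = toy_config(20, 3, rng, lam2=0.08)
        w = rng.uniform(0.4, 1.0, 20)
        beta = update_beta(np.zeros(3), w, cfg, ds)

        def obj(b):
            return neg_log_partial_likelihood(b, w, ds) + penalty_value(
                cfg.penalty_spec(), b
            )

        res = minimize(obj, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
        assert obj(beta) <= res.fun + 1e-4


class TestWeightUpdate:
    def test_huge_lambda1_pins_weights_at_one(self, rng):
        ds = toy_dataset(rng, n=15, p=2)
        cfg = toy_config(15, 2, rng, lam1=1e6)
        w = update_weights(rng.standard_normal(2), rng.uniform(0.3, 1, 15), cfg, ds)
        assert np.allclose(w, 1.0)

    def test_descent(self, rng):
        ds = toy_dataset(rng, n=25, p=3)
        cfg = toy_config(25, 3, rng, lam1=0.001)
        beta = rng.standard_normal(3) * 0.5
        w0 = rng.uniform(0.3, 1.0, 25)
        before = pawph_objective(beta, w0, cfg, ds)
        after = pawph_objective(beta, update_weights(beta, w0, cfg, ds), cfg, ds)
        assert after <= before + 1e-10

    def test_matches_coordinate_grid_oracle(self, rng):
        # oracle: the same cyclic pass but with exhaustive 1e-3 grid search
        ds = toy_dataset(rng, n=10, p=2)
        cfg = toy_config(10, 2, rng, lam1=0.002)
        beta = rng.standard_normal(2) * 0.5
        w0 = rng.uniform(0.3, 1.0, 10)
        w_fast = update_weights(beta, w0, cfg, ds)

        grid = np.exp(np.arange(np.log(cfg.w_min), 1e-12, 1e-3))
        grid = np.append(grid, 1.0)
        w_ref = w0.copy()
        for i in range(10):
            best, best_val = w_ref[i], pawph_objective(beta, w_ref, cfg, ds)
            trial = w_ref.copy()
            for g in grid:
                trial[i] = g
                val = pawph_objective(beta, trial, cfg, ds)
                if val < best_val - 1e-15:
                    best, best_val = g, val
            w_ref[i] = best
        assert np.abs(w_fast - w_ref).max() < 2e-3


class TestInitialize:
    def test_contracts(self):
        ds = generate_dataset(ScenarioConfig.preset("S5", seed=9))
        beta_tilde, w_tilde = initialize(ds)
        assert np.all((w_tilde >= 1e-3) & (w_tilde <= 1.0))
        assert len(beta_tilde) == ds.p
        # exchangeability: duplicated observations get identical weights
        from robustcox import SurvivalDataset

        X2 = np.vstack([ds.X[:5], ds.X[:5]])
        ds2 = SurvivalDataset(
            X=X2,
            time=np.concatenate([ds.time[:5], ds.time[:5]]),
            status=np.concatenate([ds.status[:5], ds.status[:5]]),
        )
        _, w2 = initialize(ds2)
        assert np.allclose(w2[:5], w2[5:])


class TestFullFit:
    def test_objective_trace_non_increasing(self, rng):
        ds = generate_dataset(
            ScenarioConfig.preset("design1", seed=21)
        )
        fit = fit_pawph(ds, PawphConfig(penalty_family="mcp", lambda1=0.01,
                                        lambda2=0.1))
        assert np.all(np.diff(fit.objective_trace) <= 1e-10)
        assert np.all((fit.w_hat > 0) & (fit.w_hat <= 1))
        assert set(fit.selected.tolist()) == set(
            np.flatnonzero(fit.beta_hat).tolist()
        )

    def test_pinned_weights_reduce_to_penalized_cox(self, rng):
        ds = toy_dataset(rng, n=60, p=4)
        bt, wt = initialize(ds)
        cfg = PawphConfig(penalty_family="lasso", lambda1=np.inf, lambda2=0.05,
                          beta_tilde=bt, w_tilde=wt)
        fit = fit_pawph(ds, cfg)
        assert np.all(fit.w_hat == 1.0)
        direct, _, _ = solve_penalized(
            ds.X, ds.time, ds.status, cfg.penalty_spec(), beta0=bt, tol=cfg.tol
        )
        assert np.allclose(fit.beta_hat, direct, atol=1e-8)
        assert set(fit.selected.tolist()) == set(np.flatnonzero(direct).tolist())

    def test_weights_not_collapsed_to_constant(self):
        # the anchor at w=1 breaks scale invariance: fitted weights must not
        # all equal some non-unit constant
        ds = generate_dataset(
            ScenarioConfig.preset("design1", seed=33)
        )
        fit = fit_pawph(ds, PawphConfig(penalty_family="lasso", lambda1=0.005,
                                        lambda2=0.05))
        w = fit.w_hat
        if not np.allclose(w, 1.0):
            assert w.max() - w.min() > 1e-6
        assert np.isclose(w.max(), 1.0, atol=1e-3)

    def test_deterministic(self, rng):
        ds = toy_dataset(rng, n=50, p=3)
        f1 = fit_pawph(ds, PawphConfig(penalty_family="scad", lambda1=0.01,
                                       lambda2=0.05))
        f2 = fit_pawph(ds, PawphConfig(penalty_family="scad", lambda1=0.01,
                                       lambda2=0.05))
        assert np.array_equal(f1.beta_hat, f2.beta_hat)
        assert np.array_equal(f1.w_hat, f2.w_hat)


class TestTuning:
    def test_degenerate_grids(self, rng):
        ds = toy_dataset(rng, n=60, p=3)
        (l1, l2), scores = tune_pawph(ds, "lasso", grid1=[0.01], grid2=[0.1],
                                      K=3, seed=4)
        assert (l1, l2) == (0.01, 0.1)
        assert scores.shape == (1, 1)

    def test_deterministic(self, rng):
        ds = toy_dataset(rng, n=60, p=3)
        a = tune_pawph(ds, "lasso", grid1=[0.005, 0.05], grid2=[0.05, 0.2],
                       K=3, seed=7)
        b = tune_pawph(ds, "lasso", grid1=[0.005, 0.05], grid2=[0.05, 0.2],
                       K=3, seed=7)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])
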