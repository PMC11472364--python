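"""Simulator: correlation structure, scenario coefficients, event times,
contamination and censoring."""

import math

import numpy as np
import pytest

from robustcox import (
    CorrelationSpec,
    OUTLIER_GRID,
    ScenarioConfig,
    SurvivalDataset,
    apply_censoring,
    build_correlation_matrix,
    contaminate,
    draw_covariates,
    draw_event_times,
    generate_dataset,
    scenario_coefficients,
)
from robustcox.datagen import InvalidSpecError


class TestCorrelationMatrix:
    def test_block_entries(self):
        R = build_correlation_matrix(CorrelationSpec("scenario_block", 30))
        assert R[0, 1] == R[0, 2] == R[1, 2] == 0.9
        assert R[3, 4] == R[3, 5] == R[4, 5] == 0.7
        assert R[0, 3] == R[1, 3] == R[2, 3] == 0.0
        assert R[6, 7] == 0.1
        assert R[0, 4] == 0.1  # block 1 vs vars 5,6 is background
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)

    @pytest.mark.parametrize("p", [6, 30, 200])
    def test_positive_definite(self, p):
        R = build_correlation_matrix(CorrelationSpec("scenario_block", p))
        assert np.linalg.eigvalsh(R).min() > 0

    def test_identity(self):
        assert np.array_equal(
            build_correlation_matrix(CorrelationSpec("identity", 5)), np.eye(5)
        )

    def test_too_small_p_rejected(self):
        with pytest.raises(InvalidSpecError):
            build_correlation_matrix(CorrelationSpec("scenario_block", 5))

    def test_non_pd_custom_rejected(self):
        M = np.full((3, 3), 0.99)
        np.fill_diagonal(M, 1.0)
        M[0, 1] = M[1, 0] = -0.99  # not PD
        with pytest.raises(np.linalg.LinAlgError):
            build_correlation_matrix(CorrelationSpec("custom", 3, custom_matrix=M))


class TestScenarioCoefficients:
    # six-scenario table: leading six coefficients plus the final one
    TABLE = {
        "S1": ([10, -3, 3, -10, -3, 3], 5),
        "S2": ([10, 0, 3, -10, -3, 0], 5),
        "S3": ([2, -3, 3, -2, -3, 3], 2),
        "S4": ([0, 0, 3, 0, -3, 0], 5),
        "S5": ([10, 0, 0, 10, 0, 0], 5),
        "S6": ([2, 0, 0, -2, 0, 0], 2),
    }

    @pytest.mark.parametrize("sid", sorted(TABLE))
    def test_table_rows(self, sid):
        head, last = self.TABLE[sid]
        beta = scenario_coefficients(sid, 30)
        assert beta[:6].tolist() == [float(h) for h in head]
        assert np.all(beta[6:29] == 0)
        assert beta[29] == last

    def test_design1(self):
        beta = scenario_coefficients("design1", 30)
        assert beta[:3].tolist() == [1.0, 2.0, -1.0]
        assert np.all(beta[3:] == 0)

    def test_sparse_scenarios_have_three_signals(self):
        for sid in ("S4", "S5", "S6"):
            assert np.count_nonzero(scenario_coefficients(sid, 30)) == 3

    def test_unknown_scenario(self):
        with pytest.raises(InvalidSpecError):
            scenario_coefficients("S9", 30)


class TestCovariates:
    def test_seeded_determinism(self):
        R = build_correlation_matrix(CorrelationSpec("scenario_block", 10))
        X1 = draw_covariates(50, R, 3)
        X2 = draw_covariates(50, R, 3)
        assert np.array_equal(X1, X2)

    def test_independence_under_identity(self):
        X = draw_covariates(100_000, np.eye(4), 0)
        r = np.corrcoef(X.T)
        off = r[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_block_correlation_monte_carlo(self):
        R = build_correlation_matrix(CorrelationSpec("scenario_block", 8))
        X = draw_covariates(200_000, R, 1)
        emp = np.corrcoef(X.T)
        assert abs(emp[0, 1] - 0.9) < 0.01
        assert np.abs(emp - R).max() < 0.01


class TestEventTimes:
    def test_null_beta_recovers_baseline_weibull_median(self):
        # closed form: median of Weibull(shape, scale) = scale*ln(2)^(1/shape)
        shape, scale = 5.0, 0.5
        X = np.zeros((200_000, 2))
        T = draw_event_times(X, np.zeros(2), shape, scale, 0)
        expect = scale * math.log(2.0) ** (1.0 / shape)
        assert abs(np.median(T) - expect) / expect < 0.01

    def test_higher_risk_shortens_times(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        n = 10_000
        X = np.zeros((2 * n, 1))
        X[n:, 0] = 2.0  # linear predictor +2 in second half
        T = draw_event_times(X, np.array([1.0]), 5.0, 0.5, 4)
        stat = mannwhitneyu(T[n:], T[:n], alternative="less")
        assert stat.pvalue < 1e-10

    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((30, 2))
        b = np.array([0.5, -1.0])
        assert np.array_equal(
            draw_event_times(X, b, 5, 0.5, 9), draw_event_times(X, b, 5, 0.5, 9)
        )

    def test_nonfinite_predictor_rejected(self):
        X = np.array([[np.nan]])
        with pytest.raises(ValueError):
            draw_event_times(X, np.array([1.0]), 5, 0.5, 0)


class TestContamination:
    def test_zero_proportion(self, rng):
        t = rng.uniform(0, 2, 40)
        out, flags = contaminate(t, 0.0, 1)
        assert np.array_equal(out, t) and flags.sum() == 0

    @pytest.mark.parametrize("prop", OUTLIER_GRID)
    @pytest.mark.parametrize("n", [300, 1000, 37])
    def test_exact_ceiling_counts(self, prop, n, rng):
        t = rng.uniform(0, 2, n)
        _, flags = contaminate(t, prop, 2)
        assert flags.sum() == math.ceil(round(prop * n, 12))

    def test_design1_count_is_fifteen(self, rng):
        t = rng.uniform(0, 2, 300)
        _, flags = contaminate(t, 0.05, 3)
        assert flags.sum() == 15

    def test_shift_equals_median_exactly(self, rng):
        t = rng.uniform(0, 2, 101)
        out, flags = contaminate(t, 0.1, 4)
        idx = flags.astype(bool)
        med = np.median(t)
        assert np.all(out[idx] == t[idx] + med)
        assert np.array_equal(out[~idx], t[~idx])
        assert np.all(out[idx] > t[idx])  # monotone effect (median > 0)


class TestCensoring:
    def test_total_censoring(self, rng):
        t = rng.uniform(5, 6, 50)
        time, status = apply_censoring(t, 0.0, 1.0, 0)
        assert status.sum() == 0 and np.all(time < 1.0)

    def test_no_censoring(self, rng):
        t = rng.uniform(0, 1, 50)
        time, status = apply_censoring(t, 2.0, 3.0, 0)
        assert status.sum() == 50 and np.array_equal(time, t)

    def test_censoring_rate_matches_independent_monte_carlo(self):
        # oracle: independent large-sample estimate of P(T <= C) under S3
        cfg = ScenarioConfig.preset("S3", seed=0)
        R = build_correlation_matrix(cfg.correlation)
        rng = np.random.default_rng(999)
        n_mc = 1_000_000
        X = rng.standard_normal((n_mc, cfg.p)) @ np.linalg.cholesky(R).T
        eta = X @ cfg.beta
        E = rng.standard_exponential(n_mc)
        T = cfg.weibull_scale * np.exp((np.log(E) - eta) / cfg.weibull_shape)
        C = rng.uniform(cfg.censor_low, cfg.censor_high, n_mc)
        oracle_rate = float(np.mean(T > C))

        rates = [
            1.0 - generate_dataset(
                ScenarioConfig.preset("S3", seed=s, n=10_000)
            ).status.mean()
            for s in range(5)
        ]
        assert abs(np.mean(rates) - oracle_rate) < 0.01


class TestPipeline:
    def test_design1_preset(self):
        ds = generate_dataset(ScenarioConfig.preset("design1", seed=5))
        assert ds.n == 300 and ds.p == 30
        assert ds.outlier_flags.sum() == 15
        assert np.array_equal(ds.true_beta[:3], [1.0, 2.0, -1.0])

    def test_no_outliers_means_no_flags(self):
        ds = generate_dataset(ScenarioConfig.preset("S4", seed=1))
        assert ds.outlier_flags.sum() == 0

    def test_bit_identical_reruns(self):
        a = generate_dataset(ScenarioConfig.preset("S2", seed=11))
        b = generate_dataset(ScenarioConfig.preset("S2", seed=11))
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.status, b.status)
        assert np.array_equal(a.outlier_flags, b.outlier_flags)

    def test_csv_round_trip(self, tmp_path):
        ds = generate_dataset(ScenarioConfig.preset("S6", seed=2, n=40))
        f = tmp_path / "data.csv"
        ds.to_csv(f)
        back = SurvivalDataset.from_csv(f)
        assert np.allclose(back.X, ds.X)
        assert np.allclose(back.time, ds.time)
        assert np.array_equal(back.status, ds.status)
        assert np.array_equal(back.outlier_flags, ds.outlier_flags)

    def test_config_round_trip(self):
        cfg = ScenarioConfig.preset("S1", seed=3, outlier_proportion=0.05)
        cfg2 = ScenarioConfig.from_dict(cfg.to_dict())
        a, b = generate_dataset(cfg), generate_dataset(cfg2)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.time, b.time)

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidSpecError):
            ScenarioConfig("custom", n=10, p=2, beta=np.ones(2), censor_low=5,
                           censor_high=1)
        with pytest.raises(InvalidSpecError):
            ScenarioConfig("custom", n=10, p=2, beta=np.ones(3))
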