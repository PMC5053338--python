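"""Synthetic-data generator, frozen reference fixture and parameter
recovery."""

import numpy as np
import pandas as pd
import pytest

from pathdc import (
    PathwayDecisionAnalysis,
    SimulationConfig,
    default_config,
    exact_correlated_dataset,
    exchangeable_correlation,
    recovery_experiment,
    simulate_dataset,
)


class TestConfig:
    def test_default_population_targets(self):
        cfg = default_config()
        assert cfg.q == 4 and cfg.n == 12
        assert cfg.y_sd == pytest.approx(1.0)
        # population R^2 = b'Rb / Var(y) = 0.9
        assert cfg.b @ cfg.r_x @ cfg.b == pytest.approx(0.9)
        np.testing.assert_allclose(cfg.b_star_pop, cfg.b)

    def test_non_positive_definite_rejected(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            SimulationConfig(r_x=r, b=np.zeros(2), n=10, noise_sd=0.1)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n >= q"):
            SimulationConfig(r_x=np.eye(3), b=np.zeros(3), n=4, noise_sd=0.1)

    def test_exchangeable_correlation_domain(self):
        with pytest.raises(ValueError, match="positive-definite range"):
            exchangeable_correlation(3, -0.6)


class TestSimulateDataset:
    def test_same_seed_same_data(self):
        cfg = default_config(seed=42)
        pd.testing.assert_frame_equal(simulate_dataset(cfg), simulate_dataset(cfg))

    def test_different_seed_different_data(self):
        a = simulate_dataset(default_config(seed=1))
        b = simulate_dataset(default_config(seed=2))
        assert not np.allclose(a.to_numpy(), b.to_numpy())

    def test_layout(self):
        data = simulate_dataset(default_config(q=3, n=8))
        assert data.shape == (4, 8)
        assert list(data.index) == ["x1", "x2", "x3", "y"]

    def test_identity_correlation_recovered_at_large_n(self):
        cfg = SimulationConfig(r_x=np.eye(4), b=np.full(4, 0.4), n=5000,
                               noise_sd=0.3, seed=11)
        data = simulate_dataset(cfg)
        emp = np.corrcoef(data.iloc[:4].to_numpy())
        off = ~np.eye(4, dtype=bool)
        assert np.abs(emp[off]).max() < 0.05

    def test_target_correlation_convergence_seed_averaged(self):
        # max elementwise deviation <= 3/sqrt(n) averaged over seeds
        r = exchangeable_correlation(3, 0.5)
        n = 2000
        devs = []
        for seed in range(5):
            cfg = SimulationConfig(r_x=r, b=np.full(3, 0.5), n=n,
                                   noise_sd=0.3, seed=seed)
            data = simulate_dataset(cfg)
            emp = np.corrcoef(data.iloc[:3].to_numpy())
            devs.append(np.abs(emp - r).max())
        assert np.mean(devs) <= 3 / np.sqrt(n)


class TestExactDataset:
    def test_sample_correlations_are_exact(self, ref4):
        data = exact_correlated_dataset(ref4.r_x, ref4.b_star, 20, seed=3)
        emp = np.corrcoef(data.iloc[:4].to_numpy())
        np.testing.assert_allclose(emp, ref4.r_x, atol=1e-12)

    def test_parent_is_exact_linear_response_plus_orthogonal_noise(self, ref4):
        data = exact_correlated_dataset(ref4.r_x, ref4.b_star, 20, noise_sd=0.1, seed=3)
        x = data.iloc[:4].to_numpy().T
        y = data.iloc[4].to_numpy()
        resid = y - x @ ref4.b_star
        # noise orthogonal to children in-sample
        assert np.abs((x - x.mean(0)).T @ (resid - resid.mean())).max() < 1e-9


class TestReferenceFixture:
    def test_dc_recomputed_from_model(self, ref4):
        est = ref4.estimator()
        np.testing.assert_allclose(est.dc_, ref4.dc_expected, atol=0.005)

    def test_x2_normal_equation_holds_exactly_in_print(self, ref4):
        # -1.097 + 0.243 = -0.854 with the printed addends
        assert ref4.b_star[1] + ref4.indirect_sums_printed[1] == pytest.approx(
            ref4.r_jy_printed[1], abs=1e-12
        )

    def test_printed_indirect_sums_match_printed_products(self, ref4):
        sums = ref4.products_printed.sum(axis=1, skipna=True).to_numpy()
        np.testing.assert_allclose(sums, ref4.indirect_sums_printed, atol=1e-9)

    def test_retro_values_reproduced(self, ref4):
        est = ref4.estimator()
        np.testing.assert_allclose(
            est.retro_[[1, 2]], ref4.retro_printed[[1, 2]], atol=0.01
        )


class TestRecovery:
    def test_high_information_run_recovers_b(self):
        # Var(y) = 1 with noise_sd = 0.1 so truth is b itself
        r = exchangeable_correlation(4, 0.3)
        base = np.array([1.0, -1.0, 0.5, -0.5])
        b = base * np.sqrt((1 - 0.1**2) / (base @ r @ base))
        cfg = SimulationConfig(r_x=r, b=b, n=5000, noise_sd=0.1, seed=5)
        res = recovery_experiment(cfg, replicates=3)
        assert np.abs(res.table["b_bias"].to_numpy()).max() < 0.05
        assert res.b_rmse.max() < 0.05

    def test_rmse_vanishes_with_noise(self):
        r = exchangeable_correlation(3, 0.2)
        b = np.array([0.6, -0.4, 0.3])
        cfg = SimulationConfig(r_x=r, b=b, n=10000, noise_sd=1e-6, seed=9)
        res = recovery_experiment(cfg, replicates=2)
        assert res.b_rmse.max() < 0.01

    def test_seed_fixed_run_reproduces_summary(self):
        cfg = default_config(seed=123)
        t1 = recovery_experiment(cfg, replicates=10).table
        t2_ = recovery_experiment(cfg, replicates=10).table
        pd.testing.assert_frame_equal(t1, t2_)

    def test_null_model_selection_frequency_recorded(self):
        # pure-noise response: record the empirical size of the cutoff
        # test; the threshold formula is approximate, so only a sanity
        # bound is asserted
        cfg = SimulationConfig(
            r_x=exchangeable_correlation(4, 0.3), b=np.zeros(4), n=12,
            noise_sd=1.0, seed=7,
        )
        res = recovery_experiment(cfg, replicates=200)
        freq = res.table["sel_freq_0.05"].to_numpy()
        assert np.all(freq < 0.5)
        assert np.all(res.table["sel_freq_0.01"] <= res.table["sel_freq_0.05"] + 0.05)

    def test_replicates_validation(self):
        with pytest.raises(ValueError, match="replicates"):
            recovery_experiment(default_config(), replicates=0)

    def test_coverage_of_population_coefficients(self):
        # fitted b* within 3 Monte-Carlo standard errors of truth in
        # >= 95% of replicates at n=1000 (errors are not heavy-tailed);
        # the analytic OLS standard error is too small here because it
        # ignores the sampling noise of the standardization itself
        cfg = default_config(n=1000, seed=31)
        reps = 60
        seeds = np.random.SeedSequence(cfg.seed).generate_state(reps) % (2**31)
        errors = np.empty((reps, 4))
        for i, seed in enumerate(seeds):
            data = simulate_dataset(
                SimulationConfig(r_x=cfg.r_x, b=cfg.b, n=cfg.n,
                                 noise_sd=cfg.noise_sd, seed=int(seed))
            )
            est = PathwayDecisionAnalysis().fit(
                data.iloc[:4].to_numpy().T, data.iloc[4].to_numpy()
            )
            errors[i] = est.b_star_ - cfg.b_star_pop
        se = np.sqrt((errors**2).mean(axis=0))
        coverage = np.all(np.abs(errors) <= 3 * se, axis=1).mean()
        assert coverage >= 0.95
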