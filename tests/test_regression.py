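"""Regression diagnostics, ARMA order selection, the joint Bayesian fit and
its derived recombination statistics."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.arima_process import ArmaProcess

from mutvar import regression as reg
from mutvar import synthetic, filters
from mutvar._arma_likelihood import arma_regression_loglike
from mutvar._util import spawn_rng
from mutvar.filters import BlockSeries
from mutvar.synthetic import BlockSimParams


def series_from(rate, density):
    rate = np.asarray(rate, dtype=float)
    return BlockSeries(chrom="chr1", start=np.arange(len(rate)) * 10_000,
                       rate=rate, density=np.asarray(density, dtype=float))


class TestOls:
    def test_noiseless_simulation_recovered_exactly(self):
        s, _ = synthetic.simulate_blocks(BlockSimParams(
            n_blocks=100, intercept_true=0.026, slope_true=0.007,
            noise_sd=0.0, arma_order=(0, 0), ar_coeffs=(), ma_coeffs=(),
            binomial_counts=False, seed=2))
        a, b, resid = reg.fit_ols(s)
        assert a == pytest.approx(0.026, abs=1e-10)
        assert b == pytest.approx(0.007, abs=1e-10)
        assert np.abs(resid).max() < 1e-12

    def test_collinear_points(self):
        a, b, _ = reg.fit_ols(series_from([0, 1, 2], [0.02, 0.03, 0.04]))
        assert (a, b) == (pytest.approx(0.02), pytest.approx(0.01))

    def test_constant_rate_is_singular(self):
        with pytest.raises(ValueError, match="singular|constant"):
            reg.fit_ols(series_from([1, 1, 1], [0.02, 0.03, 0.04]))

    def test_unbiased_under_arma_noise(self):
        """OLS point estimates stay unbiased under correlated errors; only
        the error bars are wrong. 60 replicates, slope averaged."""
        slopes = []
        for seed in range(60):
            s, _ = synthetic.simulate_blocks(BlockSimParams(
                n_blocks=2000, arma_order=(1, 0), ar_coeffs=(0.8,),
                ma_coeffs=(), noise_sd=0.003, seed=3000 + seed))
            _, b, _ = reg.fit_ols(s)
            slopes.append(b)
        mc_se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.007) < 2 * mc_se


class TestAcf:
    def test_lag_zero_is_one(self):
        x = np.random.default_rng(0).normal(size=500)
        assert reg.residual_acf(x, 10)[0] == 1.0

    def test_white_noise_within_band(self):
        x = np.random.default_rng(2).normal(size=10_000)
        acf = reg.residual_acf(x, 50)
        inside = np.abs(acf[1:]) < 4 / np.sqrt(len(x))
        assert inside.sum() >= 48

    def test_ar1_geometric_decay(self):
        rng = np.random.default_rng(3)
        x = ArmaProcess.from_coeffs([0.5], []).generate_sample(
            50_000, distrvs=rng.standard_normal)
        acf = reg.residual_acf(x, 5)
        for lag in (1, 2, 3):
            assert acf[lag] == pytest.approx(0.5 ** lag, abs=0.03)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            reg.residual_acf(np.ones(100), 10)


class TestAdf:
    def test_white_noise_is_stationary(self):
        x = np.random.default_rng(5).normal(size=2000)
        *_, verdict = reg.adf_stationarity(x)
        assert verdict

    def test_random_walk_is_not(self):
        x = np.cumsum(np.random.default_rng(5).normal(size=2000))
        *_, verdict = reg.adf_stationarity(x)
        assert not verdict

    def test_near_unit_root_returns_without_error(self):
        rng = np.random.default_rng(6)
        x = ArmaProcess.from_coeffs([0.99], []).generate_sample(
            200, distrvs=rng.standard_normal)
        stat, p, verdict = reg.adf_stationarity(x)
        assert np.isfinite(stat) and 0 <= p <= 1

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            reg.adf_stationarity(np.full(100, 0.3))


class TestLikelihood:
    @pytest.mark.parametrize("order", [(1, 0), (1, 1), (2, 1), (3, 2), (0, 1)])
    def test_matches_statsmodels_kalman_filter(self, order):
        """Independent cross-check of the jitted ARMA-regression likelihood."""
        p, q = order
        rng = np.random.default_rng(7)
        n = 400
        x = rng.gamma(0.6, 1 / 0.6, n)
        y = 0.026 + 0.007 * x + rng.normal(0, 0.003, n)
        model = ARIMA(y, exog=x, order=(p, 0, q), trend="c")
        phi = 0.3 * rng.random(p)
        th = 0.3 * rng.random(q)
        params = np.r_[0.025, 0.006, phi, th, 8e-6]
        expected = model.loglike(params, transformed=True, includes_fixed=True)
        got = arma_regression_loglike(y, x, 0.025, 0.006, phi, th, 8e-6)
        assert got == pytest.approx(expected, abs=1e-6)


class TestOrderSelection:
    def test_arma11_identified_at_large_n(self):
        rng = spawn_rng(9, 2)
        resid = ArmaProcess.from_coeffs([0.6], [0.3]).generate_sample(
            20_000, burnin=100, distrvs=rng.standard_normal)
        sel = reg.select_arma_order(resid, p_max=3, q_max=2)
        p, q = sel.chosen
        assert p >= 1 and q >= 1

    def test_white_noise_prefers_minimal_model(self):
        resid = np.random.default_rng(2).normal(size=20_000)
        sel = reg.select_arma_order(resid, p_max=2, q_max=1)
        ranked = sel.ranked
        aic_10 = float(ranked.loc[(ranked["p"] == 1) & (ranked["q"] == 0), "aic"].iloc[0])
        assert sel.chosen == (1, 0) or float(ranked["aic"].iloc[0]) > aic_10 - 2

    def test_second_rank_fallback(self):
        resid = np.random.default_rng(3).normal(size=2_000)
        sel = reg.select_arma_order(resid, p_max=2, q_max=1, rank=2)
        assert sel.rank_used == 2
        assert sel.chosen == tuple(sel.ranked.iloc[1][["p", "q"]].astype(int))
        assert sel.chosen != sel.order_at_rank(1)

    def test_p_zero_grid_rejected(self):
        with pytest.raises(ValueError):
            reg.select_arma_order(np.random.default_rng(0).normal(size=100), p_max=0)


def posterior_from_draws(alpha, beta, order=(1, 0)):
    draws = pd.DataFrame({"alpha": np.asarray(alpha, dtype=float),
                          "beta": np.asarray(beta, dtype=float),
                          "phi1": np.zeros(len(alpha)),
                          "sigma": np.full(len(alpha), 1e-3)})
    return reg.RegressionPosterior(draws=draws, order=order, n_chains=1,
                                   n_draws=len(draws), rhat={}, converged=True,
                                   prior_description={})


class TestSummaries:
    def test_prob_slope_le_zero_is_a_count(self):
        post = posterior_from_draws(alpha=[0.02] * 4, beta=[-1, 1, 2, 3])
        s = reg.summarize_recombination(post, series_from([0, 1, 2], [0.02, 0.03, 0.04]))
        assert s.prob_slope_le_0 == 0.25

    def test_rho_hat_formula(self):
        post = posterior_from_draws(alpha=[0.021], beta=[0.0])
        blocks = series_from([1.0, 2.0, 3.0], [0.028, 0.028, 0.028])
        s = reg.summarize_recombination(post, blocks)
        assert s.rho_hat == pytest.approx((0.028 - 0.021) / 0.028)

    def test_noiseless_fit_explains_all_variance(self):
        blocks = series_from([0, 1, 2, 3], [0.02, 0.03, 0.04, 0.05])
        post = posterior_from_draws(alpha=[0.02] * 3, beta=[0.01] * 3)
        s = reg.summarize_recombination(post, blocks)
        assert s.r2 == pytest.approx(1.0)
        assert s.sigma2_rec == pytest.approx(float(np.var(blocks.density)))

    def test_rho_invariant_to_density_rescaling(self):
        blocks = series_from([0, 1, 2, 3], [0.02, 0.03, 0.04, 0.05])
        post = posterior_from_draws(alpha=[0.022], beta=[0.009])
        s1 = reg.summarize_recombination(post, blocks)
        scaled = series_from(blocks.rate, blocks.density * 0.5)
        post2 = posterior_from_draws(alpha=[0.011], beta=[0.0045])
        s2 = reg.summarize_recombination(post2, scaled)
        assert s1.rho_hat == pytest.approx(s2.rho_hat)
        assert s1.mutations_per_crossover == pytest.approx(s2.mutations_per_crossover)

    def test_zero_mean_density_rejected(self):
        post = posterior_from_draws(alpha=[0.0], beta=[0.0])
        with pytest.raises(ValueError):
            reg.summarize_recombination(post, series_from([0, 1, 2], [0.0, 0.0, 0.0]))


class TestWorkedExamples:
    def test_naive_slope_based_mutations_per_crossover(self):
        assert reg.slope_implied_mutations_per_crossover_naive(0.0015) == pytest.approx(0.15)
        assert reg.slope_implied_mutations_per_crossover_naive(0.0) == 0.0
        assert reg.slope_implied_mutations_per_crossover_naive(0.003) == pytest.approx(0.30)
        with pytest.raises(ValueError):
            reg.slope_implied_mutations_per_crossover_naive(-0.001)

    def test_crossover_share_of_mutation_rate(self):
        prop = reg.proportion_mutation_rate_from_crossovers(0.0029, 1.16e-8, 1.19e-8)
        assert round(100 * prop, 2) == 0.28


class TestBayesFit:
    def test_white_noise_ar_coefficient_near_zero(self):
        s, _ = synthetic.simulate_blocks(BlockSimParams(
            n_blocks=2000, arma_order=(0, 0), ar_coeffs=(), ma_coeffs=(),
            noise_sd=0.003, seed=13))
        a = filters.apply_exclusions(s)
        post = reg.fit_bayes_arma_regression(a, (1, 0), reg.McmcConfig(seed=13))
        assert abs(post.draws["phi1"].mean()) < 0.05

    def test_posterior_reproducible_for_fixed_seed(self, arma_block_fit):
        analysis, post, _ = arma_block_fit
        again = reg.fit_bayes_arma_regression(analysis, (1, 1),
                                              reg.McmcConfig(seed=5),
                                              fallback_orders=[(2, 1)])
        pd.testing.assert_frame_equal(post.draws, again.draws)

    def test_posterior_covers_truth(self, arma_block_fit):
        analysis, post, truth = arma_block_fit
        s = reg.summarize_recombination(post, analysis)
        p = truth["params"]
        assert s.intercept_ci[0] <= p.intercept_true <= s.intercept_ci[1]
        assert s.slope_ci[0] <= p.slope_true <= s.slope_ci[1]
        assert s.prob_slope_le_0 < 0.01  # strong true slope: no posterior doubt
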