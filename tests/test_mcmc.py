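"""Sampler contracts and Monte Carlo diagnostics."""

import math

import numpy as np
import pytest

from phylobeta.mcmc import (ChainSet, SamplerSettings, autocorrelation,
                            chainset_ess, chainset_rhat, effective_sample_size,
                            fit_model, gelman_rubin, hpd_interval, mcse,
                            run_chains)


def ar1_chain(rho, n, seed=0, sd=1.0):
    rng = np.random.Generator(np.random.PCG64(seed))
    innov_sd = sd * math.sqrt(1 - rho ** 2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + rng.normal(0, innov_sd)
    return x


class TestRunChains:
    def test_same_seed_is_bit_identical(self):
        logpost = lambda x: -0.5 * float(x @ x)
        settings = SamplerSettings(n_chains=2, n_adapt=100, n_keep=200, seed=3)
        a = run_chains(logpost, np.zeros(2), settings)
        b = run_chains(logpost, np.zeros(2), settings)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_infinite_logpost_at_init_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            run_chains(lambda x: -math.inf, np.zeros(2),
                       SamplerSettings(n_chains=1, n_keep=10))

    def test_adaptation_draws_not_stored(self):
        chains = run_chains(lambda x: -0.5 * float(x @ x), np.zeros(1),
                            SamplerSettings(n_chains=1, n_adapt=50, n_keep=75))
        assert chains.draws.shape == (1, 75, 1)

    def test_conjugate_normal_toy_matches_closed_form(self):
        # Prior N(0, 1), five obs y ~ N(theta, 1): posterior
        # N(sum(y) / (n + 1), 1 / (n + 1)).
        y = np.array([0.3, -0.2, 1.1, 0.6, 0.4])
        post_mean = y.sum() / (len(y) + 1)
        post_sd = math.sqrt(1 / (len(y) + 1))

        def logpost(x):
            th = x[0]
            return -0.5 * th ** 2 - 0.5 * float(((y - th) ** 2).sum())

        chains = run_chains(logpost, np.zeros(1),
                            SamplerSettings(n_chains=2, n_adapt=500,
                                            n_keep=4000, seed=11))
        draws = chains.combined("x[0]")
        assert draws.mean() == pytest.approx(post_mean, abs=3 * mcse(draws))
        assert draws.std(ddof=1) == pytest.approx(post_sd, rel=0.05)


class TestFitModelContract:
    def test_same_seed_is_bit_identical(self, small_fit):
        from phylobeta.model import ModelSpec
        from phylobeta.synthetic_data import fit_synthetic

        again = fit_synthetic(small_fit["table"], small_fit["cov"],
                              ModelSpec(),
                              SamplerSettings(n_chains=2, n_adapt=300,
                                              n_keep=800, seed=5))
        np.testing.assert_array_equal(again.draws, small_fit["chains"].draws)

    def test_parameter_names_cover_all_blocks(self, small_fit):
        names = small_fit["chains"].names
        assert names[0] == "Intercept"
        assert names[-2:] == ["gamma", "lambda"]
        assert sum(n.startswith("u[") for n in names) == len(small_fit["table"])

    def test_lambda_draws_respect_prior_support(self, small_fit):
        lam = small_fit["chains"].combined("lambda")
        assert np.all((lam >= 0) & (lam <= 1.2))

    def test_gamma_draws_positive(self, small_fit):
        assert np.all(small_fit["chains"].combined("gamma") > 0)

    def test_unsqueezed_boundary_response_rejected(self, small_fit):
        from phylobeta.model import ModelSpec, build_design
        from phylobeta.traits import prepare_predictors

        prepared = prepare_predictors(small_fit["table"])
        design = build_design(prepared, ModelSpec())
        y = prepared.response.copy()
        y[0] = 0.0
        with pytest.raises(ValueError, match="strictly"):
            fit_model(design, y, small_fit["cov"], ModelSpec(),
                      SamplerSettings(n_chains=1, n_keep=10))


class TestGelmanRubin:
    def test_hand_computed_two_by_four(self):
        # Independent spreadsheet-style evaluation of the split formula.
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]])
        # split halves (n = 2): [1,2], [3,4], [2,3], [4,5]
        halves = np.array([[1, 2], [3, 4], [2, 3], [4, 5.0]])
        W = halves.var(axis=1, ddof=1).mean()
        B = 2 * halves.mean(axis=1).var(ddof=1)
        expected = math.sqrt(((2 - 1) / 2 * W + B / 2) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-12)

    def test_same_distribution_chains_near_one(self):
        rng = np.random.Generator(np.random.PCG64(5))
        chains = rng.normal(size=(2, 10_000))
        assert 0.999 <= gelman_rubin(chains) <= 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.Generator(np.random.PCG64(6))
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(chains) > 1.5

    def test_zero_variance_returns_nan_sentinel(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = gelman_rubin(np.ones((2, 100)))
        assert math.isnan(out)

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestEffectiveSampleSize:
    def test_iid_chain_near_n(self):
        # the truncation rule is noisy on any single chain; the iid limit
        # is a statement about its typical value
        rng = np.random.Generator(np.random.PCG64(7))
        ratios = [effective_sample_size(rng.normal(size=10_000)) / 10_000
                  for _ in range(5)]
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.10)

    def test_ar1_chain_matches_closed_form(self):
        n, rho = 50_000, 0.9
        x = ar1_chain(rho, n, seed=8)
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.15)

    def test_constant_chain_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            assert effective_sample_size(np.full(100, 2.5)) == 1.0

    def test_capped_at_n(self):
        # strongly antithetic chain would give ESS > n without the cap
        x = np.tile([1.0, -1.0], 500) + 0.01 * ar1_chain(0.0, 1000, seed=9)
        assert effective_sample_size(x) <= 1000


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        x = ar1_chain(0.5, 500, seed=10)
        assert autocorrelation(x, 10)[0] == pytest.approx(1.0)

    def test_alternating_chain_lag_one(self):
        n = 1000
        x = np.tile([1.0, -1.0], n // 2)
        rho1 = autocorrelation(x, 2)[1]
        assert rho1 == pytest.approx(-(n - 1) / n, abs=1e-12)

    def test_matches_direct_computation(self):
        x = ar1_chain(0.6, 400, seed=11)
        xc = x - x.mean()
        denom = float(xc @ xc)
        direct = [float(xc[:-k] @ xc[k:]) / denom for k in range(1, 6)]
        np.testing.assert_allclose(autocorrelation(x, 5)[1:], direct,
                                   atol=1e-12)

    def test_white_noise_band(self):
        rng = np.random.Generator(np.random.PCG64(12))
        n = 10_000
        rho = autocorrelation(rng.normal(size=n), 100)
        assert np.mean(np.abs(rho[1:]) < 3 / math.sqrt(n)) > 0.98

    def test_max_lag_bound(self):
        with pytest.raises(ValueError):
            autocorrelation(np.zeros(10), 5)


class TestHpdInterval:
    def test_grid_example_ties_to_lowest(self):
        draws = np.arange(100) / 100.0
        low, high = hpd_interval(draws, 0.95)
        assert (low, high) == (0.0, 0.94)

    def test_point_mass(self):
        low, high = hpd_interval(np.full(50, 3.3), 0.95)
        assert (low, high) == (3.3, 3.3)

    def test_matches_exhaustive_window_search(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 800))
            draws = rng.gamma(2.0, 1.0, n)  # skewed: HPD != central interval
            x = np.sort(draws)
            k = math.ceil(0.9 * n)
            widths = [x[i + k - 1] - x[i] for i in range(n - k + 1)]
            i = int(np.argmin(widths))
            assert hpd_interval(draws, 0.9) == (x[i], x[i + k - 1])

    def test_shorter_than_central_interval_on_skewed_draws(self, rng):
        draws = rng.gamma(1.5, 1.0, 5000)
        low, high = hpd_interval(draws, 0.95)
        qlow, qhigh = np.quantile(draws, [0.025, 0.975])
        assert (high - low) <= (qhigh - qlow) + 1e-12

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(10), 0.95)


class TestMcse:
    def test_iid_limit(self):
        rng = np.random.Generator(np.random.PCG64(13))
        x = rng.normal(size=10_000)
        assert mcse(x) == pytest.approx(0.01, rel=0.15)

    def test_ar1_inflation(self):
        n, rho = 50_000, 0.9
        x = ar1_chain(rho, n, seed=14)
        expected = np.std(x, ddof=1) * math.sqrt((1 + rho) / ((1 - rho) * n))
        assert mcse(x) == pytest.approx(expected, rel=0.15)

    def test_constant_chain_is_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mcse(np.full(100, 1.0)) == 0.0


class TestChainSet:
    def test_csv_roundtrip(self, tmp_path, small_fit):
        path = tmp_path / "chains.csv"
        chains = small_fit["chains"]
        chains.to_csv(path)
        again = ChainSet.from_csv(path)
        assert again.names == chains.names
        np.testing.assert_allclose(again.draws, chains.draws, atol=1e-12)

    def test_combined_length_is_chains_times_keep(self, small_fit):
        chains = small_fit["chains"]
        combined = chains.combined("gamma")
        assert combined.shape == (chains.n_chains * chains.n_keep,)

    def test_chainset_diagnostic_wrappers(self, small_fit):
        chains = small_fit["chains"]
        assert chainset_ess(chains, "gamma") > 1
        assert chainset_rhat(chains, "gamma") > 0.9
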