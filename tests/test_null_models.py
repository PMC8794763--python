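import math

import numpy as np
import pytest

import ahmbench as ab
from ahmbench.null_models import sequential_update
from ahmbench.records import record_median


class TestPersistence:
    def test_mean_is_last_observation(self, tiny_abundance):
        rec = ab.persistence_forecast(tiny_abundance)
        assert rec.mean == 7.1  # bit-exact
        assert rec.target_year == 2003
        assert rec.family == "normal"

    def test_sigma_is_sample_sd_of_differences(self, tiny_abundance):
        rec = ab.persistence_forecast(tiny_abundance)
        assert rec.sd == pytest.approx(np.std([1.2, 0.9], ddof=1), abs=1e-12)

    def test_constant_history(self):
        h = ab.AbundanceSeries(np.array([2000, 2001, 2002]), np.array([6.0, 6.0, 6.0]))
        rec = ab.persistence_forecast(h)
        assert rec.mean == 6.0 and rec.sd == 0.0

    def test_single_difference_uses_absolute_value(self):
        h = ab.AbundanceSeries(np.array([2000, 2001]), np.array([6.0, 5.2]))
        rec = ab.persistence_forecast(h)
        assert rec.sd == pytest.approx(0.8)

    def test_too_short_history(self):
        h = ab.AbundanceSeries(np.array([2000]), np.array([6.0]))
        with pytest.raises(ValueError, match=">= 2 years"):
            ab.persistence_forecast(h)


def _series_from_growth(w_std, beta, sigma, seed=None, n0=8.0):
    """Abundance series whose log growth is beta * W_std (+ noise)."""
    rng = np.random.default_rng(seed)
    eps = rng.normal(0, sigma, len(w_std)) if sigma > 0 else np.zeros(len(w_std))
    logn = np.concatenate([[math.log(n0)], math.log(n0) + np.cumsum(beta * w_std + eps)])
    years = np.arange(2000, 2000 + len(logn))
    return ab.AbundanceSeries(years, np.exp(logn))


def _wstd(values, start=2000):
    values = np.asarray(values, dtype=float)
    return ab.StandardizedWetlandSeries(np.arange(start, start + len(values)), values,
                                        np.zeros(len(values)) + 1.0, np.ones(len(values)),
                                        mode="fixed")


class TestWetlandFit:
    def test_noise_free_recovery(self):
        w = np.array([-1.2, 0.4, 1.1, -0.3, 0.8, -0.9, 0.2, 1.5])
        n = _series_from_growth(w, beta=0.1, sigma=0.0)
        post = ab.fit_wetland_model(n, _wstd(w), ab.NIGPrior(v0=1e8, b0=1e-12))
        # regression through the origin on exact data: slope recovered, residual -> 0
        assert post.beta_mean == pytest.approx(0.1, abs=1e-6)
        assert post.sigma2_mean < 1e-9

    def test_matches_least_squares_through_origin(self):
        """Vague-prior posterior mean equals the OLS through-origin slope."""
        import statsmodels.api as sm
        w = np.array([-1.2, 0.4, 1.1, -0.3, 0.8, -0.9, 0.2, 1.5, -0.6, 0.1])
        n = _series_from_growth(w, beta=0.08, sigma=0.05, seed=5)
        x, y = ab.null_models.growth_observations(n, _wstd(w))
        post = ab.fit_wetland_model(n, _wstd(w), ab.NIGPrior(v0=1e10))
        ols = sm.OLS(y, x).fit()
        assert post.beta_mean == pytest.approx(ols.params[0], abs=1e-8)

    def test_zero_signal_shrinks_to_zero(self):
        w = np.array([-1.0, 0.5, 1.2, -0.7, 0.3])
        n = ab.AbundanceSeries(np.arange(2000, 2006), np.full(6, 8.0))  # all lambda = 1
        post = ab.fit_wetland_model(n, _wstd(w))
        assert post.beta_mean == pytest.approx(0.0, abs=1e-15)

    def test_parameter_recovery_within_two_posterior_sd(self):
        rng_w = np.random.default_rng(98)
        w = rng_w.normal(0, 1, 100)
        n = _series_from_growth(w, beta=0.1, sigma=0.05, seed=99)
        post = ab.fit_wetland_model(n, _wstd(w))
        assert abs(post.beta_mean - 0.1) < 2 * post.beta_sd

    def test_minimum_observations(self):
        w = np.array([0.1, -0.2])
        n = _series_from_growth(w, beta=0.1, sigma=0.0)
        with pytest.raises(ValueError, match=">= 3 growth"):
            ab.fit_wetland_model(n, _wstd(w))

    def test_batch_equals_sequential_conjugate_updates(self):
        """Conjugacy: one batch fit == sequential chunk updates, to 1e-10."""
        rng = np.random.default_rng(7)
        w = rng.normal(0, 1, 30)
        n = _series_from_growth(w, beta=0.1, sigma=0.05, seed=7)
        x, y = ab.null_models.growth_observations(n, _wstd(w))
        prior = ab.NIGPrior()
        batch = ab.null_models._conjugate_update(prior, x, y, len(x))
        seq = ab.null_models._conjugate_update(prior, x[:10], y[:10], 10)
        seq = sequential_update(seq, x[10:21], y[10:21])
        seq = sequential_update(seq, x[21:], y[21:])
        for attr in ("m", "v", "a", "b"):
            assert getattr(seq, attr) == pytest.approx(getattr(batch, attr), abs=1e-10)


class TestWetlandForecast:
    def test_beta_pinned_to_zero_reduces_to_persistence_median(self, tiny_abundance):
        post = ab.WetlandModelPosterior(m=0.0, v=1e-12, a=5.0, b=0.01, n_obs=10)
        rec = ab.wetland_forecast(post, 7.1, w_std_t=1.3, year=2002)
        pers = ab.persistence_forecast(tiny_abundance)
        assert record_median(rec) == pytest.approx(pers.mean, rel=1e-12)

    def test_deterministic_limit(self):
        # beta-hat = 0.1, sigma -> 0, df large: median = N * exp(0.1 * W)
        post = ab.WetlandModelPosterior(m=0.1, v=1e-16, a=1e6, b=1e-10, n_obs=50)
        rec = ab.wetland_forecast(post, 8.0, w_std_t=1.0, year=2002)
        assert record_median(rec) == pytest.approx(8.0 * math.exp(0.1), rel=1e-9)
        assert rec.sd < 1e-3

    def test_moments_match_posterior_predictive_draws(self):
        """Stored mean/sd agree with 100k Student-t posterior-predictive draws."""
        post = ab.WetlandModelPosterior(m=0.08, v=0.002, a=20.0, b=0.05, n_obs=40)
        rec = ab.wetland_forecast(post, 8.0, w_std_t=0.7, year=2002)
        rng = np.random.default_rng(11)
        draws = np.exp(rec.params["loc"]
                       + rec.params["scale"] * rng.standard_t(rec.params["df"], 100_000))
        se_mean = draws.std(ddof=1) / math.sqrt(len(draws))
        assert rec.mean == pytest.approx(draws.mean(), abs=3 * se_mean)
        se_sd = draws.std(ddof=1) / math.sqrt(2 * (len(draws) - 1)) * 2.0  # heavy-tail slack
        assert rec.sd == pytest.approx(draws.std(ddof=1), abs=3 * se_sd)

    def test_predictive_median_equals_persistence_for_all_t(self, sarw_bundle):
        """beta fixed at 0 makes the wetland null a lognormal random walk whose
        median tracks the last observation, i.e. the persistence mean."""
        obs = sarw_bundle.observed
        post = ab.WetlandModelPosterior(m=0.0, v=1e-14, a=10.0, b=0.05, n_obs=20)
        for y in range(1990, 2000):
            hist = obs.truncate(y)
            rec = ab.wetland_forecast(post, hist.value_at(y), 0.4, year=y)
            pers = ab.persistence_forecast(hist)
            assert record_median(rec) == pytest.approx(pers.mean, rel=1e-12)
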