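"""Hierarchical Bayesian model machinery: likelihoods, init, MCMC, P-scores."""

import math

import numpy as np
import pytest
from scipy import stats

import vfprog as vf
from vfprog import bayes

from conftest import make_series


class TestLogLikelihood:
    def test_censored_at_symmetric_tail(self):
        # y recorded at the floor with mu exactly at the floor: P(Y* <= 0) = 1/2
        assert bayes.log_likelihood("hi_censored", 0.0, 0.0, 1.0) == pytest.approx(
            math.log(0.5)
        )

    def test_gaussian_mode(self):
        assert bayes.log_likelihood("hi_linear", 3.0, 3.0, 2.0) == pytest.approx(
            -math.log(2 * math.sqrt(2 * math.pi))
        )

    def test_censored_tail_probability(self):
        # independent high-precision oracle for log Phi(-2.5)
        oracle = stats.norm.logcdf(-2.5)
        assert oracle == pytest.approx(-5.0816483, abs=1e-6)
        assert bayes.log_likelihood("hi_censored", 0.0, 5.0, 2.0) == pytest.approx(
            oracle
        )

    def test_linear_treats_zero_as_value(self):
        # the uncensored variant scores a 0 dB record as a plain observation
        got = bayes.log_likelihood("hi_linear", 0.0, 5.0, 2.0)
        assert got == pytest.approx(stats.norm.logpdf(0.0, 5.0, 2.0))

    def test_hsk_sd_from_variability_model(self, var_model):
        mu = 30.0
        want = bayes.log_likelihood(
            "hi_censored", 28.0, mu, float(var_model.sd(mu))
        )
        got = bayes.log_likelihood("hi_hsk", 28.0, mu, variability=var_model)
        assert got == pytest.approx(want)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            bayes.log_likelihood("hi_linear", 0.0, 0.0, 0.0)


class TestPScore:
    def test_all_negative_is_one(self):
        assert bayes.pscore([-0.1, -2.0, -0.5]) == 1.0

    def test_half_weight_ties(self):
        assert bayes.pscore([-1.0, -1.0, 1.0, 1.0]) == 0.5
        assert bayes.pscore([0.0, 0.0]) == 0.5

    def test_symmetric_draws(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1, 20000)
        assert bayes.pscore(np.concatenate([d, -d])) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bayes.pscore([])


class TestMLInitialise:
    def test_shared_negative_slope(self, grid):
        vals = np.clip(np.array([np.full(54, 35 - i) for i in range(8)]), 0, 50)
        init = bayes.ml_initialise(make_series(vals))
        assert init.beta1 == pytest.approx(-1.0, abs=1e-9)
        assert init.beta0 == pytest.approx(35.0, abs=1e-9)

    def test_flat_series(self):
        vals = np.full((6, 54), 30)
        init = bayes.ml_initialise(make_series(vals))
        assert init.beta0 == pytest.approx(30.0)
        assert init.beta1 == pytest.approx(0.0)

    def test_matches_mixed_model_oracle(self, grid, one_eye):
        """Balanced design: pooled fixed effects equal the ML mixed-model
        estimates (independent statsmodels fit with per-location random
        lines)."""
        import pandas as pd
        import statsmodels.formula.api as smf

        init = bayes.ml_initialise(one_eye)
        Y = one_eye.values[:, grid.informative].astype(float)
        n, L = Y.shape
        df = pd.DataFrame(
            {
                "y": Y.ravel(),
                "t": np.repeat(one_eye.times, L),
                "loc": np.tile(np.arange(L), n),
            }
        )
        md = smf.mixedlm("y ~ t", df, groups="loc", re_formula="~t").fit()
        assert init.beta0 == pytest.approx(md.params["Intercept"], abs=0.05)
        assert init.beta1 == pytest.approx(md.params["t"], abs=0.02)

    def test_too_few_tests(self, one_eye):
        with pytest.raises(ValueError):
            bayes.ml_initialise(one_eye.truncate(1))


class TestSplitRhat:
    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (4, 400, 5)) + rng.normal(0, 0.2, (4, 1, 5))
        ours = bayes.split_rhat(x)
        theirs = np.array(
            [az.rhat(x[:, :, j][None].squeeze(0), method="split") for j in range(5)]
        )
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_diverged_chains_flagged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (2, 200, 1))
        x[1] += 5.0
        assert bayes.split_rhat(x)[0] > 2.0


class TestModelSpec:
    def test_hsk_requires_variability(self):
        with pytest.raises(ValueError, match="VariabilityModel"):
            vf.ModelSpec(variant="hi_hsk")

    def test_two_chains_minimum(self):
        with pytest.raises(ValueError, match="chains"):
            vf.ModelSpec(n_chains=1)


@pytest.fixture(scope="module")
def censored_fit(one_eye, fast_mcmc):
    return bayes.fit(one_eye, vf.ModelSpec(variant="hi_censored", seed=3,
                                           **fast_mcmc))


class TestFit:
    def test_converges_with_full_diagnostics(self, censored_fit):
        assert censored_fit.converged
        assert censored_fit.max_rhat <= 1.2
        # every monitored parameter carries a diagnostic: 118 coefficients,
        # 3 + 3 covariance components, residual SD
        assert len(censored_fit.rhat) == 118 + 6 + 1

    def test_slope_draw_shapes(self, censored_fit):
        n = censored_fit.beta.shape[0] * censored_fit.beta.shape[1]
        assert censored_fit.global_slope_draws.shape == (n,)
        assert censored_fit.cluster_slope_draws.shape == (n, 6)
        assert censored_fit.location_slope_draws.shape == (n, 52)
        ps = censored_fit.pscores()
        assert 0 <= ps.global_ <= 1
        assert ps.cluster.shape == (6,) and ps.location.shape == (52,)

    def test_reproducible_from_seed(self, one_eye, fast_mcmc):
        spec = vf.ModelSpec(variant="hi_censored", seed=9, **fast_mcmc)
        f1 = bayes.fit(one_eye, spec)
        f2 = bayes.fit(one_eye, spec)
        assert np.array_equal(f1.beta, f2.beta)

    def test_requires_two_tests(self, one_eye, fast_mcmc):
        with pytest.raises(ValueError):
            bayes.fit(one_eye.truncate(1), vf.ModelSpec(**fast_mcmc))

    def test_censored_less_biased_than_linear_on_floored_series(
        self, grid, var_model, fast_mcmc
    ):
        """Deep damage with a trailing run of 0 dB: ignoring censoring drags
        the slope towards zero (positive bias); the censored model does not."""
        rng = np.random.default_rng(41)
        t = np.linspace(0, 9, 10)
        true_slope = -2.0
        lat = 12 + true_slope * t[:, None] + rng.normal(0, 1.5, (10, 54))
        vals = np.clip(np.round(lat), 0, 50)
        s = make_series(vals, times=t)
        assert (s.values == 0).mean() > 0.2
        f_lin = bayes.fit(s, vf.ModelSpec(variant="hi_linear", seed=1, **fast_mcmc))
        f_cen = bayes.fit(s, vf.ModelSpec(variant="hi_censored", seed=1, **fast_mcmc))
        b_lin = f_lin.global_slope_draws.mean() - true_slope
        b_cen = f_cen.global_slope_draws.mean() - true_slope
        assert b_lin > 0.3  # noticeably biased towards stability
        assert abs(b_cen) < b_lin

    def test_hsk_equals_censored_under_constant_sd(self, one_eye, fast_mcmc):
        """With a constant-SD variability model pinned at the censored fit's
        residual SD, the heteroskedastic model is the censored model."""
        f_cen = bayes.fit(
            one_eye, vf.ModelSpec(variant="hi_censored", seed=5, **fast_mcmc)
        )
        sig = float(np.nanmean(f_cen.sigma))
        const = vf.VariabilityModel(b0=math.log(sig), b1=0.0, breakpoint=0.0)
        f_hsk = bayes.fit(
            one_eye,
            vf.ModelSpec(variant="hi_hsk", variability=const, seed=5, **fast_mcmc),
        )
        assert f_hsk.global_slope_draws.mean() == pytest.approx(
            f_cen.global_slope_draws.mean(), abs=0.06
        )
        assert f_hsk.pscores().global_ == pytest.approx(
            f_cen.pscores().global_, abs=0.08
        )

    def test_shrinkage_of_location_slopes(self, grid, fast_mcmc):
        """Posterior location slopes are pulled towards the global trend:
        their spread is smaller than that of raw per-location OLS slopes."""
        rng = np.random.default_rng(43)
        t = np.linspace(0, 6, 7)
        lat = 28 - 0.3 * t[:, None] + rng.normal(0, 3.0, (7, 54))
        s = make_series(np.clip(np.round(lat), 0, 50), times=t)
        f = bayes.fit(s, vf.ModelSpec(variant="hi_censored", seed=7, **fast_mcmc))
        post = f.location_slope_draws.mean(axis=0)
        Y = s.values[:, grid.informative].astype(float)
        tc = t - t.mean()
        ols = tc @ Y / (tc @ tc)
        assert post.std() < 0.8 * ols.std()


class TestPredict:
    def test_flat_series_predicts_flat(self, fast_mcmc):
        vals = np.full((6, 54), 30)
        f = bayes.fit(
            make_series(vals), vf.ModelSpec(variant="hi_linear", seed=2, **fast_mcmc)
        )
        pred = f.predict([7.0, 10.0])
        assert pred.shape == (2, 52)
        assert pred == pytest.approx(30.0, abs=0.5)

    def test_steep_decline_clamped_to_floor(self, fast_mcmc):
        vals = np.clip(np.array([np.full(54, 20 - 3 * i) for i in range(6)]), 0, 50)
        f = bayes.fit(
            make_series(vals),
            vf.ModelSpec(variant="hi_censored", seed=2, **fast_mcmc),
        )
        assert np.all(f.predict([40.0]) == 0.0)

    def test_mean_time_prediction_matches_fitted_mean(self, grid, fast_mcmc):
        """For the uncensored model the fitted line passes through the data
        centroid, so the prediction at the mean observation time is the mean
        observation (the OLS projection property)."""
        rng = np.random.default_rng(47)
        t = np.linspace(0, 5, 8)
        lat = 27 - 0.4 * t[:, None] + rng.normal(0, 2.0, (8, 54))
        s = make_series(np.clip(np.round(lat), 1, 50), times=t)
        f = bayes.fit(s, vf.ModelSpec(variant="hi_linear", seed=4, **fast_mcmc))
        pred = f.predict([t.mean()])[0]
        y_mean = s.values[:, grid.informative].astype(float).mean()
        assert pred.mean() == pytest.approx(y_mean, abs=0.25)

    def test_times_before_baseline_rejected(self, one_eye, fast_mcmc):
        f = bayes.fit(one_eye, vf.ModelSpec(variant="hi_linear", seed=2, **fast_mcmc))
        with pytest.raises(ValueError):
            f.predict([-1.0])
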