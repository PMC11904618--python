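"""DRAM sampler, likelihood, conjugate variance updates, ESS and predictive
bands, validated on injected targets with known answers."""

import numpy as np
import pytest

import pkident as pk
from pkident.sampling import (
    BayesianCalibration,
    Chain,
    LikelihoodSpec,
    PriorSpec,
    dram_sample,
    effective_sample_size,
    log_posterior,
    posterior_predictive,
    update_error_variance,
)
from pkident.synthdata import convert_units, generate_synthetic


class TestLogPosterior:
    def _spec(self, onecomp, grid, values):
        return LikelihoodSpec(
            times=grid.times, values=values, model=onecomp,
            sample_names=["F", "CL"], sigma2=1.0, grid=grid,
        )

    def test_outside_prior_support_is_minus_inf(self, onecomp, grid):
        truth = pk.solve_model(onecomp, None, grid).response
        spec = self._spec(onecomp, grid, truth)
        priors = PriorSpec.from_model(onecomp, ["F", "CL"])
        assert log_posterior(np.array([1.5, 0.2]), spec, priors, 1.0) == -np.inf

    def test_zero_residuals_gaussian_constant(self, onecomp, grid):
        truth = pk.solve_model(onecomp, None, grid).response
        spec = self._spec(onecomp, grid, truth)
        priors = PriorSpec.from_model(onecomp, ["F", "CL"])
        lp = log_posterior(np.array([0.7, 0.2]), spec, priors, 1.0)
        n = truth.size
        assert lp == pytest.approx(-0.5 * n * np.log(2 * np.pi), rel=1e-12)

    def test_hand_set_residuals(self, onecomp):
        # residuals (1, -1, 2) with sigma^2 = 1: loglik = -(3/2)log(2pi) - 3
        g = pk.TimeGrid(0, 10, 3)
        truth = pk.solve_model(onecomp, None, g).response
        spec = LikelihoodSpec(
            times=g.times, values=truth + np.array([1.0, -1.0, 2.0]),
            model=onecomp, sample_names=["F", "CL"], sigma2=1.0, grid=g,
        )
        priors = PriorSpec.from_model(onecomp, ["F", "CL"])
        lp = log_posterior(np.array([0.7, 0.2]), spec, priors, 1.0)
        assert lp == pytest.approx(-1.5 * np.log(2 * np.pi) - 3.0, rel=1e-12)

    def test_nonpositive_sigma2_rejected(self, onecomp, grid):
        truth = pk.solve_model(onecomp, None, grid).response
        spec = self._spec(onecomp, grid, truth)
        priors = PriorSpec.from_model(onecomp, ["F", "CL"])
        with pytest.raises(ValueError):
            log_posterior(np.array([0.7, 0.2]), spec, priors, 0.0)


class TestDramOnInjectedTargets:
    def test_flat_likelihood_reduces_to_prior_sampling(self):
        # constant log-density on (0, 1): the post-burn-in marginal is uniform
        from scipy.stats import ks_2samp

        priors = PriorSpec(names=["u"], lows=np.array([0.0]), highs=np.array([1.0]))
        chain = dram_sample(lambda th: 0.0, priors, 60_000,
                            np.array([0.5]), seed=10)
        post = chain.post_burn_in[::20, 0]  # thin to near-independence
        ref = np.random.default_rng(11).uniform(size=post.size)
        assert ks_2samp(post, ref).pvalue > 0.01

    def test_two_state_target_frequencies(self):
        # piecewise-constant density on (0,2): P(x<1) = 0.3
        def logp(th):
            x = th[0]
            if not 0.0 < x < 2.0:
                return -np.inf
            return np.log(0.3 if x < 1.0 else 0.7)

        chain = dram_sample(logp, None, 100_000, np.array([0.5]), seed=12,
                            cov0=np.array([[0.25]]))
        post = chain.post_burn_in[:, 0]
        freq = np.mean(post < 1.0)
        ess = effective_sample_size((post < 1.0).astype(float))
        assert abs(freq - 0.3) < 3 * np.sqrt(0.3 * 0.7 / ess)

    def test_seed_determinism_bitwise(self, onecomp, grid):
        ds = generate_synthetic(onecomp, grid=grid, noise_fraction=0.02, seed=3)
        spec = LikelihoodSpec(times=ds.times, values=ds.values, model=onecomp,
                              sample_names=["F", "CL"], grid=grid)
        runs = [
            dram_sample(spec, None, 2_000, np.array([0.7, 0.2]), seed=42)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].samples, runs[1].samples)
        assert np.array_equal(runs[0].sigma2, runs[1].sigma2)

    def test_init_outside_support_rejected(self):
        priors = PriorSpec(names=["u"], lows=np.array([0.0]), highs=np.array([1.0]))
        with pytest.raises(ValueError, match="zero posterior density"):
            dram_sample(lambda th: 0.0, priors, 100, np.array([2.0]), seed=0)

    def test_bad_cov0_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            dram_sample(lambda th: -0.5 * float(th @ th), None, 100,
                        np.zeros(2), cov0=np.array([[1.0, 2.0], [2.0, 1.0]]),
                        seed=0)


class TestErrorVarianceUpdate:
    def test_noninformative_mean(self):
        rng = np.random.default_rng(4)
        n, ss = 20, 50.0
        draws = np.array([
            update_error_variance(ss, n, rng=rng) for _ in range(100_000)
        ])
        assert np.mean(draws) == pytest.approx(ss / (n - 2), rel=0.03)

    def test_no_data_recovers_prior(self):
        # with no observations and zero residual, the draw is the prior
        rng = np.random.default_rng(5)
        n0, s02 = 6.0, 2.0
        draws = np.array([
            update_error_variance(0.0, 0, n0=n0, s02=s02, rng=rng)
            for _ in range(100_000)
        ])
        # InvGamma(n0/2, n0 s02/2) has mean n0 s02 / (n0 - 2)
        assert np.mean(draws) == pytest.approx(n0 * s02 / (n0 - 2), rel=0.03)

    def test_draws_strictly_positive(self):
        rng = np.random.default_rng(6)
        draws = [update_error_variance(1e-12, 5, rng=rng) for _ in range(1000)]
        assert min(draws) > 0.0


class TestEffectiveSampleSize:
    def test_iid_series(self):
        x = np.random.default_rng(7).standard_normal(10_000)
        assert effective_sample_size(x) == pytest.approx(10_000, rel=0.15)

    def test_constant_series_flags_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert effective_sample_size(np.ones(100)) == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            effective_sample_size(np.arange(5))

    def test_cross_check_against_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        rho, M = 0.8, 50_000
        e = rng.standard_normal(M)
        x = np.empty(M)
        x[0] = e[0]
        for i in range(1, M):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * e[i]
        ours = effective_sample_size(x)
        theirs = float(arviz.ess(x))
        assert ours == pytest.approx(theirs, rel=0.25)


class TestPosteriorPredictive:
    def test_degenerate_chain_collapses_bands(self, onecomp, grid):
        theta = np.array([0.7, 0.2])
        truth = pk.solve_model(onecomp, None, grid).response
        spec = LikelihoodSpec(times=grid.times, values=truth, model=onecomp,
                              sample_names=["F", "CL"], grid=grid)
        chain = Chain(
            samples=np.tile(theta, (500, 1)), sigma2=np.zeros(500),
            accepted_stage1=0, accepted_stage2=0, burn_in=0, rng_seed=0,
            param_names=["F", "CL"],
        )
        bands = posterior_predictive(chain, spec, grid, n_draws=100, seed=0)
        for arr in (bands.credible_lower, bands.credible_upper,
                    bands.prediction_lower, bands.prediction_upper):
            assert np.allclose(arr, truth, rtol=0, atol=1e-14)

    def test_prediction_band_contains_credible_band(self, recovery_run):
        bands = recovery_run.results.posterior_predictive(seed=1, n_draws=500)
        assert np.all(bands.prediction_lower <= bands.credible_lower)
        assert np.all(bands.prediction_upper >= bands.credible_upper)

    def test_oversampling_warns(self, recovery_run):
        with pytest.warns(UserWarning, match="replacement"):
            recovery_run.results.posterior_predictive(
                n_draws=100_000, seed=2, noise_replicates=1
            )


class TestUnitConversionAgreement:
    def test_posterior_means_agree_across_unit_scales(self, onecomp, grid):
        # calibrating on the raw molar-like scale and on a 1e9-converted scale
        # must give the same posterior means up to Monte-Carlo error
        ds = generate_synthetic(onecomp, grid=grid, noise_fraction=0.02, seed=21)
        res_raw = BayesianCalibration(
            ds.values, ds.times, onecomp, ["F", "CL"], grid=grid
        ).fit(draws=15_000, seed=22)
        scaled = convert_units(ds, 1e9)
        res_scaled = BayesianCalibration(
            scaled.values, scaled.times, onecomp.with_scale(1e9), ["F", "CL"],
            grid=grid,
        ).fit(draws=15_000, seed=23)
        for j in range(2):
            tol = 0.5 * max(res_raw.sd[j], res_scaled.sd[j])
            assert abs(res_raw.params[j] - res_scaled.params[j]) < tol
        # sigma^2 lives on the converted scale
        ratio = res_scaled.sigma2_mean / res_raw.sigma2_mean
        assert ratio == pytest.approx(1e18, rel=0.2)


def test_calibration_summary_contains_diagnostics(recovery_run):
    text = recovery_run.results.summary()
    assert "ESS" in text and "sigma2" in text
    frame = recovery_run.results.summary_frame()
    assert list(frame.columns) == ["mean", "sd", "ESS"]
    assert list(frame.index) == ["F", "CL"]
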