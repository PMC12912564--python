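import math

import numpy as np
import pytest
from scipy import integrate, stats

from memfid.mixture import (
    BayesConfig,
    ErrorSample,
    FitConfig,
    MixtureParams,
    compare_models,
    fit_mixture_bayes,
    fit_mixture_mle,
    fit_no_guessing,
    mixture_logpdf,
    mixture_loglik,
    simulate_errors,
)


def grid_max_loglik(sample, n_p=101, n_k=101, k_lo=0.1, k_hi=100.0):
    """Brute-force maximum of the likelihood over a (p_t, kappa) grid."""
    ps = np.linspace(0.0, 1.0, n_p)
    ks = np.logspace(np.log10(k_lo), np.log10(k_hi), n_k)
    best = -np.inf
    for k in ks:
        lp = mixture_logpdf(sample.errors, 1.0, k)  # log vM density per trial
        vm = np.exp(lp)
        dens = ps[:, None] * vm[None, :] + (1.0 - ps)[:, None] / 360.0
        with np.errstate(divide="ignore"):
            lls = np.sum(np.log(dens), axis=1)
        best = max(best, float(np.nanmax(lls)))
    return best


class TestLoglik:
    def test_pure_uniform(self):
        sample = ErrorSample(np.linspace(-179.0, 180.0, 100))
        ll = mixture_loglik(sample, MixtureParams(0.0, 5.0))
        assert ll == pytest.approx(-100 * math.log(360.0))

    def test_kappa_zero_is_uniform(self):
        sample = ErrorSample(np.array([-90.0, 0.0, 45.0, 180.0]))
        for p in (0.0, 0.4, 1.0):
            ll = mixture_loglik(sample, MixtureParams(p, 0.0))
            assert ll == pytest.approx(-4 * math.log(360.0))

    def test_single_error_density_oracle(self):
        # e^2 / (2 pi I0(2)) per radian, converted per degree, mixed with 1/360
        sample = ErrorSample(np.array([0.0]))
        ll = mixture_loglik(sample, MixtureParams(0.5, 2.0))
        assert ll == pytest.approx(-5.134356950, abs=1e-8)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mixture_loglik(ErrorSample(np.array([])), MixtureParams(0.5, 2.0))

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 10.0, 100.0])
    def test_density_integrates_to_one(self, kappa):
        for p in (0.0, 0.5, 1.0):
            val, err = integrate.quad(
                lambda x: math.exp(mixture_logpdf(np.array([x]), p, kappa)[0]),
                -180.0, 180.0, limit=400, epsabs=1e-12,
            )
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(7)
        errs = rng.uniform(-179.9, 180.0, 250)
        params = MixtureParams(0.6, 9.0)
        assert mixture_loglik(ErrorSample(errs), params) == pytest.approx(
            mixture_loglik(ErrorSample(-errs), params)
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams(1.2, 5.0)
        with pytest.raises(ValueError):
            MixtureParams(0.5, -1.0)


class TestMleFit:
    def test_recovers_group_level_parameters(self):
        """10k trials at published group-level truths: pT +/-0.02, K +/-10%."""
        for p_true, k_true, seed in ((0.73, 13.87, 11), (0.67, 15.63, 12)):
            sample = simulate_errors(MixtureParams(p_true, k_true), 10_000, seed=seed)
            fit = fit_mixture_mle(sample)
            assert fit.converged
            assert abs(fit.params.p_t - p_true) < 0.02
            assert abs(fit.params.kappa - k_true) / k_true < 0.10

    def test_uniform_data_gives_low_pt(self):
        rng = np.random.default_rng(3)
        sample = ErrorSample(rng.uniform(-179.99, 180.0, 5000))
        fit = fit_mixture_mle(sample)
        assert fit.params.p_t <= 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = MixtureParams(rng.uniform(0.2, 0.95), rng.uniform(2.0, 40.0))
        sample = simulate_errors(truth, int(rng.integers(50, 500)), seed=rng)
        fit = fit_mixture_mle(sample)
        assert fit.loglik >= grid_max_loglik(sample) - 1e-6

    def test_refuses_tiny_samples(self):
        with pytest.raises(ValueError):
            fit_mixture_mle(ErrorSample(np.arange(10.0)))

    def test_consistency_bias_shrinks_with_n(self):
        """Mean |bias| of fitted pT decreases monotonically over n."""
        truth = MixtureParams(0.7, 15.0)
        biases = []
        for n in (100, 1000, 10_000):
            errs = []
            for seed in range(50):
                s = simulate_errors(truth, n, seed=1000 + seed)
                errs.append(abs(fit_mixture_mle(s).params.p_t - truth.p_t))
            biases.append(np.mean(errs))
        assert biases[0] > biases[1] > biases[2]


class TestNoGuessing:
    def test_correctly_specified_recovery(self):
        sample = simulate_errors(MixtureParams(1.0, 10.0), 5000, seed=21)
        fit = fit_no_guessing(sample)
        assert abs(fit.params.kappa - 10.0) / 10.0 < 0.10
        assert fit.params.p_t == 1.0

    def test_nested_in_mixture(self):
        sample = simulate_errors(MixtureParams(0.7, 12.0), 1500, seed=22)
        assert fit_mixture_mle(sample).loglik >= fit_no_guessing(sample).loglik

    def test_matches_kappa_grid(self):
        sample = simulate_errors(MixtureParams(1.0, 8.0), 400, seed=23)
        fit = fit_no_guessing(sample)
        grid = np.logspace(-2, 2.5, 2000)
        lls = [
            float(np.sum(mixture_logpdf(sample.errors, 1.0, k))) for k in grid
        ]
        assert fit.loglik >= max(lls) - 1e-6


class TestModelComparison:
    def test_guessing_detected(self):
        sample = simulate_errors(MixtureParams(0.6, 12.0), 2000, seed=31)
        cmp = compare_models(sample)
        assert cmp.preferred == "mixture"
        assert cmp.delta_aic > 2

    def test_parsimony_without_guessing(self):
        sample = simulate_errors(MixtureParams(1.0, 12.0), 2000, seed=32)
        cmp = compare_models(sample)
        assert cmp.preferred == "no_guessing" or cmp.delta_aic <= 2

    def test_mixture_never_fits_worse(self):
        for seed in range(4):
            s = simulate_errors(MixtureParams(0.8, 20.0), 300, seed=40 + seed)
            cmp = compare_models(s)
            assert cmp.mixture.loglik >= cmp.no_guessing.loglik


class TestSimulation:
    def test_point_mass_limit(self):
        s = simulate_errors(MixtureParams(1.0, 10_000.0), 1000, seed=51)
        assert np.all(np.abs(s.errors) < 5.0)

    def test_pure_guessing_is_uniform(self):
        s = simulate_errors(MixtureParams(0.0, 10.0), 5000, seed=52)
        stat = stats.kstest(s.errors, stats.uniform(loc=-180, scale=360).cdf)
        assert stat.pvalue > 0.01

    def test_within_30_matches_analytic_cdf(self):
        p, k = 0.73, 13.87
        s = simulate_errors(MixtureParams(p, k), 100_000, seed=53)
        emp = np.mean(np.abs(s.errors) <= 30.0)
        analytic, _ = integrate.quad(
            lambda x: math.exp(mixture_logpdf(np.array([x]), p, k)[0]), -30.0, 30.0,
            limit=200,
        )
        assert emp == pytest.approx(analytic, abs=0.01)

    def test_range_and_determinism(self):
        a = simulate_errors(MixtureParams(0.5, 5.0), 500, seed=54)
        b = simulate_errors(MixtureParams(0.5, 5.0), 500, seed=54)
        assert np.array_equal(a.errors, b.errors)
        assert np.all(a.errors > -180.0) and np.all(a.errors <= 180.0)
        with pytest.raises(ValueError):
            simulate_errors(MixtureParams(0.5, 5.0), 0)


class TestBayesFit:
    def test_posterior_near_truth_large_n(self):
        s = simulate_errors(MixtureParams(0.67, 15.63), 10_000, seed=61)
        post = fit_mixture_bayes(s, seed=62)
        assert post.converged
        assert abs(post.mean.p_t - 0.67) < 0.03
        assert abs(post.mean.kappa - 15.63) / 15.63 < 0.15
        assert post.ci_low.p_t < post.mean.p_t < post.ci_high.p_t

    def test_pure_uniform_posterior_pt_small(self):
        rng = np.random.default_rng(63)
        s = ErrorSample(rng.uniform(-179.99, 180.0, 2000))
        post = fit_mixture_bayes(s, seed=64)
        assert post.mean.p_t <= 0.1

    def test_agrees_with_mle_asymptotically(self):
        s = simulate_errors(MixtureParams(0.73, 13.87), 10_000, seed=65)
        post = fit_mixture_bayes(s, seed=66)
        mle = fit_mixture_mle(s)
        assert abs(post.mean.p_t - mle.params.p_t) < 0.02
        assert abs(post.mean.kappa - mle.params.kappa) / mle.params.kappa < 0.07
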