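import math

import numpy as np
import pytest
from scipy import stats

from memfid.circular import k_to_sd
from memfid.mixture import ErrorSample, MixtureParams, fit_mixture_mle, simulate_errors
from memfid.semiparametric import guessing_threshold, semiparametric_estimates


class TestGuessingThreshold:
    def test_closed_form_oracle(self):
        # at pT=0.5 the responsibility-0.5 angle satisfies cos(theta) = ln I0(2) / 2
        assert guessing_threshold(MixtureParams(0.5, 2.0)) == pytest.approx(
            65.6696693, abs=1e-5
        )

    def test_no_guessing_mass_gives_180(self):
        assert guessing_threshold(MixtureParams(1.0, 2.0)) == 180.0
        assert guessing_threshold(MixtureParams(0.999999, 2.0)) == 180.0

    def test_cutoff_shrinks_with_concentration(self):
        cuts = [guessing_threshold(MixtureParams(0.6, k)) for k in (2.0, 5.0, 20.0, 80.0)]
        assert all(a > b for a, b in zip(cuts, cuts[1:]))

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            guessing_threshold(MixtureParams(0.0, 5.0))
        with pytest.raises(ValueError):
            guessing_threshold(MixtureParams(0.5, 0.0))

    def test_component_densities_equal_at_cutoff(self):
        from memfid.mixture import mixture_logpdf

        p, k = 0.7, 11.0
        cut = guessing_threshold(MixtureParams(p, k))
        vm = p * math.exp(mixture_logpdf(np.array([cut]), 1.0, k)[0])
        assert vm == pytest.approx((1 - p) / 360.0, rel=1e-8)


class TestEstimates:
    def test_all_within(self):
        s = ErrorSample(np.array([-20.0, 0.0, 15.0]))
        est = semiparametric_estimates(s, 90.0)
        assert est.retrieval == 1.0

    def test_hand_computed_precision(self):
        s = ErrorSample(np.array([-10.0, 0.0, 10.0]))
        est = semiparametric_estimates(s, 90.0)
        assert est.retrieval == 1.0
        assert est.precision == pytest.approx(-10.0)  # sample SD, n-1 denominator
        pop = semiparametric_estimates(s, 90.0, ddof=0)
        assert pop.precision == pytest.approx(-10.0 * math.sqrt(2.0 / 3.0))

    def test_no_within_cutoff_responses(self):
        s = ErrorSample(np.array([120.0, -150.0, 170.0]))
        est = semiparametric_estimates(s, 30.0)
        assert est.retrieval == 0.0
        assert math.isnan(est.precision)

    def test_retrieval_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        s = ErrorSample(rng.uniform(-179.9, 180.0, 400))
        rets = [semiparametric_estimates(s, c).retrieval for c in (10, 45, 90, 150, 180)]
        assert all(a <= b for a, b in zip(rets, rets[1:]))

    def test_invalid_cutoff(self):
        s = ErrorSample(np.array([0.0, 1.0]))
        for bad in (0.0, -5.0, 181.0):
            with pytest.raises(ValueError):
                semiparametric_estimates(s, bad)

    def test_guess_inflation_matches_expected_rate(self):
        """Within-cutoff guesses inflate retrieval by ~ (1-pT) * cutoff/180."""
        p, k = 0.7, 13.87
        cut = guessing_threshold(MixtureParams(p, k))
        s = simulate_errors(MixtureParams(p, k), 100_000, seed=9)
        est = semiparametric_estimates(s, cut)
        assert est.retrieval - p == pytest.approx((1 - p) * cut / 180.0, abs=0.01)


@pytest.fixture(scope="module")
def simulated_subjects():
    rng = np.random.default_rng(17)
    true_pt = np.linspace(0.3, 0.95, 60)
    subjects = []
    for i, p in enumerate(true_pt):
        kappa = float(np.exp(rng.normal(np.log(14.0), 0.3)))
        s = simulate_errors(MixtureParams(float(p), kappa), 75, seed=rng,
                            subject=f"s{i}")
        subjects.append((p, kappa, s))
    return subjects


class TestSubjectRecovery:
    def test_retrieval_tracks_true_pt(self, simulated_subjects):
        pooled = ErrorSample(np.concatenate([s.errors for _, _, s in simulated_subjects]))
        cut = guessing_threshold(fit_mixture_mle(pooled).params)
        est = [semiparametric_estimates(s, cut).retrieval for _, _, s in simulated_subjects]
        rho = stats.spearmanr([p for p, _, _ in simulated_subjects], est).statistic
        assert rho >= 0.8

    def test_precision_rank_agrees_with_mle_route(self, simulated_subjects):
        """Semiparametric precision and -SD(kappa_MLE) order subjects alike."""
        pooled = ErrorSample(np.concatenate([s.errors for _, _, s in simulated_subjects]))
        cut = guessing_threshold(fit_mixture_mle(pooled).params)
        semi, mle = [], []
        for _, _, s in simulated_subjects:
            semi.append(semiparametric_estimates(s, cut).precision)
            fit = fit_mixture_mle(s, config=None)
            mle.append(-k_to_sd(max(fit.params.kappa, 1e-3)))
        rho = stats.spearmanr(semi, mle).statistic
        assert rho >= 0.8
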