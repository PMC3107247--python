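"""Maximum-likelihood fits and chi-square ranking of interval distributions."""

import numpy as np
import pytest
from scipy import stats

from neurotraffic.distfit import (
    DegenerateSampleError,
    InsufficientSampleError,
    chi_square_gof,
    default_n_bins,
    fit_candidates,
    fit_gamma_mle,
    fit_weibull_mle,
    gamma_cv,
    rank_fits,
)
from neurotraffic.synth import generate_gamma_sample


class TestGammaMLE:
    def test_recovers_parameters_and_matches_grid_oracle(self, gamma_oracle):
        sample = generate_gamma_sample(3.0, 15.0, 10_000, seed=7)
        fit = fit_gamma_mle(sample)
        assert 2.85 <= fit.shape <= 3.15
        assert 13.9 <= fit.scale <= 16.1
        k_o, theta_o = gamma_oracle(sample.intervals)
        assert fit.shape == pytest.approx(k_o, rel=2e-3)
        assert fit.scale == pytest.approx(theta_o, rel=2e-3)

    def test_matches_scipy_reference(self):
        sample = generate_gamma_sample(2.2, 8.0, 5_000, seed=3)
        fit = fit_gamma_mle(sample)
        k_ref, _, theta_ref = stats.gamma.fit(sample.intervals, floc=0)
        assert fit.shape == pytest.approx(k_ref, rel=1e-6)
        assert fit.scale == pytest.approx(theta_ref, rel=1e-6)

    def test_exponential_data_gives_unit_shape(self):
        rng = np.random.default_rng(11)
        fit = fit_gamma_mle(rng.exponential(20.0, 10_000))
        assert 0.95 <= fit.shape <= 1.05

    def test_zero_variance_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            fit_gamma_mle(np.full(100, 5.0))

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            fit_gamma_mle(np.array([1.0, 2.0, 3.0]))

    def test_loglik_is_stationary_at_estimate(self):
        """The profile-likelihood solution zeroes the score (MLE condition)."""
        from scipy.special import digamma

        sample = generate_gamma_sample(4.0, 2.0, 2_000, seed=5)
        x = sample.intervals
        fit = fit_gamma_mle(sample)
        k, th = fit.shape, fit.scale
        dk = np.sum(np.log(x)) - x.size * (np.log(th) + digamma(k))
        dth = np.sum(x) / th**2 - x.size * k / th
        assert abs(dk) / x.size < 1e-6
        assert abs(dth) / x.size < 1e-6

    @pytest.mark.parametrize("c", [0.1, 3.0, 1000.0])
    def test_scale_equivariance(self, c):
        sample = generate_gamma_sample(2.5, 7.0, 2_000, seed=9)
        f1 = fit_gamma_mle(sample.intervals)
        f2 = fit_gamma_mle(c * sample.intervals)
        assert f2.shape == pytest.approx(f1.shape, rel=1e-6)
        assert f2.scale == pytest.approx(c * f1.scale, rel=1e-6)

    def test_shape_bias_small_at_n2000(self):
        """Mean shape estimate over 200 replicates is within 3% of truth."""
        ests = [
            fit_gamma_mle(generate_gamma_sample(3.0, 15.0, 2_000, seed=s)).shape
            for s in range(200)
        ]
        assert abs(np.mean(ests) - 3.0) < 0.09


class TestGammaCV:
    @pytest.mark.parametrize("shape, cv", [(4.0, 0.5), (1.0, 1.0), (9.0, 1 / 3)])
    def test_closed_form(self, shape, cv):
        assert gamma_cv(shape) == pytest.approx(cv)

    def test_fit_carries_cv(self):
        fit = fit_gamma_mle(generate_gamma_sample(4.0, 1.0, 1_000, seed=1))
        assert fit.cv == pytest.approx(fit.shape ** -0.5, abs=1e-12)

    def test_monte_carlo_agreement(self):
        draws = np.random.default_rng(2).gamma(4.0, 1.0, 100_000)
        emp = draws.std() / draws.mean()
        assert emp == pytest.approx(gamma_cv(4.0), rel=0.02)


class TestWeibull:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(13)
        x = 10.0 * rng.weibull(2.0, 10_000)
        fit = fit_weibull_mle(x)
        assert 1.9 <= fit.params[0] <= 2.1
        assert fit.params[1] == pytest.approx(10.0, rel=0.05)

    def test_exponential_special_case(self):
        rng = np.random.default_rng(17)
        fit = fit_weibull_mle(rng.exponential(5.0, 10_000))
        assert fit.params[0] == pytest.approx(1.0, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSampleError):
            fit_weibull_mle(np.full(50, 2.0))


class TestChiSquare:
    def test_perfect_agreement_scores_zero(self):
        fit = fit_gamma_mle(generate_gamma_sample(3.0, 15.0, 1_000, seed=21))
        # a sample placed exactly at equiprobable-quantile midpoints
        n_bins = 10
        ideal = fit.ppf((np.arange(1_000) + 0.5) / 1_000)
        res = chi_square_gof(ideal, fit, n_bins=n_bins)
        assert res.statistic == 0.0
        assert res.degrees_of_freedom == n_bins - 1 - 2

    def test_calibrated_under_true_model(self):
        """Fitting the generating family rarely rejects at the 1% level."""
        ok = 0
        for s in range(100):
            sample = generate_gamma_sample(3.0, 15.0, 5_000, seed=100 + s)
            fit = fit_gamma_mle(sample)
            if chi_square_gof(sample, fit).p_value > 0.01:
                ok += 1
        assert ok >= 95

    def test_misfit_scores_higher(self):
        sample = generate_gamma_sample(3.0, 15.0, 5_000, seed=31)
        fits = {f.name: f for f in fit_candidates(sample, ("gamma", "normal"))}
        g = chi_square_gof(sample, fits["gamma"]).statistic
        n = chi_square_gof(sample, fits["normal"]).statistic
        assert n > g

    def test_too_many_bins_rejected(self):
        sample = generate_gamma_sample(3.0, 15.0, 100, seed=41)
        fit = fit_gamma_mle(sample)
        with pytest.raises(ValueError, match="fewer bins"):
            chi_square_gof(sample, fit, n_bins=200)

    def test_default_bin_rule(self):
        assert default_n_bins(100) == 6
        assert default_n_bins(1_000) == 20
        assert default_n_bins(10_000) == 50


class TestRankFits:
    def test_gamma_ranks_first_on_gamma_data(self):
        sample = generate_gamma_sample(3.0, 15.0, 5_000, seed=51)
        ranked = rank_fits(sample, fit_candidates(sample, ("gamma", "weibull", "normal")))
        assert ranked[0][0].name == "gamma"

    @pytest.mark.parametrize("n_bins", [10, 20, 30])
    def test_ranking_stable_across_bin_counts(self, n_bins):
        sample = generate_gamma_sample(3.0, 15.0, 5_000, seed=53)
        ranked = rank_fits(
            sample, fit_candidates(sample, ("gamma", "weibull", "normal")),
            n_bins=n_bins,
        )
        assert ranked[0][0].name == "gamma"

    def test_single_candidate(self):
        sample = generate_gamma_sample(3.0, 15.0, 1_000, seed=55)
        fit = fit_gamma_mle(sample)
        assert rank_fits(sample, [fit])[0][0] is fit

    def test_duplicate_candidates_tie_break_deterministic(self):
        sample = generate_gamma_sample(3.0, 15.0, 1_000, seed=57)
        fit = fit_gamma_mle(sample)
        r1 = rank_fits(sample, [fit, fit])
        r2 = rank_fits(sample, [fit, fit])
        assert [f.name for f, _ in r1] == [f.name for f, _ in r2]
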