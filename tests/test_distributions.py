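"""Tests of Gamma-mixture densities, KL fitting and modality selection."""

import numpy as np
import pytest
from scipy import integrate, optimize
from scipy.stats import gamma as gamma_dist

from branchdyn import (FitOptions, GammaComponent, GammaMixtureFit, fit_mixture,
                       kl_divergence, mixture_pdf, mixture_stats,
                       sample_gamma_mixture, select_modality)
from branchdyn.distributions import mixture_cdf
from branchdyn.errors import DegenerateDataError, InvalidParameterError
from branchdyn.windows import EmpiricalDistribution, empirical_distribution


def _fit(*comps):
    return GammaMixtureFit([GammaComponent(*c) for c in comps])


class TestMixturePdf:
    def test_exponential_at_origin(self):
        assert mixture_pdf(0.0, _fit((1.0, 1.0, 1.0, 0.0)))[0] == pytest.approx(1.0)

    def test_mode_of_shifted_branch_point_component(self):
        # unimodal branch-point law: mode at loc + (shape-1)/rate
        fit = _fit((1.0, 2.898, 1.5106, 15.481))
        grid = np.linspace(15.481, 40, 200_001)
        mode = grid[np.argmax(mixture_pdf(grid, fit))]
        expected = 15.481 + (2.898 - 1) / 1.5106
        assert abs(mode - expected) < 2 * (grid[1] - grid[0])

    def test_symmetric_mixture_mean_at_center(self):
        # two components mirrored about c = 20 (means 15 and 25)
        fit = _fit((0.5, 225.0, 15.0, 0.0), (0.5, 625.0, 25.0, 0.0))
        assert mixture_stats(fit).mixture_mean == pytest.approx(20.0)

    @pytest.mark.parametrize("fit", [
        _fit((1.0, 2.0, 0.5, 0.0)),
        _fit((0.3, 5.0, 1.0, 2.0), (0.7, 50.0, 5.0, 0.0)),
        _fit((0.2, 100.0, 10.0, 0.0), (0.3, 400.0, 20.0, 0.0), (0.5, 900.0, 30.0, 0.0)),
    ])
    def test_quadrature_normalization(self, fit):
        lo = min(c.loc for c in fit.components)
        hi = max(gamma_dist.ppf(1 - 1e-8, c.shape, loc=c.loc, scale=1 / c.rate)
                 for c in fit.components)
        total, _ = integrate.quad(lambda x: mixture_pdf(x, fit)[0], lo, hi, limit=200)
        assert abs(total - 1.0) < 1e-6

    def test_density_zero_below_all_locs(self):
        fit = _fit((1.0, 2.0, 1.0, 10.0))
        assert mixture_pdf(np.array([0.0, 5.0, 9.99]), fit).max() == 0.0


class TestKLDivergence:
    def test_zero_at_identity(self):
        fit = _fit((1.0, 20.0, 1.0, 0.0))
        support = np.arange(0, 80)
        q = mixture_cdf(support + 0.5, fit) - mixture_cdf(np.maximum(support - 0.5, 0), fit)
        data = EmpiricalDistribution(support, q / q.sum(), 1000)
        assert kl_divergence(data, fit) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_value(self):
        # choose the exponential rate whose discretized law on {0, 1} is (3/4, 1/4)
        def renorm_q0(r):
            q0 = 1 - np.exp(-r / 2)
            q1 = np.exp(-r / 2) - np.exp(-1.5 * r)
            return q0 / (q0 + q1) - 0.75
        r = optimize.brentq(renorm_q0, 0.1, 20.0)
        data = EmpiricalDistribution(np.array([0, 1]), np.array([0.5, 0.5]), 100)
        val = kl_divergence(data, _fit((1.0, 1.0, r, 0.0)))
        assert val == pytest.approx(0.5 * np.log(0.5 / 0.75) + 0.5 * np.log(0.5 / 0.25),
                                    abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegativity_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        data = empirical_distribution(rng.poisson(rng.uniform(1, 40), 200))
        fit = _fit((1.0, rng.uniform(0.5, 50), rng.uniform(0.05, 5), 0.0))
        assert kl_divergence(data, fit) >= 0.0


class TestFitMixture:
    def test_single_gamma_recovery(self):
        x = np.random.default_rng(1).gamma(5.0, 1 / 0.5, 5000)
        fit = fit_mixture(x, 1, FitOptions(seed=1))
        c = fit.components[0]
        assert abs(c.shape - 5.0) / 5.0 < 0.05
        assert abs(c.rate - 0.5) / 0.5 < 0.05

    def test_two_component_recovery(self):
        x = sample_gamma_mixture([(0.5, 100, 10, 0), (0.5, 900, 30, 0)], 5000, 2)
        fit = fit_mixture(x, 2, FitOptions(seed=2))
        weights = sorted(c.weight for c in fit.components)
        means = sorted(c.mean for c in fit.components)
        assert abs(weights[0] - 0.5) < 0.05 and abs(weights[1] - 0.5) < 0.05
        assert abs(means[0] - 10.0) / 10.0 < 0.03
        assert abs(means[1] - 30.0) / 30.0 < 0.03

    def test_kl_nesting_in_m(self):
        x = np.random.default_rng(3).gamma(5.0, 2.0, 3000)
        kls = [fit_mixture(x, m, FitOptions(seed=3)).kl for m in (1, 2)]
        assert kls[1] <= kls[0] + 1e-9

    def test_constant_samples_raise(self):
        with pytest.raises(DegenerateDataError, match="point mass"):
            fit_mixture(np.full(100, 7.0), 1)

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(4).gamma(8.0, 1.5, 2000)
        a = fit_mixture(x, 2, FitOptions(seed=9))
        b = fit_mixture(x, 2, FitOptions(seed=9))
        assert [(c.shape, c.rate, c.weight) for c in a.components] == \
               [(c.shape, c.rate, c.weight) for c in b.components]


class TestSelectModality:
    @pytest.mark.parametrize("seed", range(3))
    def test_classifies_each_truth_class(self, seed):
        uni = np.random.default_rng(100 + seed).gamma(5.0, 2.0, 2000)
        bi = sample_gamma_mixture([(0.5, 100, 10, 0), (0.5, 900, 30, 0)], 5000,
                                  200 + seed)
        tri = sample_gamma_mixture([(1 / 3, 100, 10, 0), (1 / 3, 400, 20, 0),
                                    (1 / 3, 900, 30, 0)], 5000, 300 + seed)
        opts = FitOptions(seed=seed)
        assert select_modality(uni, opts).m == 1
        assert select_modality(bi, opts).m == 2
        assert select_modality(tri, opts).m == 3

    def test_selected_m_minimizes_bic_with_tie_toward_simpler(self):
        x = np.random.default_rng(5).gamma(5.0, 2.0, 2000)
        call = select_modality(x, FitOptions(seed=5))
        best = min(call.bics, key=call.bics.get)
        assert call.bics[call.m] <= call.bics[best] + 2.0
        assert all(call.m <= m or call.bics[m] > call.bics[call.m] - 2.0
                   for m in call.bics)


class TestMixtureStats:
    def test_closed_form_moment_identities(self):
        c = GammaComponent(1.0, 4.0, 2.0, 1.0)
        assert c.mean == pytest.approx(3.0)
        assert c.variance == pytest.approx(1.0)
        assert c.skewness == pytest.approx(1.0)
        assert c.excess_kurtosis == pytest.approx(1.5)

    def test_peak_formula(self):
        assert GammaComponent(1.0, 3.0, 2.0, 5.0).peak == pytest.approx(6.0)
        assert GammaComponent(1.0, 0.7, 2.0, 5.0).peak == pytest.approx(5.0)

    def test_moments_match_numerical_quadrature(self):
        fit = _fit((0.4, 30.0, 3.0, 0.0), (0.6, 200.0, 8.0, 0.0))
        stats = mixture_stats(fit)
        hi = 80.0
        mean_num, _ = integrate.quad(lambda x: x * mixture_pdf(x, fit)[0], 0, hi,
                                     limit=200)
        var_num, _ = integrate.quad(
            lambda x: (x - mean_num) ** 2 * mixture_pdf(x, fit)[0], 0, hi, limit=200)
        assert abs(stats.mixture_mean - mean_num) / mean_num < 1e-4
        assert abs(stats.mixture_variance - var_num) / var_num < 1e-4

    def test_mixture_peaks_found_for_trimodal_law(self):
        fit = _fit((1 / 3, 100.0, 10.0, 0.0), (1 / 3, 400.0, 20.0, 0.0),
                   (1 / 3, 900.0, 30.0, 0.0))
        peaks = mixture_stats(fit).peaks
        assert len(peaks) == 3
        for expect in (9.9, 19.95, 29.97):
            assert min(abs(p - expect) for p in peaks) < 0.2

    def test_invalid_component_rejected(self):
        with pytest.raises(InvalidParameterError):
            GammaComponent(0.5, -1.0, 2.0)
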