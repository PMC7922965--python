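"""Displacement propagators: cusp law, subordination, series, MSD."""

import warnings

import numpy as np
import pytest
from scipy import integrate, stats

import dichodiff as dd
from dichodiff.occupation import MixedUnitIntervalPDF
from dichodiff.propagator import effective_diffusivity


def closed_form_tent_mixture(x, D, t, tau_p, tau_m):
    """Independent evaluation of the short-time three-term propagator."""
    from scipy.special import erfc

    tot = tau_p + tau_m
    w1 = (tau_p / tot) * (1 - t / tau_p)
    wu = 2 * t / tot
    x = np.abs(np.asarray(x, dtype=float))
    gauss = np.exp(-(x**2) / (4 * D * t)) / np.sqrt(4 * np.pi * D * t)
    tent = np.exp(-(x**2) / (4 * D * t)) / np.sqrt(np.pi * D * t) - (
        x / (2 * D * t)
    ) * erfc(x / np.sqrt(4 * D * t))
    return w1 * gauss + wu * tent


class TestConditionalGaussian:
    def test_peak_and_symmetry(self):
        T, D = 0.7, 10.0
        assert dd.conditional_gaussian(0.0, T, D) == pytest.approx(
            1 / np.sqrt(4 * np.pi * D * T)
        )
        x = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(
            dd.conditional_gaussian(x, T, D), dd.conditional_gaussian(-x, T, D)
        )

    def test_fraction_form_equals_time_form(self):
        assert dd.conditional_gaussian(1.0, 0.35, 10.0) == pytest.approx(
            dd.conditional_gaussian(1.0, 0.7, 10.0, t=0.5)
        )

    def test_zero_occupancy_signals_atom(self):
        with pytest.raises(ValueError, match="atom"):
            dd.conditional_gaussian(1.0, 0.0, 10.0)


class TestSubordination:
    def test_pure_fast_atom_gives_gaussian(self):
        g = MixedUnitIntervalPDF(
            atom0=0.0, atom1=1.0, density=lambda p: np.zeros_like(np.asarray(p))
        )
        pdf = dd.propagator_from_g(g, 10.0, 2.0)
        x = np.linspace(-10, 10, 21)
        np.testing.assert_allclose(
            np.atleast_1d(pdf.density(x)),
            stats.norm(scale=np.sqrt(2 * 10.0 * 2.0)).pdf(x),
            rtol=1e-9,
        )

    def test_flat_law_matches_closed_form(self, uniform_model):
        t = 0.3
        g = dd.g_short_time(uniform_model, t)
        pdf = dd.propagator_from_g(g, uniform_model.D_plus, t)
        x = np.linspace(-8, 8, 20)
        np.testing.assert_allclose(
            np.atleast_1d(pdf.density(x)),
            closed_form_tent_mixture(x, 10.0, t, 2.5, 5.0),
            rtol=1e-8,
        )
        assert pdf.atom_at_zero == pytest.approx(g.atom0)

    def test_normalisation_with_exact_law(self):
        g = dd.g_exact_exponential(1.0, 5.0, 2.0)
        pdf = dd.propagator_from_g(g, 10.0, 2.0)
        assert pdf.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_rejects_unnormalised_law(self):
        bad = MixedUnitIntervalPDF(
            atom0=0.3, atom1=0.3, density=lambda p: np.zeros_like(np.asarray(p))
        )
        with pytest.raises(ValueError, match="normalises"):
            dd.propagator_from_g(bad, 10.0, 1.0)


class TestShortTimePropagator:
    @pytest.mark.parametrize(
        "tau_p, tau_m, t", [(2.5, 5.0, 1.0), (4.0, 6.0, 2.0), (1.0, 1.0, 0.1)]
    )
    def test_total_mass_is_one(self, tau_p, tau_m, t):
        params = dd.ModelParams(10.0, 0.0, dd.Exponential(tau_p), dd.Exponential(tau_m))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdf = dd.propagator_short_time(params, t)
        assert pdf.total_mass() == pytest.approx(1.0, abs=1e-6)
        x = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(pdf.density(x), pdf.density(-x))

    def test_requires_frozen_slow_state(self):
        params = dd.ModelParams(10.0, 1.0, dd.Exponential(1.0), dd.Exponential(1.0))
        with pytest.raises(ValueError, match="D_minus"):
            dd.propagator_short_time(params, 0.1)

    def test_cusp_slope_matches_expansion(self, exp_unequal):
        t = 0.1
        pdf = dd.propagator_short_time(exp_unequal, t)
        c0, c1, c2 = dd.small_x_expansion(exp_unequal, t)
        eps = 1e-4 * np.sqrt(10.0 * t)
        slope = (float(pdf.density(np.array(2 * eps))) - float(pdf.density(np.array(eps)))) / eps
        assert slope == pytest.approx(-c1, rel=1e-2)
        assert float(pdf.density(np.array(eps))) == pytest.approx(c0, rel=1e-3)

    def test_expansion_reduces_at_equal_means(self, exp_equal):
        t = 0.1
        c0, c1, c2 = dd.small_x_expansion(exp_equal, t)
        tau, D = 1.0, 10.0
        assert c1 == pytest.approx(1 / (2 * D * tau), rel=1e-14)
        assert c0 == pytest.approx((3 * t + tau) / (4 * tau * np.sqrt(np.pi * D * t)), rel=1e-14)
        assert c2 == pytest.approx(
            (5 * t - tau) / (16 * tau * np.sqrt(np.pi) * (D * t) ** 1.5), rel=1e-14
        )

    @pytest.mark.parametrize(
        "tau_p, tau_m, t", [(1.0, 1.0, 0.05), (1.0, 5.0, 0.1), (2.5, 5.0, 0.3)]
    )
    def test_cusp_exists_for_all_params(self, tau_p, tau_m, t):
        params = dd.ModelParams(10.0, 0.0, dd.Exponential(tau_p), dd.Exponential(tau_m))
        assert dd.small_x_expansion(params, t)[1] > 0

    def test_cusp_is_non_analytic(self, exp_equal):
        # one-sided slopes converge while the central second difference
        # diverges like 1/h: the signature of a |x| kink, not a smooth dip
        t = 0.1
        pdf = dd.propagator_short_time(exp_equal, t)
        f0 = float(pdf.density(np.array(0.0)))
        second = []
        for h in (1e-2, 5e-3, 2.5e-3):
            fh = float(pdf.density(np.array(h)))
            second.append((2 * fh - 2 * f0) / h**2)
        assert second[1] / second[0] == pytest.approx(2.0, rel=0.1)
        assert second[2] / second[1] == pytest.approx(2.0, rel=0.1)


class TestLongTimeAndTails:
    def test_effective_diffusivity_below_fast_state(self, exp_unequal, exp_equal):
        assert effective_diffusivity(exp_unequal) == pytest.approx(10.0 / 6.0)
        assert effective_diffusivity(exp_equal) == pytest.approx(5.0)
        assert effective_diffusivity(exp_unequal) < exp_unequal.D_plus

    def test_long_time_gaussian_variance(self, exp_equal):
        t = 30.0
        pdf = dd.propagator_long_time(exp_equal, t)
        assert pdf.atom_at_zero == 0.0
        assert pdf.variance() == pytest.approx(10.0 * t, rel=1e-8)
        assert pdf.variance() == pytest.approx(float(dd.msd(exp_equal, t)), rel=1e-8)

    def test_tail_ratio_approaches_one(self, exp_equal):
        t = 0.1
        pdf = dd.propagator_short_time(exp_equal, t, exponential_weights=True)
        sigma = np.sqrt(2 * 10.0 * t)
        ratios = [
            float(pdf.density(np.array(z * sigma)))
            / float(dd.tail_gaussian(exp_equal, t, np.array(z * sigma)))
            for z in (5.0, 7.0, 10.0)
        ]
        assert ratios[0] > ratios[1] > ratios[2] > 1.0
        assert ratios[2] == pytest.approx(1.0, abs=5e-3)

    def test_tail_gaussian_prefactor_and_symmetry(self, exp_equal, exp_unequal):
        t = 0.1
        val = dd.tail_gaussian(exp_equal, t, np.array(0.0))
        assert float(val) == pytest.approx(
            np.exp(-0.1) / 2 / np.sqrt(4 * np.pi * 10.0 * t)
        )
        assert float(dd.tail_gaussian(exp_equal, t, np.array(2.0))) == pytest.approx(
            float(dd.tail_gaussian(exp_equal, t, np.array(-2.0)))
        )
        with pytest.raises(ValueError, match="equal-means"):
            dd.tail_gaussian(exp_unequal, t, 1.0)


class TestExactSeries:
    @pytest.mark.parametrize("t", [0.5, 2.0])
    def test_matches_subordination_quadrature(self, t):
        tau, D = 1.0, 10.0
        g = dd.g_exact_exponential(tau, tau, t)
        pdf = dd.propagator_from_g(g, D, t)
        for x in (0.1, 1.0, 3.0):
            assert dd.series_exact_equal_means(tau, D, t, x) == pytest.approx(
                float(pdf.density(np.array(x))), rel=1e-6
            )

    def test_short_time_limit_approaches_tent_law(self, exp_equal):
        t = 0.01
        pdf = dd.propagator_short_time(exp_equal, t, exponential_weights=True)
        for x in (0.05, 0.3, 1.0):
            assert dd.series_exact_equal_means(1.0, 10.0, t, x) == pytest.approx(
                float(pdf.density(np.array(x))), rel=1e-3
            )

    def test_even_in_x(self):
        x = np.array([-2.0, -0.5, 0.5, 2.0])
        vals = dd.series_exact_equal_means(1.0, 10.0, 1.0, x)
        np.testing.assert_allclose(vals[:2], vals[3:1:-1], rtol=1e-12)

    def test_truncation_diagnostics(self):
        with pytest.raises(ArithmeticError, match="not converged"):
            dd.series_exact_equal_means(1.0, 10.0, 50.0, 1.0, n_terms=5)


class TestSuperstatBaseline:
    def test_laplace_density_properties(self):
        meanD, t = 5.0, 1.0
        total, _ = integrate.quad(lambda x: dd.superstat_laplace(x, meanD, t), -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert dd.superstat_laplace(0.0, meanD, t) == pytest.approx(
            1 / np.sqrt(4 * meanD * t)
        )
        var, _ = integrate.quad(
            lambda x: x * x * dd.superstat_laplace(x, meanD, t), -np.inf, np.inf
        )
        assert var == pytest.approx(2 * meanD * t, rel=1e-8)

    def test_log_linear_versus_tent(self, exp_equal):
        # the exponential-mixture baseline is log-linear everywhere; the
        # two-state tent is not, and the densities split at the far tail
        t = 0.1
        meanD = effective_diffusivity(exp_equal)
        x = np.linspace(1.0, 5.0, 9) * np.sqrt(2 * 10.0 * t)
        log_ss = np.log(dd.superstat_laplace(x, meanD, t))
        assert np.max(np.abs(np.diff(log_ss, 2))) < 1e-10
        pdf = dd.propagator_short_time(exp_equal, t, exponential_weights=True)
        log_tent = np.log(np.maximum(pdf.density(x), 1e-300))
        assert np.max(np.abs(np.diff(log_tent, 2))) > 1e-3
        x5 = 5.0 * np.sqrt(2 * 10.0 * t)
        ratio = float(pdf.density(np.array(x5))) / dd.superstat_laplace(x5, meanD, t)
        assert ratio < 0.5 or ratio > 2.0


class TestMsd:
    def test_degenerate_single_diffusivity(self):
        params = dd.ModelParams(3.0, 3.0, dd.Exponential(1.0), dd.Exponential(5.0))
        assert float(dd.msd(params, 2.0)) == pytest.approx(2 * 3.0 * 2.0)

    def test_monte_carlo_linearity(self, exp_unequal, rng):
        n = 30_000
        for t in (0.5, 5.0, 50.0):
            x = dd.sample_endpoint_ensemble(exp_unequal, t, n, rng)
            m2 = np.mean(x**2)
            se = np.std(x**2, ddof=1) / np.sqrt(n)
            assert abs(m2 - float(dd.msd(exp_unequal, t))) < 5 * se


class TestIntervalProbability:
    def test_full_line_and_half_line(self, exp_unequal):
        t = 0.5
        pdf = dd.propagator_short_time(exp_unequal, t)
        assert dd.interval_probability(pdf, -np.inf, np.inf) == pytest.approx(1.0, abs=1e-6)
        w = pdf.atom_at_zero
        assert dd.interval_probability(pdf, 1e-12, np.inf) == pytest.approx(
            (1 - w) / 2, abs=1e-6
        )
        with pytest.raises(ValueError):
            dd.interval_probability(pdf, 1.0, -1.0)

    def test_atom_included_only_when_interval_covers_origin(self, exp_unequal):
        pdf = dd.propagator_short_time(exp_unequal, 0.5)
        inner = dd.interval_probability(pdf, -1.0, 1.0)
        shifted = dd.interval_probability(pdf, 0.5, 2.5)
        assert inner > pdf.atom_at_zero
        assert shifted < 0.5 * (1 - pdf.atom_at_zero)


def test_monte_carlo_endpoints_match_short_exact_and_long_laws(exp_equal, exp_unequal, rng):
    from conftest import mixed_displacement_gof
    from dichodiff.propagator import DisplacementPDF

    n = 100_000
    # deep in the short-time regime the tent law is quantitatively right
    for params in (exp_equal, exp_unequal):
        x = dd.sample_endpoint_ensemble(params, 0.1, n, rng)
        pdf = dd.propagator_short_time(params, 0.1, exponential_weights=True)
        assert mixed_displacement_gof(x, pdf) > 0.001
    # at t=0.5 the asymptotic tent has a visible O(t^2) bias, but the exact
    # equal-means law matches the simulator at full statistical resolution
    t = 0.5
    exact = DisplacementPDF(
        atom_at_zero=0.5 * np.exp(-t),
        density=lambda xx: np.atleast_1d(dd.series_exact_equal_means(1.0, 10.0, t, xx)),
        t=t,
    )
    x = dd.sample_endpoint_ensemble(exp_equal, t, n, rng)
    assert mixed_displacement_gof(x, exact) > 0.001
    x = dd.sample_endpoint_ensemble(exp_equal, 30.0, n, rng)
    assert stats.kstest(x, stats.norm(scale=np.sqrt(10.0 * 30.0)).cdf).pvalue > 0.001
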