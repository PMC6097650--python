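"""Hypothesis likelihoods against closed-form Gaussian oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from bpa import (
    builtin_function,
    likelihood_h1,
    likelihood_h2,
    likelihood_vectors,
    log_likelihood_ratio,
    make_variable_model,
)

H1_IDENTITY_ORACLE = 1.0 / (math.pi * math.sqrt(3.0))  # x=y=0, alpha=0.5


class TestH2:
    def test_closed_form_values(self, half_models):
        mx, my = half_models
        phi = stats.norm.pdf
        assert likelihood_h2(0, 0, mx, my) == pytest.approx(phi(0) ** 2, abs=1e-9)
        assert likelihood_h2(1, 0, mx, my) == pytest.approx(
            phi(1) * phi(0), abs=1e-9
        )

    def test_independent_of_variance_split(self):
        """Any alpha split convolves back to the unit normal, so the
        independence likelihood cannot depend on alpha."""
        my = make_variable_model(0.5)
        a = likelihood_h2(0.7, -1.2, make_variable_model(0.2), my)
        b = likelihood_h2(0.7, -1.2, make_variable_model(0.8), my)
        assert a == pytest.approx(b, rel=1e-10)


class TestH1:
    def test_identity_analytic_oracle(self, half_models, identity_f):
        mx, my = half_models
        got = likelihood_h1(0.0, 0.0, mx, my, identity_f)
        assert got == pytest.approx(H1_IDENTITY_ORACLE, abs=1e-9)

    def test_identity_brute_force_trapezoid(self, half_models, identity_f):
        """Cross-check the quadrature against dense trapezoidal
        integration of the same integrand on [-10, 10]."""
        mx, my = half_models
        i = np.arange(-10.0, 10.0 + 1e-4, 1e-4)
        x, y = 0.3, -0.4
        integrand = (
            mx.info.pdf(i) * mx.noise.pdf(x - i) * my.noise.pdf(y - i)
        )
        brute = np.trapezoid(integrand, i)  # both brackets equal for identity
        got = likelihood_h1(x, y, mx, my, identity_f)
        assert got == pytest.approx(brute, abs=1e-8)

    def test_symmetry_under_swap(self, identity_f):
        mx = my = make_variable_model(0.35)
        a = likelihood_h1(1.3, -0.2, mx, my, identity_f)
        b = likelihood_h1(-0.2, 1.3, mx, my, identity_f)
        assert a == pytest.approx(b, rel=1e-10)

    def test_discordant_extremes_penalized(self, identity_f):
        """Opposite-sign extremes force a large noise residual under the
        association hypothesis, so H2 must win there."""
        mx = my = make_variable_model(0.8)
        l1 = likelihood_h1(2.0, -2.0, mx, my, identity_f)
        l2 = likelihood_h2(2.0, -2.0, mx, my)
        assert l1 < l2

    def test_branch_sum_matches_inverse_form(self):
        """For a monotone f the change-of-variables second bracket must
        equal the literal f-inverse form, here integrated directly."""
        f = builtin_function("cubic")
        mx, my = make_variable_model(0.6), make_variable_model(0.4)
        x, y = np.array([0.8]), np.array([0.5])
        l1, _ = likelihood_vectors(x, y, mx, my, f)
        # literal second bracket: i over f's range, f^-1 applied
        i = np.linspace(-np.sqrt(0.4) * 10, np.sqrt(0.4) * 10, 400_001)
        second = np.trapezoid(
            my.info.pdf(i) * mx.noise.pdf(x[0] - f.inverse(i)) * my.noise.pdf(y[0] - i),
            i,
        )
        first = np.trapezoid(
            (lambda j: mx.info.pdf(j) * mx.noise.pdf(x[0] - j) * my.noise.pdf(y[0] - f.forward(j)))(
                np.linspace(-np.sqrt(0.6) * 10, np.sqrt(0.6) * 10, 400_001)
            ),
            np.linspace(-np.sqrt(0.6) * 10, np.sqrt(0.6) * 10, 400_001),
        )
        assert l1[0] == pytest.approx(0.5 * first + 0.5 * second, rel=1e-6)

    def test_forward_only_mode(self, half_models, identity_f):
        mx, my = half_models
        full = likelihood_h1(0.0, 0.0, mx, my, identity_f, branch_mode="forward_only")
        # both brackets equal for identity at the origin, so modes agree
        assert full == pytest.approx(H1_IDENTITY_ORACLE, abs=1e-9)

    def test_bad_branch_mode_rejected(self, half_models, identity_f):
        mx, my = half_models
        with pytest.raises(ValueError):
            likelihood_h1(0, 0, mx, my, identity_f, branch_mode="bogus")


class TestNumerics:
    def test_strict_positivity(self, identity_f, rng):
        mx, my = make_variable_model(0.3), make_variable_model(0.9)
        x, y = rng.normal(size=50), rng.normal(size=50)
        l1, l2 = likelihood_vectors(x, y, mx, my, identity_f)
        assert np.all(l1 > 0) and np.all(l2 > 0)

    @pytest.mark.parametrize("alpha_x, alpha_y", [(0.5, 0.5), (0.2, 0.8)])
    def test_quadrature_order_convergence(self, identity_f, alpha_x, alpha_y, rng):
        """Doubling the quadrature order moves both likelihoods by less
        than 1e-8 relative at default settings."""
        mx, my = make_variable_model(alpha_x), make_variable_model(alpha_y)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a1, a2 = likelihood_vectors(x, y, mx, my, identity_f, order=300)
        b1, b2 = likelihood_vectors(x, y, mx, my, identity_f, order=600)
        np.testing.assert_allclose(a1, b1, rtol=1e-8)
        np.testing.assert_allclose(a2, b2, rtol=1e-8)

    def test_h2_oracle_on_grid_all_alphas(self):
        phi = stats.norm.pdf
        pts = np.linspace(-3, 3, 7)
        for ax in (0.2, 0.5, 0.8):
            for ay in (0.2, 0.5, 0.8):
                mx, my = make_variable_model(ax), make_variable_model(ay)
                for xv in pts:
                    got = likelihood_h2(xv, 1.5, mx, my)
                    assert got == pytest.approx(phi(xv) * phi(1.5), abs=1e-6)


class TestLogLikelihoodRatio:
    def test_identity_origin_value(self, half_models, identity_f):
        mx, my = half_models
        expected = math.log(H1_IDENTITY_ORACLE / stats.norm.pdf(0) ** 2)
        got = log_likelihood_ratio(0.0, 0.0, mx, my, identity_f)
        assert got == pytest.approx(expected, abs=1e-7)

    def test_concordant_extremes_favor_association(self, identity_f):
        mx = my = make_variable_model(0.8)
        assert log_likelihood_ratio(2.5, 2.5, mx, my, identity_f) > 0
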