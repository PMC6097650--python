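"""Relationship functions: builtins, inverses, and the OLS fit."""

import numpy as np
import pytest

from bpa import builtin_function, fit_linear_relationship
from bpa.synthetic import standardized_relationship


def _grid_for(f, n=100):
    lo = f.domain.lo if np.isfinite(f.domain.lo) else -5.0
    hi = f.domain.hi if np.isfinite(f.domain.hi) else 5.0
    # exponential overflows the inverse round-trip beyond ~exp(30)
    return np.linspace(max(lo, -25.0), min(hi, 25.0), n)


INVERTIBLE = [
    ("identity", {}),
    ("linear", {"slope": 2.0, "intercept": 1.0}),
    ("linear", {"slope": -0.7, "intercept": 0.3}),
    ("quadratic", {"scale": 1.5}),
    ("cubic", {"scale": 0.5}),
    ("exponential", {"rate": 1.0}),
    ("sinusoidal", {"frequency": 1.0, "restricted": True}),
]


class TestBuiltins:
    @pytest.mark.parametrize("name, params", INVERTIBLE)
    def test_inverse_round_trip(self, name, params):
        f = builtin_function(name, **params)
        v = _grid_for(f)
        np.testing.assert_allclose(f.inverse(f.forward(v)), v, atol=1e-9)

    def test_identity_values(self):
        f = builtin_function("identity")
        assert f.forward(1.7) == 1.7
        assert f.inverse(1.7) == 1.7

    def test_quadratic_nonnegative_branch(self):
        f = builtin_function("quadratic")
        assert f.forward(2.0) == 4.0
        assert f.inverse(4.0) == 2.0
        assert f.domain.lo == 0.0

    def test_full_line_quadratic_has_no_inverse(self):
        f = builtin_function("quadratic", restricted=False)
        assert not f.invertible
        assert np.isinf(f.domain.lo)

    def test_full_line_sinusoid_has_no_inverse(self):
        assert not builtin_function("sinusoidal").invertible

    def test_derivative_matches_finite_difference(self):
        for name, params in INVERTIBLE:
            f = builtin_function(name, **params)
            v = _grid_for(f, 20)[1:-1]
            h = 1e-6
            fd = (np.asarray(f.forward(v + h)) - np.asarray(f.forward(v - h))) / (2 * h)
            np.testing.assert_allclose(
                f.derivative(v), fd, rtol=1e-4, atol=1e-4, err_msg=name
            )

    def test_unknown_name_lists_available(self):
        with pytest.raises(ValueError, match="identity"):
            builtin_function("sigmoid")


class TestLinearFit:
    def test_exact_fit(self):
        f = fit_linear_relationship([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert f.params["slope"] == pytest.approx(2.0)
        assert f.params["intercept"] == pytest.approx(1.0)
        assert f.inverse(5.0) == pytest.approx(2.0)

    def test_normalized_fit_recovers_pearson_slope(self, rng):
        """On standardised data OLS gives intercept 0 and slope equal to
        the correlation coefficient — verified against brute-force
        least squares on the design matrix."""
        from bpa import normalize_series

        x = normalize_series(rng.normal(size=300))
        y = normalize_series(x + rng.normal(size=300))
        f = fit_linear_relationship(x, y)
        r = float(np.corrcoef(x, y)[0, 1])
        assert f.params["slope"] == pytest.approx(r, abs=1e-10)
        assert f.params["intercept"] == pytest.approx(0.0, abs=1e-10)
        # brute-force normal equations
        A = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert f.params["slope"] == pytest.approx(beta[0], abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_relationship([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_flat_slope_loses_inverse(self, rng):
        x = rng.normal(size=50)
        f = fit_linear_relationship(x, np.zeros(50))
        assert not f.invertible


class TestStandardizedConjugate:
    def test_identity_with_equal_alphas_stays_identity(self):
        g = standardized_relationship(builtin_function("identity"), 0.5, 0.5)
        v = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(g.forward(v), v, atol=1e-9)

    def test_conjugate_round_trip(self):
        f = builtin_function("exponential")
        g = standardized_relationship(f, 2 / 3, 2 / 3)
        v = np.linspace(-3, 3, 50)
        np.testing.assert_allclose(g.inverse(g.forward(v)), v, atol=1e-8)

    def test_conjugate_calibrates_information_variance(self, rng):
        """g maps N(0, a_x) information onto variance a_y information —
        checked by simulation."""
        f = builtin_function("cubic")
        ax, ay = 0.5, 0.7
        g = standardized_relationship(f, ax, ay)
        # cubic draws are heavy-tailed (relative MC sd of the sample
        # variance ~1% at this size), so the band is a generous 5 sd
        draws = g.forward(rng.normal(scale=np.sqrt(ax), size=400_000))
        assert np.var(draws) == pytest.approx(ay, rel=0.05)
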