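"""Closed-form distribution mathematics against independent numeric oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

from standdist.distributions import (
    InflectionPoint,
    ParameterDomainError,
    RDistParams,
    RichardsPrototypeParams,
    Weibull3Params,
    r_cdf,
    r_inflection,
    r_pdf,
    r_quantile,
    richards_to_rdist,
    weibull3_cdf,
    weibull3_inflection,
    weibull3_pdf,
    weibull3_quantile,
)

from conftest import MID_R, random_r_params, random_weibull_params


def numeric_inflection_abscissa(pdf, lo, hi, h=1e-6):
    """Root of the CDF's second derivative (= the density's mode), located by
    brentq on a central difference of the density."""
    def d2(x):
        return pdf(x + h) - pdf(x - h)
    return optimize.brentq(d2, lo, hi, xtol=1e-12)


class TestRDist:
    def test_logistic_midpoint(self):
        for p in (0.3, 1.26, 4.0):
            assert r_cdf(9.4, RDistParams(p, 9.4, -1.0)) == pytest.approx(0.5, abs=1e-15)

    def test_asymptotes(self):
        assert r_cdf(1e4, MID_R) == pytest.approx(1.0, abs=1e-12)
        assert r_cdf(-1e4, MID_R) == 0.0

    def test_cdf_value_at_inflection_abscissa(self):
        # x = q + p ln(-r) gives ordinate (1 - 1/r)^r; for r = -3 that is 27/64
        par = RDistParams(1.26, 9.40, -3.0)
        x = par.q + par.p * math.log(3.0)
        assert r_cdf(x, par) == pytest.approx(27 / 64, abs=1e-12)

    def test_strictly_increasing(self):
        x = np.linspace(-20, 60, 400)
        f = np.asarray(r_cdf(x, MID_R))
        assert np.all(np.diff(f) > 0) or np.all(np.diff(f) >= 0)
        assert f[0] < 1e-6 and f[-1] > 1 - 1e-6

    def test_pdf_normalization(self):
        val, _ = integrate.quad(lambda x: r_pdf(x, MID_R), -60, 120, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_pdf_matches_cdf_derivative(self):
        h = 1e-5
        for x in (5.0, 10.0, 14.0):
            fd = (r_cdf(x + h, MID_R) - r_cdf(x - h, MID_R)) / (2 * h)
            assert r_pdf(x, MID_R) == pytest.approx(fd, abs=1e-6)

    def test_pdf_mode_at_inflection(self):
        infl = r_inflection(MID_R)
        x = np.linspace(infl.abscissa - 8, infl.abscissa + 8, 2001)
        dens = np.asarray(r_pdf(x, MID_R))
        assert abs(x[np.argmax(dens)] - infl.abscissa) < 0.01

    def test_quantile_closed_form(self):
        # logistic: q - p ln(1/u - 1)
        got = r_quantile(0.9, RDistParams(1.0, 10.0, -1.0))
        assert got == pytest.approx(10.0 - math.log(1 / 0.9 - 1.0), abs=1e-12)

    def test_quantile_median_logistic(self):
        assert r_quantile(0.5, RDistParams(2.0, 7.3, -1.0)) == pytest.approx(7.3)

    def test_quantile_bisection_crosscheck(self):
        par = RDistParams(1.0, 10.0, -1.0)
        x = optimize.brentq(lambda t: r_cdf(t, par) - 0.9, -50, 100, xtol=1e-12)
        assert r_quantile(0.9, par) == pytest.approx(x, abs=1e-9)

    @pytest.mark.parametrize("u", [0.001, 0.333, 0.5, 0.9, 0.999])
    def test_quantile_roundtrip(self, u):
        assert r_cdf(r_quantile(u, MID_R), MID_R) == pytest.approx(u, abs=1e-10)

    def test_quantile_domain(self):
        with pytest.raises(ValueError):
            r_quantile(0.0, MID_R)
        with pytest.raises(ValueError):
            r_quantile(1.0, MID_R)

    def test_inflection_logistic_symmetry(self):
        infl = r_inflection(RDistParams(1.5, 8.0, -1.0))
        assert infl.abscissa == pytest.approx(8.0)
        assert infl.ordinate == pytest.approx(0.5)

    def test_inflection_example(self):
        infl = r_inflection(RDistParams(1.26, 9.40, -3.0))
        assert infl.abscissa == pytest.approx(9.40 + 1.26 * math.log(3.0), abs=1e-12)
        assert infl.ordinate == pytest.approx(27 / 64, abs=1e-12)

    def test_inflection_matches_numeric_second_derivative(self, rng):
        for _ in range(20):
            par = random_r_params(rng)
            infl = r_inflection(par)
            x = numeric_inflection_abscissa(
                lambda t: r_pdf(t, par), infl.abscissa - 5 * par.p,
                infl.abscissa + 5 * par.p,
            )
            assert abs(x - infl.abscissa) < 1e-6

    def test_inflection_ordinate_decreases_with_r(self):
        rs = -np.linspace(0.3, 10.0, 100)
        ords = [(1 - 1 / r) ** r for r in rs]
        assert all(a > b for a, b in zip(ords, ords[1:]))
        # ordinates of plantation-range shapes live around 0.37-0.65
        assert 0.35 < min(ords[:64]) and max(ords[:5]) < 0.7

    def test_parameter_domain_errors(self):
        for bad in [(-1, 9, -2), (1, -9, -2), (1, 9, 2), (0, 9, -2)]:
            with pytest.raises(ParameterDomainError):
                RDistParams(*bad)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.floats(0.5, 3.0), q=st.floats(3.0, 18.0), r=st.floats(-7.0, -0.3),
        u=st.floats(0.01, 0.99),
    )
    def test_quantile_inverts_cdf_property(self, p, q, r, u):
        par = RDistParams(p, q, r)
        assert r_cdf(r_quantile(u, par), par) == pytest.approx(u, abs=1e-10)


class TestRichardsMapping:
    def test_explicit_mapping(self):
        par = richards_to_rdist(RichardsPrototypeParams(A=1, B=-math.e, k=1.0, m=2.0))
        assert (par.p, par.q, par.r) == pytest.approx((1.0, 1.0, -1.0))

    def test_cdf_equivalence_on_grid(self, rng):
        # prototype y = (1 - B e^{-kx})^{1/(1-m)} equals the R-distribution CDF
        for _ in range(10):
            B = -rng.uniform(3.0, 50.0)
            k = rng.uniform(0.3, 2.0)
            m = rng.uniform(1.2, 4.0)
            par = richards_to_rdist(RichardsPrototypeParams(A=1, B=B, k=k, m=m))
            x = np.linspace(par.q - 6 * par.p, par.q + 6 * par.p, 50)
            proto = (1.0 - B * np.exp(-k * x)) ** (1.0 / (1.0 - m))
            np.testing.assert_allclose(np.asarray(r_cdf(x, par)), proto, atol=1e-12)

    def test_empirical_B_range_gives_positive_location(self):
        for B in (-3.001, -10.0, -1e4):
            for k in (0.2, 1.0, 5.0):
                assert richards_to_rdist(
                    RichardsPrototypeParams(A=1, B=B, k=k, m=2.0)
                ).q > 0

    def test_m_near_one_sends_shape_to_minus_infinity(self):
        r1 = richards_to_rdist(RichardsPrototypeParams(1, -9.0, 1.0, 1.01)).r
        r2 = richards_to_rdist(RichardsPrototypeParams(1, -9.0, 1.0, 1.0001)).r
        assert r2 < r1 < -50

    def test_invalid_prototype(self):
        with pytest.raises(ParameterDomainError):
            RichardsPrototypeParams(A=1, B=1.0, k=1.0, m=2.0)
        with pytest.raises(ParameterDomainError):
            RichardsPrototypeParams(A=1, B=-3.0, k=1.0, m=0.5)


class TestWeibull3:
    def test_support_boundary(self):
        par = Weibull3Params(3.0, 5.0, 2.0)
        assert weibull3_cdf(3.0, par) == 0.0
        assert weibull3_cdf(1.0, par) == 0.0

    def test_exponential_median(self):
        assert weibull3_cdf(math.log(2), Weibull3Params(0, 1, 1)) == pytest.approx(0.5)
        assert weibull3_quantile(0.5, Weibull3Params(0, 1, 1)) == pytest.approx(
            math.log(2)
        )

    def test_known_value(self):
        assert weibull3_cdf(8.0, Weibull3Params(3, 5, 2)) == pytest.approx(
            1 - math.exp(-1), abs=1e-12
        )

    def test_pdf_normalization(self):
        par = Weibull3Params(1.0, 4.53, 1.93)
        val, _ = integrate.quad(lambda x: weibull3_pdf(x, par), par.a, 80, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_median_closed_form(self):
        par = Weibull3Params(2.0, 5.0, 3.0)
        assert weibull3_quantile(0.5, par) == pytest.approx(
            par.a + par.b * math.log(2) ** (1 / par.c)
        )

    @pytest.mark.parametrize("u", [0.001, 0.333, 0.5, 0.9, 0.999])
    def test_quantile_roundtrip(self, u):
        par = Weibull3Params(1.0, 5.0, 2.0)
        assert weibull3_cdf(weibull3_quantile(u, par), par) == pytest.approx(
            u, abs=1e-10
        )

    def test_inflection_known_case(self):
        infl = weibull3_inflection(Weibull3Params(0, 1, 2))
        assert infl.abscissa == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert infl.ordinate == pytest.approx(1 - math.exp(-0.5), abs=1e-12)

    def test_inflection_absent_for_concave_cdf(self):
        assert weibull3_inflection(Weibull3Params(0, 1, 1)) is None
        assert weibull3_inflection(Weibull3Params(0, 1, 0.7)) is None

    def test_inflection_ordinate_limit(self):
        assert weibull3_inflection(Weibull3Params(0, 1, 1e6)).ordinate == pytest.approx(
            1 - math.exp(-1), abs=1e-5
        )

    def test_inflection_matches_numeric_second_derivative(self, rng):
        for _ in range(20):
            par = random_weibull_params(rng, c_min=1.2)
            infl = weibull3_inflection(par)
            lo = par.a + 1e-3 * par.b
            hi = float(weibull3_quantile(0.999, par))
            x = numeric_inflection_abscissa(lambda t: weibull3_pdf(t, par), lo, hi)
            assert abs(x - infl.abscissa) < 1e-6

    def test_parameter_domain_errors(self):
        for bad in [(-1, 5, 2), (1, -5, 2), (1, 5, -2), (1, 0, 2)]:
            with pytest.raises(ParameterDomainError):
                Weibull3Params(*bad)


def test_logistic_reduction_is_exact():
    """At r = -1 the R distribution is the logistic CDF in (x - q)/p."""
    par = RDistParams(1.7, 8.2, -1.0)
    x = np.linspace(-10, 30, 101)
    logistic = 1.0 / (1.0 + np.exp(-(x - par.q) / par.p))
    np.testing.assert_allclose(np.asarray(r_cdf(x, par)), logistic, atol=1e-12)


def test_inflection_point_type_invariant():
    infl = r_inflection(MID_R)
    assert isinstance(infl, InflectionPoint)
    assert 0.0 < infl.ordinate < 1.0
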