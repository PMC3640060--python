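"""Closed-form mathematics of the R distribution and the three-parameter Weibull.

The R distribution is a reparameterization of the Richards growth function

    y = A * (1 - B * exp(-k * x)) ** (1 / (1 - m)),    A = 1, B < 0, k > 0, m > 1,

used as a cumulative diameter-distribution model.  Substituting

    p = 1 / k        (scale, cm)
    q = ln(-B) / k   (location, cm)
    r = 1 / (1 - m)  (shape, dimensionless, r < 0)

gives the CDF

    F(x) = [1 + exp(-(x - q) / p)] ** r,

a strictly increasing sigmoid on the whole real line with F(-inf) = 0 and
F(+inf) = 1.  At r = -1 it reduces to the logistic CDF with location q and
scale p.  Unlike the three-parameter Weibull, whose location parameter must
stay below every observation, the R distribution imposes no data-dependent
constraint on q — the property that makes it attractive for diameter
distribution fitting.

The three-parameter Weibull (location a, scale b, shape c) is provided as the
baseline family; its numerics delegate to :mod:`scipy.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ParameterDomainError",
    "RDistParams",
    "RichardsPrototypeParams",
    "Weibull3Params",
    "InflectionPoint",
    "r_cdf",
    "r_pdf",
    "r_logpdf",
    "r_quantile",
    "r_inflection",
    "richards_to_rdist",
    "weibull3_cdf",
    "weibull3_pdf",
    "weibull3_quantile",
    "weibull3_inflection",
]


class ParameterDomainError(ValueError):
    """A distribution parameter violates its domain constraint."""


@dataclass(frozen=True)
class RDistParams:
    """Parameters of the R distribution.

    Attributes
    ----------
    p : float
        Scale, cm; p > 0.
    q : float
        Location, cm; q > 0.
    r : float
        Shape, dimensionless; r < 0.
    """

    p: float
    q: float
    r: float

    def __post_init__(self) -> None:
        if not (self.p > 0):
            raise ParameterDomainError(f"scale p must be > 0, got {self.p}")
        if not (self.q > 0):
            raise ParameterDomainError(f"location q must be > 0, got {self.q}")
        if not (self.r < 0):
            raise ParameterDomainError(f"shape r must be < 0, got {self.r}")


@dataclass(frozen=True)
class RichardsPrototypeParams:
    """Richards prototype y = A(1 - B e^{-kx})^{1/(1-m)} restricted to CDFs.

    A is the asymptote (fixed at 1 for a CDF), B < 0 the initial-state
    coefficient, k > 0 the rate per cm, m > 1 the allometric shape.
    """

    A: float
    B: float
    k: float
    m: float

    def __post_init__(self) -> None:
        if self.A != 1:
            raise ParameterDomainError(f"asymptote A must be 1 for a CDF, got {self.A}")
        if not (self.B < 0):
            raise ParameterDomainError(f"B must be < 0 for a diameter CDF, got {self.B}")
        if not (self.k > 0):
            raise ParameterDomainError(f"rate k must be > 0, got {self.k}")
        if not (self.m > 1):
            raise ParameterDomainError(f"shape m must be > 1, got {self.m}")


@dataclass(frozen=True)
class Weibull3Params:
    """Three-parameter Weibull: location a >= 0 (cm), scale b > 0 (cm), shape c > 0."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a >= 0):
            raise ParameterDomainError(f"location a must be >= 0, got {self.a}")
        if not (self.b > 0):
            raise ParameterDomainError(f"scale b must be > 0, got {self.b}")
        if not (self.c > 0):
            raise ParameterDomainError(f"shape c must be > 0, got {self.c}")


@dataclass(frozen=True)
class InflectionPoint:
    """Inflection point of a cumulative diameter curve.

    abscissa : diameter, cm.  ordinate : cumulative probability in (0, 1).
    """

    abscissa: float
    ordinate: float


# --------------------------------------------------------------------------
# R distribution
# --------------------------------------------------------------------------

def _z(x, params: RDistParams):
    return (np.asarray(x, dtype=float) - params.q) / params.p


def r_cdf(x, params: RDistParams):
    """Cumulative distribution function of the R distribution.

    Evaluated in log space, F = exp(r * log(1 + e^{-z})) with z = (x - q)/p,
    so extreme arguments underflow cleanly to 0 / 1.
    """
    z = _z(x, params)
    out = np.exp(params.r * np.logaddexp(0.0, -z))
    return out if out.ndim else float(out)


def r_logpdf(x, params: RDistParams):
    """Log density of the R distribution."""
    z = _z(x, params)
    out = (
        math.log(-params.r)
        - math.log(params.p)
        - z
        + (params.r - 1.0) * np.logaddexp(0.0, -z)
    )
    return out if out.ndim else float(out)


def r_pdf(x, params: RDistParams):
    """Density of the R distribution, f(x) = (-r/p) e^{-z} (1 + e^{-z})^{r-1}."""
    out = np.exp(r_logpdf(x, params))
    return out if np.ndim(out) else float(out)


def r_quantile(u, params: RDistParams):
    """Inverse CDF: x = q - p * ln(u^{1/r} - 1) for u in (0, 1)."""
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("quantile argument must lie strictly in (0, 1)")
    out = params.q - params.p * np.log(np.expm1(np.log(u) / params.r))
    return out if out.ndim else float(out)


def r_inflection(params: RDistParams) -> InflectionPoint:
    """Inflection point of the R-distribution CDF.

    Abscissa x* = q + p ln(-r); ordinate (1 - 1/r)^r, a function of the shape
    parameter alone — the curve-shape summary used when relating the
    distribution to stand characteristics.
    """
    abscissa = params.q + params.p * math.log(-params.r)
    ordinate = (1.0 - 1.0 / params.r) ** params.r
    return InflectionPoint(abscissa=abscissa, ordinate=ordinate)


def richards_to_rdist(proto: RichardsPrototypeParams) -> RDistParams:
    """Convert Richards prototype parameters to R-distribution parameters.

    p = 1/k, q = ln(-B)/k, r = 1/(1-m).  Requires B < -1 so that q > 0
    (empirically B < -3 when fitting diameter CDFs).
    """
    q = math.log(-proto.B) / proto.k
    if q <= 0:
        raise ParameterDomainError(
            f"B = {proto.B} gives non-positive location q = {q}; need B < -1"
        )
    return RDistParams(p=1.0 / proto.k, q=q, r=1.0 / (1.0 - proto.m))


# --------------------------------------------------------------------------
# Three-parameter Weibull
# --------------------------------------------------------------------------

def _frozen(params: Weibull3Params):
    return stats.weibull_min(params.c, loc=params.a, scale=params.b)


def weibull3_cdf(x, params: Weibull3Params):
    """Weibull CDF, F(x) = 1 - exp(-((x-a)/b)^c); exactly 0 for x <= a."""
    out = _frozen(params).cdf(np.asarray(x, dtype=float))
    return out if np.ndim(out) else float(out)


def weibull3_pdf(x, params: Weibull3Params):
    out = _frozen(params).pdf(np.asarray(x, dtype=float))
    return out if np.ndim(out) else float(out)


def weibull3_quantile(u, params: Weibull3Params):
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("quantile argument must lie strictly in (0, 1)")
    out = _frozen(params).ppf(u)
    return out if out.ndim else float(out)


def weibull3_inflection(params: Weibull3Params) -> InflectionPoint | None:
    """Inflection point of the Weibull CDF, or None when c <= 1.

    For c > 1: abscissa a + b((c-1)/c)^{1/c}, ordinate 1 - e^{-(c-1)/c}.
    For c <= 1 the CDF is concave on its support and has no interior
    inflection.
    """
    c = params.c
    if c <= 1:
        return None
    t = (c - 1.0) / c
    return InflectionPoint(
        abscissa=params.a + params.b * t ** (1.0 / c),
        ordinate=1.0 - math.exp(-t),
    )
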