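"""Stand-level prediction of diameter distributions: PPM and PRM.

PPM (parameter prediction method) regresses per-stand fitted quantities —
distribution parameters, percentile diameters, the inflection abscissa — on
whole-stand characteristics with stepwise polynomial regression (linear and
quadratic terms, entry/stay significance level 0.5).  PRM (parameter
recovery method) inverts the distribution algebra to recover the parameters
that regression cannot predict reliably: the R-distribution shape r from the
inflection abscissa, the full (p, q, r) triple from two percentile diameters
plus the inflection abscissa, and the Weibull scale b from the median.

The five evaluation methods combine these:

    A  R distribution;  p ~ age, q ~ D_g, x* ~ D_g; r recovered from x*.
    B  R distribution;  p, q by stepwise regression on six characteristics,
       x* ~ D_g; r recovered from x*.
    C  R distribution, pure PRM; D_0.333, D_0.9, x* each ~ D_g, then
       (p, q, r) recovered jointly.
    D  Weibull (NRM fits); a, c, D_0.5 by stepwise regression on six
       characteristics; b recovered from the median.
    E  As D but trained on MLEM fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
import yaml
from scipy import optimize

from .diameter_classes import StandRecord
from .distributions import (
    RDistParams,
    Weibull3Params,
    r_inflection,
    r_quantile,
    weibull3_quantile,
)
from .fitting import FitResult

__all__ = [
    "PredictionEquation",
    "PPMModelSet",
    "fit_ppm_equations",
    "build_method_models",
    "recover_r_from_inflection",
    "recover_rdist_from_percentiles",
    "recover_weibull_b",
    "predict_stand_distribution",
    "save_model_set",
    "load_model_set",
    "METHOD_CHARACTERISTICS",
    "SIX_CHARACTERISTICS",
]

#: The six stand characteristics used by the multi-variable methods.
SIX_CHARACTERISTICS = (
    "age",
    "planting_density",
    "site_index",
    "mean_height",
    "dominant_height",
    "dg",
)

#: Characteristics each method must find on an input stand.
METHOD_CHARACTERISTICS = {
    "A": ("age", "dg"),
    "B": SIX_CHARACTERISTICS,
    "C": ("dg",),
    "D": SIX_CHARACTERISTICS,
    "E": SIX_CHARACTERISTICS,
}


@dataclass
class PredictionEquation:
    """One fitted regression: response ~ intercept + sum coef * char^degree."""

    response: str
    terms: list[tuple[str, int]]  # (characteristic name, degree 1 or 2)
    coefficients: list[float]     # aligned with terms
    intercept: float
    r_squared: float

    def predict(self, chars: dict[str, float]) -> float:
        val = self.intercept
        for (name, deg), coef in zip(self.terms, self.coefficients):
            if name not in chars:
                raise KeyError(
                    f"equation for {self.response} needs characteristic '{name}'"
                )
            val += coef * chars[name] ** deg
        return float(val)


@dataclass
class PPMModelSet:
    """The prediction equations of one evaluation method (A-E)."""

    family: str                       # "r" or "weibull3"
    method_code: str                  # A..E
    equations: dict[str, PredictionEquation] = field(default_factory=dict)

    @property
    def required_characteristics(self) -> tuple[str, ...]:
        return METHOD_CHARACTERISTICS[self.method_code]


def _term_column(stands: list[StandRecord], name: str, deg: int) -> np.ndarray:
    vals = np.array([s.characteristics()[name] for s in stands], dtype=float)
    return vals**deg


def fit_ppm_equations(
    response_values: np.ndarray,
    stands: list[StandRecord],
    response_name: str,
    candidates: tuple[str, ...],
    alpha_enter: float = 0.5,
    alpha_stay: float = 0.5,
) -> PredictionEquation:
    """Stepwise polynomial regression of a response on stand characteristics.

    Candidate terms are the linear and quadratic powers of each candidate
    characteristic.  Forward steps add the most significant candidate with
    p < alpha_enter; backward steps drop fitted terms with p > alpha_stay;
    iteration stops at a fixed point.  Rank-deficient additions are skipped
    with a warning.
    """
    y = np.asarray(response_values, dtype=float)
    if len(stands) < 10:
        raise ValueError("stepwise regression needs >= 10 stands")
    pool = [(name, deg) for name in candidates for deg in (1, 2)]
    cols = {t: _term_column(stands, *t) for t in pool}
    selected: list[tuple[str, int]] = []

    def ols(terms):
        X = sm.add_constant(
            np.column_stack([cols[t] for t in terms]) if terms
            else np.empty((y.size, 0))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.OLS(y, X).fit()

    changed = True
    while changed:
        changed = False
        # forward
        best_p, best_t = alpha_enter, None
        for t in pool:
            if t in selected:
                continue
            trial = selected + [t]
            X = np.column_stack([cols[u] for u in trial])
            if np.linalg.matrix_rank(sm.add_constant(X)) < len(trial) + 1:
                continue  # collinear with terms already in the model
            res = ols(trial)
            pval = res.pvalues[-1]
            if np.isfinite(pval) and pval < best_p:
                best_p, best_t = pval, t
        if best_t is not None:
            selected.append(best_t)
            changed = True
        # backward
        if selected:
            res = ols(selected)
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_stay:
                selected.pop(worst)
                changed = True

    res = ols(selected)
    r2 = float(res.rsquared) if selected else 0.0
    return PredictionEquation(
        response=response_name,
        terms=list(selected),
        coefficients=[float(c) for c in res.params[1:]],
        intercept=float(res.params[0]),
        r_squared=max(0.0, r2),
    )


# --------------------------------------------------------------------------
# PRM inversions
# --------------------------------------------------------------------------

def recover_r_from_inflection(p: float, q: float, x_star: float) -> float:
    """Shape r from the inflection abscissa: r = -exp((x* - q)/p).

    Exact inverse of x* = q + p ln(-r); defined for every real x*, always
    returns r < 0.
    """
    if p <= 0:
        raise ValueError(f"scale p must be > 0, got {p}")
    return -math.exp((x_star - q) / p)


def _log_expm1(y: float) -> float:
    # log(e^y - 1), stable for both small and large positive y
    if y > 30.0:
        return y
    if y > 1.0:
        return y + math.log1p(-math.exp(-y))
    return math.log(math.expm1(y))


def _percentile_p_q(r: float, d333: float, d900: float) -> tuple[float, float]:
    # F(d) = u  <=>  exp(-(d-q)/p) = u^{1/r} - 1
    g1 = _log_expm1(math.log(0.333) / r)
    g2 = _log_expm1(math.log(0.9) / r)
    p = (d900 - d333) / (g1 - g2)
    q = d333 + p * g1
    return p, q


def recover_rdist_from_percentiles(
    d333: float, d900: float, x_star: float,
    r_bracket: tuple[float, float] = (-50.0, -0.01),
) -> RDistParams:
    """Recover (p, q, r) from D_0.333, D_0.9 and the inflection abscissa.

    For fixed r the two percentile conditions give p(r) and q(r) in closed
    form; the remaining equation x* = q(r) + p(r) ln(-r) is solved by
    one-dimensional root finding in r.  The bracket is expanded
    geometrically on failure before raising.
    """
    if not d333 < d900:
        raise ValueError(f"need D_0.333 < D_0.9, got {d333} >= {d900}")

    def g(r):
        p, q = _percentile_p_q(r, d333, d900)
        return q + p * math.log(-r) - x_star

    lo, hi = r_bracket  # lo < hi < 0
    for _ in range(6):
        grid = -np.geomspace(-lo, -hi, 200)  # increasing grid of negative r
        vals = np.array([g(r) for r in grid])
        sign = np.sign(vals)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if idx.size:
            a, b = grid[idx[0]], grid[idx[0] + 1]
            r = optimize.brentq(g, a, b, xtol=1e-13, rtol=8.9e-16)
            p, q = _percentile_p_q(r, d333, d900)
            return RDistParams(p=p, q=q, r=r)
        lo, hi = lo * 10.0, hi / 10.0
    raise ValueError(
        f"no R-distribution shape solves (D_0.333={d333}, D_0.9={d900}, "
        f"x*={x_star}); the triple is infeasible"
    )


def recover_weibull_b(a: float, c: float, d50: float) -> float:
    """Weibull scale from the median: b = (D_0.5 - a) / (ln 2)^{1/c}."""
    if d50 <= a:
        raise ValueError(f"median {d50} must exceed location {a}")
    if c <= 0:
        raise ValueError(f"shape c must be > 0, got {c}")
    return (d50 - a) / math.log(2.0) ** (1.0 / c)


# --------------------------------------------------------------------------
# Method A-E model building and prediction
# --------------------------------------------------------------------------

def _r_responses(fit: FitResult) -> dict[str, float]:
    pr = fit.params
    return {
        "p": pr.p,
        "q": pr.q,
        "xstar": r_inflection(pr).abscissa,
        "d333": float(r_quantile(0.333, pr)),
        "d900": float(r_quantile(0.9, pr)),
    }


def _w_responses(fit: FitResult) -> dict[str, float]:
    pr = fit.params
    return {"a": pr.a, "c": pr.c, "d50": float(weibull3_quantile(0.5, pr))}


#: response -> candidate characteristics, per method code.
_METHOD_SPECS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"p": ("age",), "q": ("dg",), "xstar": ("dg",)},
    "B": {"p": SIX_CHARACTERISTICS, "q": SIX_CHARACTERISTICS, "xstar": ("dg",)},
    "C": {"d333": ("dg",), "d900": ("dg",), "xstar": ("dg",)},
    "D": {"a": SIX_CHARACTERISTICS, "c": SIX_CHARACTERISTICS,
          "d50": SIX_CHARACTERISTICS},
    "E": {"a": SIX_CHARACTERISTICS, "c": SIX_CHARACTERISTICS,
          "d50": SIX_CHARACTERISTICS},
}


def build_method_models(
    method_code: str,
    fits: dict[str, FitResult],
    stands: list[StandRecord],
    alpha: float = 0.5,
) -> PPMModelSet:
    """Fit the prediction-equation set of one evaluation method.

    ``fits`` maps stand_id to the per-stand fit the method trains on:
    R-distribution NRM fits for A-C, Weibull NRM fits for D, Weibull MLEM
    fits for E.
    """
    method_code = method_code.upper()
    if method_code not in _METHOD_SPECS:
        raise ValueError(f"unknown method code {method_code!r}")
    family = "r" if method_code in "ABC" else "weibull3"
    fitted_stands = [s for s in stands if s.stand_id in fits]
    if len(fitted_stands) < 10:
        raise ValueError("need fits for >= 10 stands to build a model set")
    for sid, fit in fits.items():
        if fit.family != family:
            raise ValueError(
                f"method {method_code} trains on {family} fits; "
                f"stand {sid} has a {fit.family} fit"
            )
    extract = _r_responses if family == "r" else _w_responses
    responses = {s.stand_id: extract(fits[s.stand_id]) for s in fitted_stands}
    model = PPMModelSet(family=family, method_code=method_code)
    for resp, candidates in _METHOD_SPECS[method_code].items():
        y = np.array([responses[s.stand_id][resp] for s in fitted_stands])
        model.equations[resp] = fit_ppm_equations(
            y, fitted_stands, resp, candidates, alpha_enter=alpha, alpha_stay=alpha
        )
    return model


def predict_stand_distribution(
    method_code: str, stand: StandRecord, models: PPMModelSet
):
    """Predict a stand's diameter distribution parameters with method A-E.

    Returns RDistParams (methods A-C) or Weibull3Params (D, E).  Raises
    KeyError naming any missing characteristic; recovery failures propagate
    as ValueError.
    """
    method_code = method_code.upper()
    if method_code != models.method_code:
        raise ValueError(
            f"model set was built for method {models.method_code}, "
            f"asked for {method_code}"
        )
    chars = stand.characteristics()
    for name in models.required_characteristics:
        if name not in chars or not np.isfinite(chars[name]):
            raise KeyError(f"stand {stand.stand_id}: missing characteristic '{name}'")
    eq = {k: e.predict(chars) for k, e in models.equations.items()}

    if method_code in ("A", "B"):
        p = max(eq["p"], 1e-2)
        q = max(eq["q"], 1e-2)
        r = recover_r_from_inflection(p, q, eq["xstar"])
        return RDistParams(p=p, q=q, r=r)
    if method_code == "C":
        return recover_rdist_from_percentiles(eq["d333"], eq["d900"], eq["xstar"])
    # D / E
    d50 = eq["d50"]
    a = float(np.clip(eq["a"], 0.0, max(d50 - 1e-3, 0.0)))
    c = max(eq["c"], 1e-2)
    b = recover_weibull_b(a, c, d50)
    return Weibull3Params(a=a, b=b, c=c)


# --------------------------------------------------------------------------
# Serialization (structured text, YAML)
# --------------------------------------------------------------------------

def save_model_set(models: PPMModelSet, path) -> None:
    doc = {
        "family": models.family,
        "method_code": models.method_code,
        "equations": {
            resp: {
                "terms": [[n, d] for n, d in e.terms],
                "coefficients": e.coefficients,
                "intercept": e.intercept,
                "r_squared": e.r_squared,
            }
            for resp, e in models.equations.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model_set(path) -> PPMModelSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    models = PPMModelSet(family=doc["family"], method_code=doc["method_code"])
    for resp, e in doc["equations"].items():
        models.equations[resp] = PredictionEquation(
            response=resp,
            terms=[(n, int(d)) for n, d in e["terms"]],
            coefficients=[float(c) for c in e["coefficients"]],
            intercept=float(e["intercept"]),
            r_squared=float(e["r_squared"]),
        )
    return models
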