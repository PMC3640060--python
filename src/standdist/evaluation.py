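"""Goodness-of-fit testing and cohort-level comparison.

The per-stand test is one-sample Kolmogorov-Smirnov against the predicted
(not refitted) distribution, so the asymptotic critical value
c(alpha)/sqrt(n) applies; c(0.05) = 1.358.  Cohort reports aggregate the sum
of RSS (on cumulative class frequencies) and the non-rejection percentage,
stratified by thinning status — the comparison layout used to rank the five
prediction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special

from .diameter_classes import StandRecord, build_histogram
from .distributions import RDistParams, Weibull3Params, r_cdf, weibull3_cdf

__all__ = ["KSResult", "EvaluationReport", "ks_test", "rss_r2",
           "evaluate_cohort", "write_report"]


@dataclass
class KSResult:
    statistic: float
    critical: float
    rejected: bool
    n: int


@dataclass
class EvaluationReport:
    """Cohort evaluation: per-stand KS/RSS plus stratified summaries."""

    method_code: str
    per_stand: pd.DataFrame
    total_rss: float = field(init=False)
    non_rejection: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        df = self.per_stand
        self.total_rss = float(df["rss"].sum())
        ok = ~df["rejected"]
        self.non_rejection = {"total": 100.0 * ok.mean()}
        for label, mask in (("unthinned", ~df["thinned"]), ("thinned", df["thinned"])):
            if mask.any():
                self.non_rejection[label] = 100.0 * ok[mask].mean()


def ks_test(
    diameters, cdf: Callable[[np.ndarray], np.ndarray], alpha: float = 0.05
) -> KSResult:
    """One-sample Kolmogorov-Smirnov test of a tree list against a CDF.

    D = sup_x |F_emp(x) - F(x)| from both one-sided suprema at the sorted
    sample points; the decision compares D with the asymptotic critical
    value kolmogi(alpha)/sqrt(n).
    """
    d = np.sort(np.asarray(diameters, dtype=float))
    n = d.size
    if n < 5:
        raise ValueError(f"KS test needs >= 5 trees, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    F = np.asarray(cdf(d), dtype=float)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - F)
    d_minus = np.max(F - (i - 1) / n)
    stat = float(max(d_plus, d_minus))
    crit = float(special.kolmogi(alpha)) / np.sqrt(n)
    return KSResult(statistic=stat, critical=crit, rejected=stat > crit, n=n)


def rss_r2(observed, predicted) -> tuple[float, float]:
    """Residual sum of squares and R² between observed cumulative
    frequencies and predicted CDF values; R² = 1 iff RSS = 0."""
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(predicted, dtype=float)
    if obs.shape != est.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {est.shape}")
    if obs.size < 2:
        raise ValueError("need >= 2 points")
    rss = float(np.sum((obs - est) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    return rss, r2


def _cdf_of(params) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(params, RDistParams):
        return lambda x: r_cdf(x, params)
    if isinstance(params, Weibull3Params):
        return lambda x: weibull3_cdf(x, params)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def evaluate_cohort(
    predictions: dict[str, RDistParams | Weibull3Params | None],
    stands: list[StandRecord],
    alpha: float = 0.05,
    method_code: str = "",
    class_width: float = 2.0,
) -> EvaluationReport:
    """Evaluate predicted distributions on a cohort of stands.

    ``predictions`` maps stand_id to predicted parameters; a None entry
    (recovery failure upstream) is scored as a rejection with infinite-free
    RSS omitted from the total.  KS runs on the raw diameters; RSS on the
    cumulative class frequencies at class upper boundaries.
    """
    rows = []
    for stand in stands:
        if stand.stand_id not in predictions:
            raise KeyError(f"no prediction for stand {stand.stand_id}")
        params = predictions[stand.stand_id]
        if params is None:
            rows.append(
                {"stand_id": stand.stand_id, "thinned": stand.thinned,
                 "n": stand.n_trees, "ks_statistic": np.nan,
                 "ks_critical": np.nan, "rejected": True, "rss": 0.0}
            )
            continue
        cdf = _cdf_of(params)
        ks = ks_test(stand.diameters, cdf, alpha=alpha)
        hist = build_histogram(stand, width=class_width)
        rss, _ = rss_r2(hist.cumulative, cdf(hist.upper_boundaries))
        rows.append(
            {"stand_id": stand.stand_id, "thinned": stand.thinned,
             "n": ks.n, "ks_statistic": ks.statistic,
             "ks_critical": ks.critical, "rejected": ks.rejected, "rss": rss}
        )
    return EvaluationReport(method_code=method_code, per_stand=pd.DataFrame(rows))


def write_report(report: EvaluationReport, per_stand_path, summary_path,
                 sep: str = ",") -> None:
    """Write the per-stand table and a structured-text summary block."""
    report.per_stand.to_csv(per_stand_path, sep=sep, index=False,
                            float_format="%.6g")
    lines = [
        f"method: {report.method_code or 'unspecified'}",
        f"stands: {len(report.per_stand)}",
        f"sum_rss: {report.total_rss:.6g}",
    ]
    for key in ("unthinned", "thinned", "total"):
        if key in report.non_rejection:
            lines.append(f"non_rejection_{key}_pct: {report.non_rejection[key]:.2f}")
    with open(summary_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
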