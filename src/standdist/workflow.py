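"""End-to-end workflow: fit -> build prediction models -> predict -> evaluate.

This is the library layer behind the command-line interface.  The full study
replica runs the three-step evaluation protocol on a synthetic cohort pair:
(1) per-stand NRM/MLEM fits on the fitting cohort, (2) PPM/PRM prediction
equations built from those fits, (3) Kolmogorov-Smirnov and RSS evaluation
of methods A-E on the independent evaluation cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .diameter_classes import StandRecord, build_histogram
from .evaluation import EvaluationReport, evaluate_cohort
from .fitting import FitResult, fit_mle_weibull3, fit_nrm
from .stand_prediction import (
    PPMModelSet,
    build_method_models,
    predict_stand_distribution,
)
from .synthetic_stands import CohortDesign, generate_cohorts

__all__ = ["StudyResult", "fit_cohort", "predict_cohort", "run_study"]

_METHOD_TRAINING = {"A": "r_nrm", "B": "r_nrm", "C": "r_nrm",
                    "D": "weibull3_nrm", "E": "weibull3_mle"}


@dataclass
class StudyResult:
    """Everything the study replica computes."""

    fits: dict[str, dict[str, FitResult]]       # fit key -> stand_id -> fit
    models: dict[str, PPMModelSet]              # method code -> model set
    reports: dict[str, EvaluationReport]        # method code -> evaluation

    def fit_total_rss(self, key: str) -> float:
        return sum(f.rss for f in self.fits[key].values())

    def fit_mean_r2(self, key: str) -> float:
        vals = [f.r_squared for f in self.fits[key].values()]
        return sum(vals) / len(vals)


def fit_cohort(
    stands: list[StandRecord],
    class_width: float = 2.0,
    eval_points: str = "upper",
) -> dict[str, dict[str, FitResult]]:
    """Per-stand fits of both families: R by NRM, Weibull by NRM and MLEM.

    Stands whose histograms have too few occupied classes for a
    three-parameter fit are skipped with a warning.
    """
    out: dict[str, dict[str, FitResult]] = {
        "r_nrm": {}, "weibull3_nrm": {}, "weibull3_mle": {}
    }
    for stand in stands:
        hist = build_histogram(stand, width=class_width)
        if hist.n_occupied < 4:
            warnings.warn(
                f"stand {stand.stand_id}: only {hist.n_occupied} occupied "
                f"classes; skipped"
            )
            continue
        mind = float(stand.diameters.min())
        out["r_nrm"][stand.stand_id] = fit_nrm(
            hist, "r", eval_points=eval_points
        )
        out["weibull3_nrm"][stand.stand_id] = fit_nrm(
            hist, "weibull3", eval_points=eval_points, min_diameter=mind
        )
        out["weibull3_mle"][stand.stand_id] = fit_mle_weibull3(
            stand, hist, eval_points=eval_points
        )
    return out


def predict_cohort(
    models: PPMModelSet, stands: list[StandRecord]
) -> dict[str, object]:
    """Predict distribution parameters for every stand; recovery failures
    yield None (scored as rejections downstream)."""
    preds: dict[str, object] = {}
    for stand in stands:
        try:
            preds[stand.stand_id] = predict_stand_distribution(
                models.method_code, stand, models
            )
        except ValueError as exc:
            warnings.warn(f"stand {stand.stand_id}: prediction failed ({exc})")
            preds[stand.stand_id] = None
    return preds


def run_study(
    design: CohortDesign | None = None,
    alpha: float = 0.05,
    methods: str = "ABCDE",
    class_width: float = 2.0,
) -> StudyResult:
    """Run the full three-step study replica on a synthetic design."""
    design = design or CohortDesign()
    fitting, evaluation = generate_cohorts(design)
    fits = fit_cohort(fitting, class_width=class_width)
    models = {}
    reports = {}
    for code in methods:
        models[code] = build_method_models(code, fits[_METHOD_TRAINING[code]], fitting)
        preds = predict_cohort(models[code], evaluation)
        reports[code] = evaluate_cohort(
            preds, evaluation, alpha=alpha, method_code=code, class_width=class_width
        )
    return StudyResult(fits=fits, models=models, reports=reports)
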