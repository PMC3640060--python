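"""Synthetic plantation cohorts for exercising the fitting/prediction system.

The generator emulates the structure of a spacing-trial study of even-aged
conifer plantations: five planting densities (1667-10000 stems/ha), repeated
measurement at ages 6-20, three replicate plots per density, 0.06-ha fitting
plots and 0.05-ha evaluation plots.  Quadratic mean DBH follows a monotone
saturating growth curve in age, damped by planting density; stem density
declines by self-thinning.  Distribution parameters are tied to stand
characteristics through quadratic links plus multiplicative lognormal noise
— location tracks D_g most strongly, scale grows with age, shape steepens
with age — and tree diameters are drawn by inverse-CDF sampling.

The evaluation cohort contains an unthinned stratum and a thinned stratum
produced by deterministically removing the smallest fraction of trees
(thinning from below).  Everything is a pure function of (design, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .diameter_classes import StandRecord
from .distributions import RDistParams, Weibull3Params, r_cdf, r_quantile, weibull3_quantile

__all__ = ["CohortDesign", "generate_stand", "generate_cohorts",
           "save_design", "load_design"]

#: Default quadratic links value = c0 + c1*X + c2*X^2, keyed by parameter,
#: with X the named stand characteristic.  Calibrated once so that the
#: generated parameter and D_g ranges match the printed ranges of the study
#: design being emulated (p ~ 0.5-2.6, q ~ 3.4-18.3, r ~ -0.3..-6.8,
#: D_g ~ 5-18 cm).
_R_LINKS = {
    "p": ("age", (0.45, 0.09, -0.0015)),
    "q": ("dg", (-0.40, 0.95, 0.002)),
    "r": ("age", (-0.60, -0.09, 0.0)),  # negative shape, magnitude grows with age
}
_R_NOISE = {"p": 0.05, "q": 0.03, "r": 0.08}

# Weibull generating links: the location sits on the diameter-class lattice
# (odd integers for 2-cm classes anchored at 1 cm) so that the fixed-location
# MLE convention is exactly attainable.
_W_LINKS = {
    "a": ("dg", (0.0, 0.35, 0.0)),
    "b": ("dg", (0.30, 0.50, 0.0)),
    "c": ("age", (1.80, 0.06, 0.0)),
}
_W_NOISE = {"a": 0.0, "b": 0.05, "c": 0.06}


@dataclass
class CohortDesign:
    """Study-design knobs for synthetic cohort generation."""

    planting_densities: tuple[int, ...] = (1667, 3333, 5000, 6667, 10000)
    ages: tuple[int, ...] = (6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    stands_per_cell: int = 3
    trees_per_stand: int | None = None  # None -> derived from density * area
    generating_family: str = "r"
    parameter_links: dict | None = None
    noise_sd: dict | None = None
    seed: int = 0
    fitting_plot_area: float = 0.06   # ha
    eval_plot_area: float = 0.05      # ha
    #: evaluation stands use the lower spacing range (denser plots were not
    #: carried into the thinning trial being emulated)
    eval_planting_densities: tuple[int, ...] = (1667, 3333, 5000)
    n_eval_unthinned: int = 63
    n_eval_thinned: int = 96
    thin_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.generating_family not in ("r", "weibull3"):
            raise ValueError(f"unknown family {self.generating_family!r}")
        if self.parameter_links is None:
            self.parameter_links = dict(
                _R_LINKS if self.generating_family == "r" else _W_LINKS
            )
        if self.noise_sd is None:
            self.noise_sd = dict(
                _R_NOISE if self.generating_family == "r" else _W_NOISE
            )


def _dg_curve(age: float, planting_density: float) -> float:
    """Quadratic mean DBH (cm) from a saturating age trend damped by density."""
    asym = 25.2 * (1667.0 / planting_density) ** 0.30
    return asym * -np.expm1(-0.065 * age)


def _self_thinned_density(age: float, planting_density: float) -> float:
    """Surviving stems/ha after density-dependent mortality from age 5 on."""
    rate = 0.0363 * (planting_density / 10000.0) ** 2
    return planting_density * np.exp(-rate * max(age - 5.0, 0.0))


def _link_value(design: CohortDesign, name: str, chars: dict[str, float],
                rng: np.random.Generator) -> float:
    char, (c0, c1, c2) = design.parameter_links[name]
    x = chars[char]
    val = c0 + c1 * x + c2 * x * x
    sd = design.noise_sd.get(name, 0.0)
    if sd > 0:
        val *= np.exp(rng.normal(0.0, sd))
    return float(val)


def _draw_params(design: CohortDesign, chars: dict[str, float],
                 rng: np.random.Generator, cell: str):
    if design.generating_family == "r":
        p = _link_value(design, "p", chars, rng)
        q = _link_value(design, "q", chars, rng)
        r = _link_value(design, "r", chars, rng)
        if p < 0.05 or q < 0.5 or r > -0.05:
            warnings.warn(f"cell {cell}: clipping infeasible R parameter draw")
            p, q, r = max(p, 0.05), max(q, 0.5), min(r, -0.05)
        return RDistParams(p=p, q=q, r=r)
    a = _link_value(design, "a", chars, rng)
    a = 1.0 + 2.0 * np.floor(max(a - 1.0, 0.0) / 2.0)  # snap to class lattice
    b = _link_value(design, "b", chars, rng)
    c = _link_value(design, "c", chars, rng)
    if b < 0.1 or c < 0.2:
        warnings.warn(f"cell {cell}: clipping infeasible Weibull parameter draw")
        b, c = max(b, 0.1), max(c, 0.2)
    return Weibull3Params(a=a, b=b, c=c)


def _sample_diameters(params, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(params, RDistParams):
        # truncate below the 1-cm measurement floor via the inverse CDF
        u_lo = float(r_cdf(1.0, params))
        u = rng.uniform(u_lo, 1.0 - 1e-12, size=n)
        return np.asarray(r_quantile(u, params))
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=n)
    return np.asarray(weibull3_quantile(u, params))


def generate_stand(
    age: float,
    planting_density: float,
    design: CohortDesign,
    seed,
    stand_id: str = "S0",
    area: float | None = None,
    return_params: bool = False,
):
    """Generate one StandRecord (optionally also its generating parameters).

    ``seed`` may be an int or a numpy SeedSequence; generation is a pure
    function of (age, density, design, seed).
    """
    rng = np.random.default_rng(seed)
    area = design.fitting_plot_area if area is None else area
    stand_density = _self_thinned_density(age, planting_density) * np.exp(
        rng.normal(0.0, 0.015)
    )
    stand_density = min(stand_density, planting_density)
    dg_target = _dg_curve(age, planting_density) * np.exp(rng.normal(0.0, 0.04))
    site_index = float(np.clip(rng.normal(14.5, 1.2), 12.0, 18.0))
    hd_frac = -np.expm1(-0.07 * age) / -np.expm1(-0.07 * 20.0)
    dominant_height = site_index * hd_frac * np.exp(rng.normal(0.0, 0.03))
    mean_height = 0.88 * dominant_height * np.exp(rng.normal(0.0, 0.03))

    chars = {"age": float(age), "dg": float(dg_target)}
    params = _draw_params(design, chars, rng, cell=stand_id)
    n = design.trees_per_stand or max(int(round(stand_density * area)), 30)
    record = StandRecord(
        stand_id=stand_id,
        diameters=_sample_diameters(params, n, rng),
        age=float(age),
        planting_density=float(planting_density),
        stand_density=float(stand_density),
        site_index=site_index,
        mean_height=float(mean_height),
        dominant_height=float(dominant_height),
    )
    return (record, params) if return_params else record


def thin_from_below(record: StandRecord, fraction: float) -> StandRecord:
    """Remove the smallest ``fraction`` of trees (deterministic low thinning)."""
    if not 0 < fraction < 1:
        raise ValueError(f"thinning fraction must be in (0,1), got {fraction}")
    d = np.sort(record.diameters)
    k = int(np.ceil(fraction * d.size))
    return replace(
        record,
        diameters=d[k:],
        stand_density=record.stand_density * (1.0 - k / d.size),
        thinned=True,
    )


def generate_cohorts(design: CohortDesign, return_params: bool = False):
    """Generate the fitting and evaluation cohorts of the default study design.

    Returns (fitting, evaluation) lists of StandRecord — with the defaults,
    150 fitting stands (5 densities x 10 ages x 3 replicates) and 159
    evaluation stands (63 unthinned + 96 thinned from below).  With
    return_params=True each element is a (record, generating params) pair.
    """
    ss = np.random.SeedSequence(design.seed)
    n_fit = (
        len(design.planting_densities) * len(design.ages) * design.stands_per_cell
    )
    eval_ages = [a for a in design.ages if a >= 9] or list(design.ages)
    n_eval = design.n_eval_unthinned + design.n_eval_thinned
    children = ss.spawn(n_fit + n_eval)
    it = iter(children)

    fitting = []
    for dens in design.planting_densities:
        for age in design.ages:
            for rep in range(design.stands_per_cell):
                out = generate_stand(
                    age, dens, design, next(it),
                    stand_id=f"F-{dens}-a{age:02d}-r{rep}",
                    area=design.fitting_plot_area,
                    return_params=return_params,
                )
                fitting.append(out)

    evaluation = []
    for i in range(design.n_eval_unthinned):
        age = eval_ages[i % len(eval_ages)]
        dens = design.eval_planting_densities[i % len(design.eval_planting_densities)]
        out = generate_stand(
            age, dens, design, next(it),
            stand_id=f"EU-{i:03d}", area=design.eval_plot_area,
            return_params=return_params,
        )
        evaluation.append(out)
    for i in range(design.n_eval_thinned):
        age = eval_ages[i % len(eval_ages)]
        dens = design.eval_planting_densities[i % len(design.eval_planting_densities)]
        out = generate_stand(
            age, dens, design, next(it),
            stand_id=f"ET-{i:03d}", area=design.eval_plot_area,
            return_params=return_params,
        )
        if return_params:
            rec, par = out
            evaluation.append((thin_from_below(rec, design.thin_fraction), par))
        else:
            evaluation.append(thin_from_below(out, design.thin_fraction))
    return fitting, evaluation


# --------------------------------------------------------------------------
# Design-file I/O (structured text)
# --------------------------------------------------------------------------

def save_design(design: CohortDesign, path) -> None:
    doc = {
        "planting_densities": list(design.planting_densities),
        "ages": list(design.ages),
        "stands_per_cell": design.stands_per_cell,
        "trees_per_stand": design.trees_per_stand,
        "generating_family": design.generating_family,
        "parameter_links": {
            k: [char, list(coefs)] for k, (char, coefs) in design.parameter_links.items()
        },
        "noise_sd": design.noise_sd,
        "seed": design.seed,
        "fitting_plot_area": design.fitting_plot_area,
        "eval_plot_area": design.eval_plot_area,
        "eval_planting_densities": list(design.eval_planting_densities),
        "n_eval_unthinned": design.n_eval_unthinned,
        "n_eval_thinned": design.n_eval_thinned,
        "thin_fraction": design.thin_fraction,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_design(path) -> CohortDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("parameter_links"):
        doc["parameter_links"] = {
            k: (char, tuple(coefs)) for k, (char, coefs) in doc["parameter_links"].items()
        }
    for key in ("planting_densities", "ages", "eval_planting_densities"):
        if key in doc and doc[key] is not None:
            doc[key] = tuple(doc[key])
    return CohortDesign(**doc)
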