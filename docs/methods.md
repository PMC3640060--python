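# Methods

## The R distribution

The package models the cumulative diameter distribution of an even-aged
stand with

    F(x) = [1 + e^{-(x-q)/p}]^r,      p > 0, q > 0, r < 0,

the Richards growth function `y = (1 - B e^{-kx})^{1/(1-m)}` rewritten with
`p = 1/k`, `q = ln(-B)/k`, `r = 1/(1-m)`. The rewrite is exact: empirical
Richards fits of diameter CDFs have `B < -3` and `m > 1`, which maps to
`q > 0` and `r < 0`. The density is
`f(x) = (-r/p) e^{-z} (1 + e^{-z})^{r-1}` with `z = (x-q)/p`; the quantile
function is `x = q - p ln(u^{1/r} - 1)`; the CDF inflection point sits at
`x* = q + p ln(-r)` with ordinate `(1 - 1/r)^r`. At `r = -1` the family is
the logistic distribution. `q` acts as a location (it tracks quadratic mean
DBH almost one-to-one in fitted stands), `p` as a scale, and `r` as a shape:
the inflection ordinate — where the cumulative curve turns — depends on `r`
alone, falling from 1/e-like values toward `1 - e^{-1}`-complements as `r`
moves from 0⁻ to -∞; over the empirically observed shape range it spans
roughly 0.37-0.65. (One published account of this family prints an ordinate
minimum of 0.3787 alongside a shape minimum of -6.83, which evaluates to
≈0.393 under this formula; the small discrepancy in that source cannot be
reconciled from its text and is simply noted here.)

All evaluation is done in log space (`exp(r * logaddexp(0, -z))`), so
extreme arguments underflow cleanly and CDF/PDF values are accurate over the
whole real line.

The baseline is the three-parameter Weibull
`F(x) = 1 - exp(-((x-a)/b)^c)` (location `a`, scale `b`, shape `c`),
evaluated as exactly 0 for `x <= a` rather than erroring, so least-squares
objectives remain defined when a trial location exceeds a low class
boundary. Numerics delegate to `scipy.stats.weibull_min`.

Parameter-domain violations (`p <= 0`, `r >= 0`, `b <= 0`, ...) raise at
construction time, not evaluation time; optimizers work in transformed
coordinates (below) and therefore never construct invalid parameters.

## Diameter classes

Classes are 2 cm wide on an absolute scale anchored at 1 cm: class `k` (an
even midpoint) covers `[k-1, k+1)`, so 1.0-2.9 cm trees fall in class 2 and
3.0-4.9 cm trees in class 4. Values like 2.95 fall in the lower class — the
".9" upper limits denote 0.1-cm measurement precision, not closed
intervals. Relative frequencies `f_k = n_k/N` and cumulative frequencies
`F_k` form the observed cumulative distribution; empty interior classes are
retained so the cumulative curve lives on a contiguous grid. Binned
skewness and kurtosis are frequency-weighted central moments of the class
midpoints scaled by `s^3`/`s^4`; kurtosis is reported raw (non-excess) by
default with an `excess=True` option, since the convention cannot be pinned
down for this application and raw is the commoner forestry choice.

## Estimation

**NRM** minimizes `sum_k (F_k - F(x_k; theta))^2` over the class grid. The
CDF is evaluated at class **upper boundaries** by default — there the
observed cumulative frequency is an exact, unbiased empirical-CDF value —
with midpoints available as an option. Optimization uses
`scipy.optimize.least_squares` in transformed coordinates: `(log p, log q,
log(-r))` for the R distribution and `(a, log b, log c)` with `a` boxed in
`[0, d_min]` for the Weibull. The shape is additionally boxed to
`r ∈ [-50, -0.01]`: past `|r| ≈ 50` the family is numerically
indistinguishable from its Gumbel-type limit and the objective has a flat
runaway ridge (`r → -∞` with `q → 0` compensating through
`q + p ln(-r)`), which otherwise burns the iteration budget without
improving the fit. Defaults: iteration cap 500, relative objective
tolerance 1e-10, both configurable. Least squares is unweighted.
Non-convergence is flagged (`converged=False`, best-so-far parameters
returned), never raised.

**MLEM** for the Weibull fixes `a` at the lower limit of the minimum
diameter class and maximizes the likelihood of the raw diameters over
`(b, c)` (`scipy.stats.weibull_min.fit` with fixed location); if a diameter
sits exactly on the fixed location, `a` is shifted half a class width down
with a warning so the likelihood stays finite. RSS and R² are computed
afterward on the cumulative class frequencies so MLEM and NRM fits are
directly comparable. A maximum-likelihood fit of the R distribution
(Nelder-Mead on the log-likelihood in the same transformed coordinates) is
provided for completeness; the primary estimator for the R distribution is
NRM.

Initial guesses: for the R distribution `q0` = empirical median, `p0` =
IQR/(2 ln 3) (exact for the logistic), `r0 = -1`; for the Weibull, `a0`
just below the first occupied class lower bound and `(b0, c0)` from the
two-point percentile method at cumulative frequencies 0.333 and 0.9. From
these guesses NRM converges on ≥99% of simulated stands.

## Stand-level prediction (PPM and PRM)

PPM regresses per-stand fitted quantities on whole-stand characteristics
with stepwise polynomial regression: candidate terms are the linear and
quadratic powers of each characteristic, with entry and stay significance
levels both 0.5 (interpreted from the customary stepwise semantics of
statistical software); collinear additions are skipped. PRM inverts the
distribution algebra exactly:

* `r = -exp((x* - q)/p)` from the inflection abscissa (closed form);
* `(p, q, r)` jointly from `D_0.333`, `D_0.9` and `x*`: for fixed `r` the
  two percentile conditions give `p(r)` and `q(r)` in closed form, and the
  remaining equation is solved by bracketed one-dimensional root finding in
  `r ∈ (-50, -0.01)` (expanded geometrically before erroring on genuinely
  infeasible triples);
* Weibull `b = (D_0.5 - a)/(ln 2)^{1/c}` from the median (chosen because the
  median lies near the Weibull inflection point).

The five evaluation methods combine these (stand characteristics:
age `t`, planting density `N`, site index `SI`, mean height `H`, dominant
height `H_dom`, quadratic mean DBH `D_g`):

| Method | Family | Trained on | Regressions | Recovery | Characteristics |
|--------|--------|-----------|-------------|----------|-----------------|
| A | R | NRM fits | `p ~ t`, `q ~ D_g`, `x* ~ D_g` | `r` from `x*` | 2 |
| B | R | NRM fits | `p, q ~` all six, `x* ~ D_g` | `r` from `x*` | 6 |
| C | R | NRM fits | `D_0.333, D_0.9, x* ~ D_g` | full `(p,q,r)` | 1 |
| D | Weibull | NRM fits | `a, c, D_0.5 ~` all six | `b` from median | 6 |
| E | Weibull | MLEM fits | `a, c, D_0.5 ~` all six | `b` from median | 6 |

Method B's equations are direct regressions of `p` and `q` on the six
characteristics (not transformed responses), and Method C's predictors are
quadratics in `D_g` only — the readings consistent with each method's
stated number of input variables. Predicted `p`/`q` (A, B) are floored at
small positive values and predicted Weibull locations clipped below the
predicted median; a percentile triple with no consistent shape raises, and
the pipeline scores such stands as rejections rather than aborting the
cohort.

## Evaluation

The per-stand test is one-sample Kolmogorov-Smirnov of the raw tree list
against the **predicted** (not refitted) distribution, so the asymptotic
critical value `c(alpha)/sqrt(n)` applies (`c(0.05) = 1.358`,
`scipy.special.kolmogi`). `D` is the larger of the two one-sided suprema at
the sorted sample points — the exact supremum for continuous CDFs. When a
distribution was fitted on the same stand being tested, classical KS is
conservative; cohort reports are meant for independent evaluation stands.
KS runs on raw diameters (binning would coarsen `D` non-conservatively);
RSS/R² are computed on cumulative class frequencies at class upper
boundaries. Cohort reports aggregate the sum of RSS and the percentage of
non-rejected stands overall and by thinning stratum.

## Synthetic study design

The generator emulates a five-density spacing trial of a fast-growing
conifer plantation measured repeatedly over ages 6-20:

* planting densities 1667, 3333, 5000, 6667, 10000 stems/ha; measurement
  ages 6, 7, 8, 9, 10, 12, 14, 16, 18, 20; 3 replicate 0.06-ha plots per
  density — 150 fitting stands;
* an evaluation set of 159 stands on 0.05-ha plots at ages ≥ 9 drawn from
  the lower spacing range (1667-5000 stems/ha): 63 unthinned plus 96 thinned
  from below, the smallest 10% of stems removed deterministically (a light
  first-thinning intensity);
* quadratic mean DBH follows a saturating growth curve
  `D_g = 25.2 (1667/N)^{0.30} (1 - e^{-0.065 t})` with 4% lognormal noise,
  calibrated once so the cohort spans ≈5-18 cm as in the emulated trial;
  stem density declines by self-thinning at rate `0.0363 (N/10000)^2` per
  year from age 5; site index ~ N(14.5, 1.2) m clipped to [12, 18], heights
  from a saturating dominant-height curve through the site index.

Distribution parameters are linked to stand characteristics by quadratics
plus multiplicative lognormal noise, mirroring the relative strengths
observed in fitted plantation data — location driven by `D_g` (strongest
link), scale by age, shape magnitude growing with age so the inflection
ordinate drifts down with age:

    p = 0.45 + 0.09 t - 0.0015 t²         (5% noise)
    q = -0.40 + 0.95 D_g + 0.002 D_g²     (3% noise)
    r = -(0.60 + 0.09 t)                  (8% noise)

Diameters are drawn by inverse-CDF sampling truncated below the 1-cm
measurement floor. For Weibull-generated cohorts the location is snapped to
the class lattice (odd integers), so the fixed-location MLEM convention is
exactly attainable and estimator-consistency checks have a well-defined
truth. Everything is a pure function of `(design, seed)`.

What the generator does **not** emulate: spatial structure, competition,
mechanistic growth or mortality, measurement error in DBH, multimodality
after heavy thinning, and the years of regrowth that in real trials smooth
a thinning's truncation signature. Passing tests therefore demonstrate the
correctness and internal consistency of the estimation/prediction system
under its own assumptions, not its accuracy on any particular field data.

## Verification scale and numerical choices

The test suite verifies, among else: analytic inflection points against
numeric density-mode roots (50 random parameter sets per family, 1e-6 cm);
PDF normalization (1e-6) and quantile/CDF round trips (1e-10); exact
logistic reduction (1e-12); noiseless NRM identifiability (1e-4 relative);
estimator bias on 200 simulated stands of 1000 trees (median relative bias
per parameter below 2% — cohorts restricted to ages ≥ 10 where the 1-cm
floor carries no generating mass, so the generating model is exactly the
fitted model); exact PRM inversions (1e-6); the full 150+159-stand pipeline
(methods A and C ≥ 70% KS non-rejection; MLEM never beating NRM in total
RSS); and the 5% size of the KS rule over 1000 null replicates. These
problem sizes keep the whole suite under a minute of compute apart from the
bias study (~20 s) while leaving Monte-Carlo error comfortably inside the
asserted margins.

Known limitations: the R-distribution MLE uses a derivative-free optimizer
and is slower and slightly less stable than NRM on coarse histograms; the
stepwise selector explores squares but not interactions or transforms;
per-stand shape estimates (`r`, and Weibull `c` on few classes) carry large
sampling variance on 2-cm histograms — a property of the data resolution,
not of the optimizer — so shape-dependent summaries should be read at
cohort level, not per stand.
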