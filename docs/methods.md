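# Methods

## Thermal performance model

The core model is the sine-family (Boatman) TPC

    rate(T) = r_max · [sin(π · u^a)]^b,   u = (T − t_min)/(t_max − t_min),

defined as exactly zero at and beyond the critical temperatures (`u` is
clipped to [0, 1] before the powers, so no complex values arise and the
biological reading — activity ceases at the lethal boundary — is built in).
The skewness parameter `a > 1` pushes the optimum towards `t_max`, the shape
typical of warm-water specialists; `b` sharpens (`b > 1`) or flattens the
peak. The optimum has the closed form

    T_opt = t_min + (t_max − t_min) · (1/2)^(1/a),

independent of `b` (the sine reaches 1 at `u^a = 1/2` regardless of the
outer power); the test suite cross-checks it against brute-force grid
argmax. Seven further standard TPC forms (gaussian, concave quadratic,
Brière-2, Lactin-2, Ratkowsky, Weibull, Sharpe–Schoolfield with
high-temperature inactivation at a 20 °C reference) form the selection
battery. Every form is clamped to finite, non-negative rates so that AIC
comparison is well defined for any in-bounds parameter vector.

## Fitting and model selection

Each model is fitted by bounded least squares (scipy's trust-region
reflective solver, tolerances 10⁻¹⁰, at most 10⁴ evaluations per start)
from `n_starts` start vectors: one data-informed heuristic
(`t_min = min T − 2`, `t_max = max T + 2`, `r_max = max rate`,
`a = b = 1`) plus seeded uniform draws within the box constraints. The
multi-start is essential: the Boatman surface is multimodal in `(a, b)`.
Default box constraints adapt to the data — `r_max ∈ (0, 10·max rate]`,
`t_min ∈ [−20 °C, min T]`, `t_max ∈ [max T, 60 °C]`, `a, b ∈ (0, 20]`.

Models are ranked by the Gaussian-likelihood AIC

    AIC = n·ln(2π·RSS/n) + n + 2(k + 1),

counting the error variance as an estimated parameter so that models of
different dimension are comparable; ties break by smaller `k`, then model
id. A perfect fit (RSS = 0) returns a −∞ sentinel with a warning. Critical
temperatures of the fitted curve (`ct_min`/`ct_max`) are the explicit
`t_min`/`t_max` parameters for models that have them, otherwise the
outermost crossings of 10⁻³·r_max on [−20, 60] °C located by bisection.

## Bootstrap

Case resampling (the default; robust to variance misspecification) redraws
`(T, rate)` pairs with replacement; residual resampling redraws centered
residuals around the fitted values, truncated at zero. Each replicate is
refitted starting from the point estimate and summarized by percentile
intervals at `(1 ± level)/2`; the prediction band is the per-temperature
percentile envelope of the replicate curves.

For the Boatman model the replicate refits run through a batched projected
Levenberg–Marquardt: all replicates are iterated simultaneously with the
model's analytic Jacobian, Nielsen gain-ratio damping, Marquardt diagonal
scaling and projection onto the box constraints. On identical resamples it
reaches the same minima as the scipy reference solver (asserted in the test
suite) at a fraction of the runtime, which is what makes the coverage
experiment below tractable. Replicates that have not met the convergence
criteria (relative cost change or step below 10⁻⁸, or vanishing scaled
gradient) within 1000 iterations are counted as failures — these are
almost always resamples that lost the descending limb of the curve, leaving
`t_max` unidentified so the optimizer drifts along a flat ridge. An error
is raised if more than half of the replicates fail. Models without an
analytic Jacobian fall back to per-replicate scipy refits.

A caveat recorded rather than hidden: percentile bands need not strictly
contain the point fit at every grid temperature; with the default settings
they do in practice.

## THS index

THS(T) = rate(T)/r_max clipped to [0, 1] and forced to 0 outside the
critical temperatures: 1 at the optimum, 0 at the lethal boundaries, and
scale-free (multiplying all rates by a constant leaves it unchanged).
Bands: low [0, 0.2], moderate (0.2, 0.6], optimal (0.6, 1]. Only the low
and optimal ranges are conventional; the remainder is labelled moderate,
with the boundary memberships as written.

## Rasters and projection

Grids are geographic WGS84, stored as ESRI ASCII (.asc) text rasters with
nodata −9999 and THS emitted at float32 precision; a `scale` option divides
temperatures on read for datasets stored in tenths of a degree. Projection
is purely pixel-local (it commutes with cropping, which the tests exploit),
and no land/sea mask is applied — suitability is computed wherever
temperature exists, since freshwater habitat is sub-pixel at any practical
resolution. Summaries use latitude bands of 10° by default (closed-open,
south to north, membership by cell-center latitude), reporting
area-unweighted mean THS and the fraction of pixels above 0.6 per band and
month; empty bands are emitted with a zero-pixel marker, never dropped.

## Synthetic data

*Activity datasets.* `generate_dataset` adds Normal(0, sd²) noise truncated
at zero to exact model evaluations. The canonical 28-point dataset
(`thomas_fixture`) places noiseless Boatman evaluations at 28 evenly spaced
temperatures on [2, 28] °C with parameters `r_max = 119`, `t_min = 0 °C`,
`t_max = 36 °C`, `b = 1` and `a = ln 2 / ln(36/28.7) ≈ 3.0586`, chosen so
the upper critical temperature, the maximum rate and the analytic optimum
(28.7 °C) equal the published thermal traits of the medusa stage. The
historical observation of 0.9 pulsations/min at 2 °C is kept as a
documentation constant (`THOMAS_OBSERVED_RANGE`), not as fixture data: the
original observations were never deposited, so the cold-tail shape is
unknowable and the fixture makes no claim about it. Users with their own
digitization can supply it as a `temperature,rate` CSV anywhere a dataset
is accepted.

*Climate stacks.* An idealized Earth: quadratic latitudinal profile between
an equatorial annual mean of 27 °C and a polar mean of −20 °C, a seasonal
cosine whose half-range grows linearly with |latitude| to 20 °C at the
poles (peaking in July north, January south), uniform scenario offsets
(+1 °C SSP126 / +4 °C SSP585 by 2100, linearly interpolated to half by
2050), and Normal(0, 0.5²) per-pixel noise drawn once and shared across
months — so same-seed stacks for two scenarios differ by exactly the
scenario delta. Default grid: 2.5°, 72 × 144, global. These values are
realistic-Earth round numbers fixed once; all are overridable in
`ClimateSpec`. The generator deliberately omits continentality, topography
and ocean–land contrast, so passing map tests demonstrate the seasonal and
latitudinal logic of the projection engine, not fidelity to any real
climatology.

## Monte-Carlo experiment design

The statistical performance checks in the acceptance suite simulate from
the canonical parameter set at n = 28 with noise sd 5 pulsations/min, using
28 temperatures spanning the full tolerance window [2, 36] °C — the
standard designed-TPC layout with observations on both limbs. This matters:
with the historical 2–28 °C layout (ascending limb only) the optimum is
statistically unidentifiable to sub-degree precision no matter the
optimizer, because the data end before the curve turns over. Problem sizes
used: 200 datasets for optimum recovery (median |error| < 0.5 °C observed
≈ 0.12 °C), 200 × 500 replicates for bootstrap coverage (observed 0.91 at
nominal 0.95, with guard-tripped datasets counted as misses), 100
replicates for the AIC selection check.

## Known limitations

- The exact historical activity table behind the published fit is not
  public; the canonical dataset reproduces its printed thermal traits, not
  its raw observations, so per-model AIC values of the original comparison
  cannot be replicated.
- Case-bootstrap intervals for `t_opt` are conservative (upper tails
  inflate along the `t_max` ridge when resamples lose high-temperature
  points).
- GeoTIFF I/O is not implemented; conversion to/from .asc is a one-liner
  with GDAL (`gdal_translate -of AAIGrid`).
- 2050 offsets are a linear interpolation of the 2100 scenario deltas, not
  CMIP6 output.
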