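# Methods

## The growth model

`dendrofit` models the cumulative diameter (DBH, cm) of a tree over one
growing season as a five-parameter logistic (LG5, a Richards-family
sigmoid):

    D(t) = L + (K − L) · [1 + (1/θ) · exp(−r · (t − doy_ip))]^(−θ)

* `L`, `K` — lower and upper asymptotes (cm), `K > L`;
* `doy_ip` — the inflection day: the (real-valued) day of year at which
  the instantaneous growth rate is maximal;
* `r` — rate parameter (day⁻¹), `r > 0`;
* `θ` — asymmetry (dimensionless), `θ > 0`.  At `θ = 1` the curve is the
  symmetric logistic; large `θ` approaches the Gompertz limit, where the
  slope at the inflection tends to `(K − L)·r/e`.

This parameterization was chosen because the inflection sits exactly at
`doy_ip` for every `θ`, it collapses to the symmetric logistic at
`θ = 1`, and both the derivative and inverse are closed form:

    D′(t) = (K − L)·θ·r·u·(1 + u)^(−θ−1),  u = (1/θ)·exp(−r(t − doy_ip))
    t(y)  = doy_ip − (1/r)·ln[θ·(((y − L)/(K − L))^(−1/θ) − 1)]

Day-of-year is treated as a real number (not clamped to 1–366) so the
inverse and asymptote logic stay well defined.  The inverse is computed
with `log1p`/`expm1` branches so it remains accurate near both
asymptotes; within float64, diameters closer to an asymptote than
machine resolution carry no day information, which bounds attainable
round-trip accuracy (interior growth quantiles round-trip to < 1e−9
days).

## Likelihood

The objective is a Gaussian negative log-likelihood with a *fixed*
residual scale σ (default 0.1 cm): `nll = −Σ wᵢ log φ(dbhᵢ; D(doyᵢ), σ)`.
σ is not estimated; it only rescales the objective, so the best-fit
parameters are σ-invariant (tested).  Parameter vectors outside the
valid domain (`K ≤ L`, `r ≤ 0`, `θ ≤ 0`) score `+∞`, which keeps every
optimizer inside the domain without reparameterization.

The optional weight vector emphasizes early- and late-season points:

    wᵢ = 1 + λ·|doyᵢ − median(doy)| / (0.5·(max(doy) − min(doy)))

i.e. `w = 1` at the median day rising linearly to `1 + λ` (default
`λ = 1`) at the season ends.  This linear-in-day-distance form is this
package's own construction: it has a single interpretable knob and
directly encodes the intent (pull the asymptotes toward the observed
extremes).  Weighted optimizer runs are *scored and compared on the
plain likelihood*: the weighting is a fitting device, not a different
probability model, so weighted and unweighted optima live on one common
scale (each `FitResult` keeps the minimized weighted objective
separately).

## The optimization cascade

Five-parameter sigmoid fits to cumulative data have flat, ridged
likelihood surfaces.  The cascade:

1. **Starting values** — `L₀ = min(dbh)`, `K₀ = max(dbh)`,
   `doy_ip₀ = round(median(doy))`, `r₀ = 0.08`, `θ₀ = 1`.  Stage-1 box
   bounds: `L ∈ [L₀ − 0.5, L₀ + range/2]`, `K ∈ [K₀ − range/2, K₀ + 0.5]`
   (`range = K₀ − L₀`, floored at 0.01 cm), `doy_ip ∈ [min(doy), max(doy)]`,
   `r ∈ [10⁻⁴, 1]`, `θ ∈ [0.05, 20]`.  The bound widths are configurable
   (`bound_scale`).  A series whose diameter range is below caliper
   precision (0.01 cm) is flagged *low-growth* and fitted with widened
   asymptote bounds; its growth-process parameters should be treated
   with caution downstream.
2. **Stage 1** — bounded broad search with L-BFGS-B from the starting
   values (run both unweighted and weighted).  A non-finite stage-1
   outcome is retried once with doubled bound widths.
3. **Stage 2** — Nelder-Mead, unbounded BFGS, and a seeded simulated
   annealing search (`scipy.optimize.dual_annealing`, evaluation budget
   10⁴ by default, within the stage-1 box) are restarted from the
   respective stage-1 optimum.  Eight results total.
4. **Selection** — minimal plain nll wins; results within `1e−6`
   (`tie_tol`) count as tied and are resolved by the fixed preference
   Nelder-Mead > L-BFGS-B > BFGS > SANN, unweighted before weighted, so
   selection is deterministic.  With a fixed seed the whole cascade is
   bit-reproducible.

**Uncertainty.**  The 5×5 Hessian of the plain nll is computed at each
optimum by central differences (relative step 3e−4); its inverse
approximates the parameter covariance, and 95% intervals are
`estimate ± 2·sqrt(diag(H⁻¹))`.  A singular or non-positive-definite
Hessian yields an "unavailable" CI report, never a crash.  Intervals are
calibrated only when σ matches the true residual scale; with the 0.1 cm
default and millimeter-scale residuals they are conservative
(over-wide).  The coverage simulation in the test suite therefore sets
σ to the generator's noise (0.003 cm).

**Sample-size analysis.**  `subsample_series` thins a series to `n`
points at rounded-linspace indices (first and last always kept);
`frequency_analysis` reruns the full cascade per `n` and tabulates
estimates with CIs.  In simulations the asymptote estimates stay inside
the full-data CIs down to n = 9, while the inflection day wanders — it
behaves as the model's free parameter, which is why phenology is
derived from growth quantiles rather than from `doy_ip`.

## Season bounds (a, b)

The asymptotes describe the growth *process* and can lie outside the
observed data.  The diameters at the season's boundaries are estimated
semi-parametrically: the fitted curve is frozen and clipped,
`D_clip(t) = min(b, max(a, D(t)))`, and `(a, b)` maximize the clipped
likelihood over a joint grid bounded by the observed diameters
(`a ∈ [min(dbh), D(median doy)]`, `b ∈ [D(median doy), max(dbh)]`,
restricted to the open interval `(L, K)` so both crossing days exist).
A 50×50 coarse grid is scored; cells with `2·(nll − nll_min) ≤ χ²₀.₉₅`
are retained (df = 2 because the pair is searched jointly; df = 1 is
configurable for per-parameter profiling) and the search refocuses on a
50×50 fine grid over their bounding box.  Annual growth is `b − a`.
If no grid cell is valid (the curve misses the data entirely) the
estimate falls back to the data extremes clamped just inside `(L, K)` —
keeping the crossing days finite — with a warning.

## Phenology

Because `doy_ip` is unstable across sampling designs, phenological days
come from the curve's closed-form inverse at growth quantiles of the
season bounds: day of `a + q·(b − a)` with defaults q = 0.01 (start),
0.5 (mid) and 0.99 (end); the thresholds are configurable since "first
day of growth" has no canonical numeric definition.  The maximum growth
rate scans the analytic derivative over integer days 1–365 and reports
the maximum and its day.

## Quantile-convex hull (QCH) and deviations

Negative residuals from the base fit mark suppressed growth; positive
residuals are only a return to trend.  The QCH refits the LG5 to the
upper envelope: in-season points (`t_a ≤ doy ≤ t_b`) whose base
residuals reach the q-th residual quantile (default 0.8, i.e. the top
20% — the reading under which deviations from the hull come out almost
all non-positive), plus the two anchors `(t_a, a)` and `(t_b, b)` so the
hull honors the season bounds.  If fewer than six points are selected,
selection widens to the top `max(6, 20% of n)` residuals with a
warning.  The refit runs the focused stage-2 methods seeded from the
base parameters.

Deviations are `raw = dbh − hull(doy)` and
`weighted = raw × hull′(doy)`; the annual index is `Σ weighted`.
Slope-weighting discounts deviations at times when little growth is
expected, making the index comparable across trees and years.
`residual_synchrony` averages base-fit residuals across trees on a
shared day grid (pooled days clustered at gaps > 2 days; per tree the
nearest observation within ±2 days) and reports the mean with 2 SE — a
synchronized dip beyond 2 SE flags a stand-wide pause.

## Synthetic data

`simulate_tree` emulates the measurement protocol the workflow targets:
weekly readings on days 110–300, sigmoid growth with default truth
`L = 19.0`, `K = 19.46` cm, `doy_ip = 170`, `r = 0.06`/day, `θ = 1.5`
(a ~19-cm beech gaining 0.46 cm), and Gaussian noise at digital-caliper
precision, 0.003 cm (0.03 mm).  Optional truth bounds clip the curve,
and pauses subtract `depth × expected increment` over a window — a
*persistent* deficit (growth lost, not recovered), so pause residuals
are negative during and after the window.  `simulate_stand` jitters
`r` and `θ` by ±10% and `L` by ±0.2 cm (preserving `K − L`) with
deterministic per-tree sub-seeds, optionally sharing pause windows
across trees for synchrony experiments.

What the generator does **not** emulate: diurnal shrink–swell cycles,
temperature- or water-driven growth mechanisms, autocorrelated
measurement error, band slippage, or multi-year dynamics.  Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated observation model, not robustness to every
field artifact.

## Numerical choices and problem sizes

* Optimizer tolerances: Nelder-Mead `xatol 1e−9 / fatol 1e−11`
  (≤ 20 000 evaluations), L-BFGS-B `ftol 1e−14 / gtol 1e−10`, BFGS
  `gtol 1e−8`, annealing budget 10⁴ evaluations with a stored seed.
* Ties on the nll are broken at `1e−6`; duplicate measurement days are
  averaged before fitting; series shorter than six points are skipped.
* The recovery/coverage simulation uses 100 trees at weekly sampling
  (28 points each); the subsampling study uses a 33-point series
  thinned to n ∈ {9, 13, 17, 25, 33}; grid searches for `(a, b)` use
  50×50 coarse and fine grids.  These sizes give stable statistics at
  desk scale while keeping a full run in minutes on one core.

## Known limitations

* The Gaussian error model is fixed-scale; σ misspecification distorts
  CI widths (not point estimates).
* `(a, b)` are bounded by the observed diameters, so a season whose
  true start precedes the first measurement is censored at the data.
* Slow-growing trees (range near observational error) yield unreliable
  growth-process parameters even when total growth is well estimated;
  they are flagged, not dropped.
* The QCH inherits any bias of the base fit inside the season; with
  very long pauses the "upper envelope" points may themselves be
  depressed.
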