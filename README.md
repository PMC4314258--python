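# dendrofit

Intra-annual tree growth modelling from dendrometer-band time series.

Dendrometer bands — steel or plastic collars whose gap is read with
precision digital calipers — turn weekly field visits into
sub-millimeter records of stem diameter through a growing season.
`dendrofit` fits a parametric growth model to one tree-year of such
data and derives the quantities forest ecologists compare across trees,
species, sites and years: total annual growth, growth phenology, and an
index of drought-driven growth suppression.

The core model is the five-parameter logistic (LG5 / Richards) curve

    D(t) = L + (K − L) · [1 + (1/θ) e^(−r (t − doy_ip))]^(−θ)

with asymptotes `L`, `K` (cm), inflection day `doy_ip`, rate `r`
(day⁻¹) and asymmetry `θ` (θ = 1 is the symmetric logistic).  It is fit
by maximum likelihood under a fixed-scale Gaussian error model through a
staged optimizer cascade — a bounded L-BFGS-B broad search whose
optimum restarts Nelder-Mead, BFGS and seeded simulated annealing, each
also run with early/late-season weighting — with deterministic
best-model selection and Hessian-based confidence intervals.  On top of
the fit:

* **season bounds** `(a, b)`: start/end-of-season diameters estimated by
  clipping the frozen curve and maximizing likelihood over a
  chi-square-refocused grid; `b − a` is annual growth;
* **phenology**: days of 1%, 50% and 99% of seasonal growth via the
  curve's closed-form inverse, plus the maximum growth rate;
* **quantile-convex hull (QCH)**: an LG5 refit to the upper residual
  envelope, so deviations below it isolate growth pauses; deviations
  weighted by the hull's local slope sum to an annual suppression index;
* **residual synchrony** across a stand, flagging weather-driven pauses
  shared by all trees.

A seeded synthetic-data generator (weekly sampling, caliper-precision
noise, optional synchronized pauses with known truth) underpins the
test suite and provides ready-made benchmarks.

## Worked example

```python
import dendrofit as df
from dendrofit import LG5Regressor, SeasonBoundsEstimator, QuantileConvexHull

# one synthetic tree-year: weekly data, caliper noise, known truth
s = df.simulate_tree(df.SimSpec(noise_sd=0.003, seed=42))

reg = LG5Regressor(random_state=0).fit(s.doy, s.dbh)
print(reg.method_, [round(v, 4) for v in reg.params_])
# Nelder-Mead [19.0016, 19.46, 169.6687, 0.06, 1.648]

sb = SeasonBoundsEstimator(base=reg).fit(s.doy, s.dbh)
print(round(sb.a_, 4), round(sb.b_, 4), round(sb.annual_growth_, 4))
# 19.0034 19.46 0.4566

ph = sb.phenology()
print(round(ph.start_day, 1), round(ph.mid_day, 1), round(ph.end_day, 1))
# 119.4 172.3 246.4

qch = QuantileConvexHull(bounds=sb, random_state=0).fit(s.doy, s.dbh)
print(f"{qch.deviations(s.doy, s.dbh).annual_index:.6f}")
# -0.000022
```

The fit recovers the generator's truth (L = 19.0, K = 19.46,
doy_ip = 170, r = 0.06, θ = 1.5) to within noise; the season grew
0.457 cm between diameters `a` and `b`; half the season's growth was
reached on day 172; and the near-zero annual deviation index says this
pause-free tree never fell off its expected growth trajectory (a
drought year drives it negative).

Estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn tooling; every operation is also available as a plain
function (`fit_cascade`, `estimate_ab`, `fit_qch`, ...).

## Command line

```sh
dendrofit simulate --n-trees 20 --seed 1 --pause 160:30:0.5 --out stand.csv --truth-out truth.csv
dendrofit fit stand.csv --out fits.csv            # per-method table + best + CIs
dendrofit analyze fits.csv stand.csv --outdir out # bounds, phenology, deviations, synchrony
```

All knobs (σ, weighting λ, seeds, grid sizes, annealing budget, QCH
quantile, phenology thresholds, CSV column mapping) live in a YAML
config passed with `--config`; unset keys fall back to logged defaults.
Per-tree failures are logged and skipped, never fatal to a batch.

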