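"""Post-fit analyses: growth phenology, the quantile-convex hull, and
residual synchrony across trees.

Phenology — because the inflection-day parameter behaves as a "free"
parameter across sample sizes, phenological dates come from the curve's
inverse instead: the day a chosen fraction q of the season's growth
(a + q*(b - a)) is attained.  Defaults: start q=0.01, mid q=0.5, end
q=0.99.  The maximum growth rate is the derivative maximized over
integer days 1..365.

Quantile-convex hull (QCH) — negative residuals from the growth model
mark suppressed growth (drought, heat), but positive residuals are not
symmetric evidence of extra growth, merely a return to trend.  The QCH
therefore refits the LG5 to the *upper envelope* of the data: the
in-season points whose base-fit residuals reach the q-th quantile
(default 0.8, i.e. the top 20%), anchored at the season-bound crossings
(t_a, a) and (t_b, b).  Deviations below this hull isolate growth
pauses; weighting each deviation by the hull's local slope discounts
off-peak noise, and their annual sum indexes growth suppression for the
year — comparable across trees, sites and years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import CascadeConfig, FitResult, FitSet, fit_cascade, select_best, _make_result, _objective, _run_method, initial_values
from .growth import LG5Params, lg5_derivative, lg5_inverse, lg5_predict
from .season_bounds import BoundsEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "PhenologyMetrics",
    "QCHResult",
    "DeviationSeries",
    "growth_quantile_day",
    "phenology_metrics",
    "max_growth",
    "fit_qch",
    "deviations",
    "residual_synchrony",
]


@dataclass
class PhenologyMetrics:
    start_day: float
    mid_day: float
    end_day: float
    max_rate: float        # cm / day
    max_rate_day: int

    def __post_init__(self) -> None:
        if not (self.start_day < self.mid_day < self.end_day):
            raise ValueError("phenology days out of order")
        if self.max_rate <= 0:
            raise ValueError("maximum growth rate must be positive")


def growth_quantile_day(fit: FitResult | LG5Params, bounds: BoundsEstimate, q: float) -> float:
    """Day of year when a fraction q of the season's growth (a -> b) is
    attained, via the closed-form curve inverse."""
    params = fit.params if isinstance(fit, FitResult) else fit
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    y = bounds.a + q * (bounds.b - bounds.a)
    if y <= params.L:
        raise ValueError(f"target diameter {y:.4f} at or below the lower asymptote L={params.L:.4f}")
    if y >= params.K:
        raise ValueError(f"target diameter {y:.4f} at or above the upper asymptote K={params.K:.4f}")
    return float(lg5_inverse(params, y))


def max_growth(fit: FitResult | LG5Params) -> tuple[float, int]:
    """Maximum growth rate (cm/day) over integer days 1..365 and its day."""
    params = fit.params if isinstance(fit, FitResult) else fit
    days = np.arange(1, 366)
    rates = lg5_derivative(params, days)
    i = int(np.argmax(rates))
    return float(rates[i]), int(days[i])


def phenology_metrics(
    fit: FitResult | LG5Params,
    bounds: BoundsEstimate,
    q_start: float = 0.01,
    q_end: float = 0.99,
) -> PhenologyMetrics:
    rate, day = max_growth(fit)
    return PhenologyMetrics(
        start_day=growth_quantile_day(fit, bounds, q_start),
        mid_day=growth_quantile_day(fit, bounds, 0.5),
        end_day=growth_quantile_day(fit, bounds, q_end),
        max_rate=rate,
        max_rate_day=day,
    )


@dataclass
class QCHResult:
    params: LG5Params
    selected: np.ndarray   # indices into the series used for the refit
    q: float
    nll: float


def fit_qch(
    doy,
    dbh,
    fit: FitResult,
    bounds: BoundsEstimate,
    q: float = 0.8,
    config: CascadeConfig | None = None,
) -> QCHResult:
    """Refit the LG5 to the upper residual envelope of the in-season data.

    In-season points (t_a <= doy <= t_b) whose base-fit residual reaches
    the q-th residual quantile are kept, plus the two season-bound anchors
    (t_a, a) and (t_b, b); the refit runs the focused stage-2 methods
    seeded from the base parameters.  Fewer than six selected points widen
    the selection to the top max(6, 20% of n) residuals, with a warning.
    """
    cfg = config or CascadeConfig()
    doy = np.asarray(doy, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    in_season = (doy >= bounds.t_a) & (doy <= bounds.t_b)
    idx = np.where(in_season)[0]
    resid = dbh[idx] - lg5_predict(fit.params, doy[idx])
    cut = np.quantile(resid, q) if len(resid) else np.inf
    sel = idx[resid >= cut]
    if len(sel) < 6:
        k = max(6, int(np.ceil(0.2 * len(doy))))
        k = min(k, len(idx))
        logger.warning("QCH selection below 6 points; widening to the top %d residuals", k)
        sel = idx[np.argsort(resid)[-k:]]
        sel = np.sort(sel)

    t_fit = np.concatenate([[bounds.t_a], doy[sel], [bounds.t_b]])
    y_fit = np.concatenate([[bounds.a], dbh[sel], [bounds.b]])
    order = np.argsort(t_fit)
    t_fit, y_fit = t_fit[order], y_fit[order]

    # focused stage-2 refit seeded from the base parameters
    fun = _objective(t_fit, y_fit, cfg.resid_sd, None)
    spec = initial_values(t_fit, y_fit, cfg)
    bounds_box = list(zip(spec.lower, spec.upper))
    x0 = np.asarray(fit.params, dtype=float)
    results = []
    with np.errstate(invalid="ignore", over="ignore"):
        for method in ("Nelder-Mead", "BFGS"):
            x, f, ok = _run_method(method, fun, x0, bounds_box, cfg)
            results.append(_make_result(method, False, x, f, ok, fun))
    best = select_best(FitSet(results=results), tie_tol=cfg.tie_tol)
    return QCHResult(params=best.params, selected=sel, q=q, nll=best.nll)


@dataclass
class DeviationSeries:
    doy: np.ndarray
    raw_dev: np.ndarray        # dbh - hull prediction (cm)
    weighted_dev: np.ndarray   # raw_dev * hull slope (cm^2 / day)
    annual_index: float        # sum of weighted deviations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"doy": self.doy, "raw_dev": self.raw_dev, "weighted_dev": self.weighted_dev}
        )


def deviations(doy, dbh, qch: QCHResult) -> DeviationSeries:
    """Raw and slope-weighted deviations from the hull, plus their annual sum.

    Weighting by the hull's growth rate discounts deviations at times of
    the season when little growth is expected.
    """
    doy = np.asarray(doy, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    raw = dbh - lg5_predict(qch.params, doy)
    wdev = raw * lg5_derivative(qch.params, doy)
    return DeviationSeries(doy=doy, raw_dev=raw, weighted_dev=wdev, annual_index=float(np.sum(wdev)))


def residual_synchrony(trees: list[tuple[np.ndarray, np.ndarray, FitResult]], match_window: float = 2.0) -> pd.DataFrame:
    """Mean base-fit residual across trees per shared measurement day.

    Trees are matched to each shared day by nearest observation within
    +/- ``match_window`` days; days matched by fewer than two trees are
    dropped.  Returns columns (doy, mean_resid, two_se, n_trees).  A
    synchronized dip below -2 SE flags a stand-wide growth pause.
    """
    if len(trees) < 2:
        raise ValueError("synchrony needs at least two trees")
    residuals = []
    for doy, dbh, fit in trees:
        doy = np.asarray(doy, dtype=float)
        dbh = np.asarray(dbh, dtype=float)
        residuals.append((doy, dbh - lg5_predict(fit.params, doy)))

    # shared day grid: cluster the pooled days, breaking at gaps > window
    all_days = np.sort(np.concatenate([d for d, _ in residuals]))
    clusters = np.split(all_days, np.where(np.diff(all_days) > match_window)[0] + 1)
    grid = np.array([np.round(np.mean(c)) for c in clusters])

    rows = []
    for g in grid:
        vals = []
        for doy, res in residuals:
            k = int(np.argmin(np.abs(doy - g)))
            if abs(doy[k] - g) <= match_window:
                vals.append(res[k])
        if len(vals) >= 2:
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            rows.append({"doy": g, "mean_resid": vals.mean(), "two_se": 2.0 * se, "n_trees": len(vals)})
    return pd.DataFrame(rows, columns=["doy", "mean_resid", "two_se", "n_trees"])
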