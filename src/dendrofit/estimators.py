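"""Scikit-learn-style estimators for the intra-annual growth workflow.

Three estimators compose the pipeline:

``LG5Regressor``
    fits the five-parameter logistic growth curve to one tree-year of
    (day-of-year, DBH) data by the staged maximum-likelihood cascade;
``SeasonBoundsEstimator``
    freezes a fitted curve and estimates the season's start and end
    diameters (a, b) by the clipped-model grid search;
``QuantileConvexHull``
    refits the curve to the upper residual envelope so that deviations
    below it isolate growth pauses.

All follow the fit/predict/get_params conventions so they compose with
sklearn model selection; X is the day-of-year as a single-column matrix
(a 1-d vector is accepted and reshaped), y is DBH in cm.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_is_fitted

from . import cascade as _cascade
from . import extensions as _ext
from . import season_bounds as _sb
from .cascade import CascadeConfig
from .growth import lg5_derivative, lg5_inverse, lg5_predict
from .season_bounds import BoundsConfig

__all__ = ["LG5Regressor", "SeasonBoundsEstimator", "QuantileConvexHull"]


def _check_Xy(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of day-of-year values")
        X = X[:, 0]
    elif X.ndim != 1:
        raise ValueError("X must be 1-d or a single-column 2-d array")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if y is None:
        return X
    y = np.asarray(y, dtype=float)
    if y.shape != X.shape:
        raise ValueError("X and y must have matching lengths")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    return X, y


class LG5Regressor(RegressorMixin, BaseEstimator):
    """LG5 (Richards) growth curve fit by the staged ML cascade.

    Parameters
    ----------
    resid_sd : fixed Gaussian residual scale sigma (cm); rescales the
        objective only — the fitted curve is sigma-invariant.
    weight_lambda : amplitude of the early/late-season weighting used by
        the weighted optimizer variants.
    r0, theta0 : starting rate and asymmetry for the broad search.
    bound_scale : multiplier on the default stage-1 bound widths.
    sann_maxfun : evaluation budget of the annealing stage.
    tie_tol : |delta nll| treated as a tie during model selection.
    random_state : seed of the annealing search.

    Attributes
    ----------
    params_ : the selected LG5Params (L, K, doy_ip, r, theta).
    nll_ : negative log-likelihood of the selected fit.
    method_ : label of the winning optimizer (e.g. "Nelder-Mead").
    fitset_ : all cascade results (``.to_frame()`` mirrors a per-method
        results table).
    hessian_ : 5x5 observed-information matrix at the optimum.
    low_growth_ : True when the diameter range is below caliper precision.
    """

    def __init__(
        self,
        resid_sd: float = 0.1,
        weight_lambda: float = 1.0,
        r0: float = 0.08,
        theta0: float = 1.0,
        bound_scale: float = 1.0,
        sann_maxfun: int = 10_000,
        tie_tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.resid_sd = resid_sd
        self.weight_lambda = weight_lambda
        self.r0 = r0
        self.theta0 = theta0
        self.bound_scale = bound_scale
        self.sann_maxfun = sann_maxfun
        self.tie_tol = tie_tol
        self.random_state = random_state

    def _config(self) -> CascadeConfig:
        return CascadeConfig(
            resid_sd=self.resid_sd,
            weight_lambda=self.weight_lambda,
            r0=self.r0,
            theta0=self.theta0,
            bound_scale=self.bound_scale,
            sann_maxfun=self.sann_maxfun,
            tie_tol=self.tie_tol,
            seed=self.random_state,
        )

    def fit(self, X, y):
        doy, dbh = _check_Xy(X, y)
        if len(doy) < 6:
            raise ValueError("need at least 6 observations to fit the growth curve")
        cfg = self._config()
        self.low_growth_ = _cascade.initial_values(doy, dbh, cfg).low_growth
        self.fitset_ = _cascade.fit_cascade(doy, dbh, cfg)
        if self.fitset_.best_index < 0:
            raise RuntimeError("no optimizer converged for this series")
        best = self.fitset_.best
        self.params_ = best.params
        self.nll_ = best.nll
        self.method_ = best.label
        self.hessian_ = best.hessian
        self.n_features_in_ = 1
        self._doy = doy
        self._dbh = dbh
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        return lg5_predict(self.params_, _check_Xy(X))

    def derivative(self, X):
        """Instantaneous growth rate (cm/day) at the given days."""
        check_is_fitted(self, "params_")
        return lg5_derivative(self.params_, _check_Xy(X))

    def inverse(self, y):
        """Day of year at which the fitted curve attains diameter y."""
        check_is_fitted(self, "params_")
        return lg5_inverse(self.params_, y)

    def conf_int(self) -> _cascade.CIReport:
        """95% parameter intervals from the observed information."""
        check_is_fitted(self, "params_")
        return _cascade.param_ci(self.fitset_.best)

    def residuals(self):
        check_is_fitted(self, "params_")
        return self._dbh - lg5_predict(self.params_, self._doy)


class SeasonBoundsEstimator(BaseEstimator):
    """Season start/end diameters (a, b) via the clipped-curve grid search.

    ``base`` is an (unfitted) LG5Regressor template cloned and fitted
    during ``fit``; pass a fitted one to reuse an existing curve.  The
    curve is frozen while (a, b) are searched, first on a coarse grid and
    then refined inside the chi-square-retained region.

    Attributes: ``a_``, ``b_``, ``t_a_``, ``t_b_``, ``annual_growth_``,
    ``nll_``, ``fallback_``, ``base_`` (the fitted curve).
    """

    def __init__(
        self,
        base: LG5Regressor | None = None,
        coarse_grid: int = 50,
        fine_grid: int = 50,
        chi2_df: int = 2,
        chi2_level: float = 0.95,
        resid_sd: float = 0.1,
    ):
        self.base = base
        self.coarse_grid = coarse_grid
        self.fine_grid = fine_grid
        self.chi2_df = chi2_df
        self.chi2_level = chi2_level
        self.resid_sd = resid_sd

    def fit(self, X, y):
        doy, dbh = _check_Xy(X, y)
        base = self.base if self.base is not None else LG5Regressor(resid_sd=self.resid_sd)
        if hasattr(base, "params_"):
            self.base_ = base
        else:
            self.base_ = clone(base).fit(doy, dbh)
        cfg = BoundsConfig(
            resid_sd=self.resid_sd,
            coarse_grid=self.coarse_grid,
            fine_grid=self.fine_grid,
            chi2_df=self.chi2_df,
            chi2_level=self.chi2_level,
        )
        est = _sb.estimate_ab(doy, dbh, self.base_.fitset_.best, cfg)
        self.bounds_ = est
        self.a_, self.b_ = est.a, est.b
        self.t_a_, self.t_b_ = est.t_a, est.t_b
        self.nll_ = est.nll_at_opt
        self.fallback_ = est.fallback
        self.annual_growth_ = _sb.annual_growth(est)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """The fitted curve clipped to [a, b]."""
        check_is_fitted(self, "bounds_")
        return _sb.clipped_predict(self.base_.params_, self.a_, self.b_, _check_Xy(X))

    def phenology(self, q_start: float = 0.01, q_end: float = 0.99) -> _ext.PhenologyMetrics:
        """Start/mid/end-of-growth days and the maximum growth rate."""
        check_is_fitted(self, "bounds_")
        return _ext.phenology_metrics(
            self.base_.fitset_.best, self.bounds_, q_start=q_start, q_end=q_end
        )


class QuantileConvexHull(BaseEstimator):
    """Upper-envelope LG5 refit isolating growth pauses.

    Selects in-season points whose base-fit residuals reach the q-th
    quantile (plus the season-bound anchors) and refits the curve to
    them; ``deviations(X, y)`` then returns raw and slope-weighted
    deviations from the hull and their annual sum.

    Attributes: ``hull_params_``, ``selected_``, ``bounds_``, ``base_``,
    ``nll_``.
    """

    def __init__(
        self,
        q: float = 0.8,
        bounds: SeasonBoundsEstimator | None = None,
        resid_sd: float = 0.1,
        random_state: int = 0,
    ):
        self.q = q
        self.bounds = bounds
        self.resid_sd = resid_sd
        self.random_state = random_state

    def fit(self, X, y):
        doy, dbh = _check_Xy(X, y)
        sb = self.bounds if self.bounds is not None else SeasonBoundsEstimator(resid_sd=self.resid_sd)
        if hasattr(sb, "bounds_"):
            self.bounds_est_ = sb
        else:
            self.bounds_est_ = clone(sb).fit(doy, dbh)
        self.base_ = self.bounds_est_.base_
        cfg = CascadeConfig(resid_sd=self.resid_sd, seed=self.random_state)
        res = _ext.fit_qch(
            doy, dbh, self.base_.fitset_.best, self.bounds_est_.bounds_, q=self.q, config=cfg
        )
        self.qch_ = res
        self.hull_params_ = res.params
        self.selected_ = res.selected
        self.nll_ = res.nll
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "hull_params_")
        return lg5_predict(self.hull_params_, _check_Xy(X))

    def deviations(self, X, y) -> _ext.DeviationSeries:
        """Raw and slope-weighted deviations of (X, y) from the hull."""
        check_is_fitted(self, "hull_params_")
        doy, dbh = _check_Xy(X, y)
        return _ext.deviations(doy, dbh, self.qch_)
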