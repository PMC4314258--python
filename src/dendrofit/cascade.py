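"""Staged maximum-likelihood optimization for LG5 growth curves.

Five-parameter sigmoids fit to cumulative growth data have flat, ridged
likelihood surfaces: many parameter combinations give near-identical
curves.  The cascade tames this in two stages.  Stage 1 runs a bounded,
broad L-BFGS-B search from data-driven starting values (asymptotes at
the observed diameter extremes, inflection at the median day, a gentle
positive slope).  Stage 2 restarts Nelder-Mead, unbounded BFGS and a
seeded simulated-annealing search from the stage-1 optimum; the same
four methods are also run with the extreme-point weighting switched on.
The best model is the minimal negative log-likelihood, with ties broken
by a fixed method preference (Nelder-Mead first) so selection is
deterministic.

Uncertainty comes from the observed information: the numerical Hessian
of the nll at the optimum, whose inverse approximates the parameter
covariance; 95% intervals are the estimate +/- 2 standard errors.
"""

from __future__ import annotations

import inspect
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .growth import LG5Params
from .likelihood import make_weights, nll

logger = logging.getLogger(__name__)

PARAM_NAMES = ("L", "K", "doy_ip", "r", "theta")

# tie-break preference when nll values are within tolerance
_METHOD_RANK = {"Nelder-Mead": 0, "L-BFGS-B": 1, "BFGS": 2, "SANN": 3}

__all__ = [
    "CascadeConfig",
    "StartSpec",
    "FitResult",
    "FitSet",
    "CIReport",
    "initial_values",
    "fit_cascade",
    "select_best",
    "param_ci",
    "numeric_hessian",
    "subsample_series",
    "frequency_analysis",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable knobs of the fitting cascade.

    resid_sd : fixed Gaussian residual scale sigma (cm).  Rescales the
        objective only; best-fit parameters are sigma-invariant.
    weight_lambda : amplitude of the early/late-season weighting.
    r0, theta0 : starting rate and asymmetry.
    bound_scale : multiplier on the default L/K bound widths.
    sann_maxfun : evaluation budget for the annealing stage.
    tie_tol : |delta nll| below which fits count as tied.
    seed : seed for the annealing search (the only stochastic stage).
    """

    resid_sd: float = 0.1
    weight_lambda: float = 1.0
    r0: float = 0.08
    theta0: float = 1.0
    bound_scale: float = 1.0
    sann_maxfun: int = 10_000
    tie_tol: float = 1e-6
    seed: int = 0


@dataclass
class StartSpec:
    params0: LG5Params
    lower: np.ndarray
    upper: np.ndarray
    low_growth: bool = False

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        p0 = np.asarray(self.params0, dtype=float)
        if not (np.all(self.lower < p0) and np.all(p0 < self.upper)):
            raise ValueError("starting values must lie strictly inside the bounds")

    def widened(self, factor: float = 2.0) -> "StartSpec":
        p0 = np.asarray(self.params0, dtype=float)
        return StartSpec(
            params0=self.params0,
            lower=p0 - factor * (p0 - self.lower),
            upper=p0 + factor * (self.upper - p0),
            low_growth=self.low_growth,
        )


@dataclass
class FitResult:
    """One optimizer run.  ``nll`` is the plain (unweighted) negative
    log-likelihood at the optimum — the common scale on which methods are
    compared; ``objective`` is the value of the (possibly weighted)
    objective the method actually minimized."""

    method: str
    weighted: bool
    params: LG5Params
    nll: float
    objective: float = np.nan
    hessian: np.ndarray | None = None
    converged: bool = False

    @property
    def label(self) -> str:
        return self.method + (" wt" if self.weighted else "")


@dataclass
class FitSet:
    results: list[FitResult] = field(default_factory=list)
    best_index: int = -1

    @property
    def best(self) -> FitResult:
        if self.best_index < 0:
            raise ValueError("no converged fit available")
        return self.results[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.results):
            row = {"method": r.method, "weighted": r.weighted}
            row.update(dict(zip(PARAM_NAMES, r.params)))
            row["nll"] = r.nll
            row["objective"] = r.objective
            row["converged"] = r.converged
            row["best"] = i == self.best_index
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CIReport:
    estimate: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    available: bool = True
    message: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimate, "lower95": self.lower95, "upper95": self.upper95},
            index=list(PARAM_NAMES),
        )


def initial_values(doy, dbh, config: CascadeConfig | None = None) -> StartSpec:
    """Data-driven starting values and stage-1 box bounds.

    Asymptotes start at the observed diameter extremes, the inflection at
    the (integer-rounded) median day; r and theta start at fixed gentle
    defaults.  A series whose diameter range falls below caliper precision
    (0.01 cm) is flagged low-growth and gets widened asymptote bounds.
    """
    cfg = config or CascadeConfig()
    doy = np.asarray(doy, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    L0, K0 = float(dbh.min()), float(dbh.max())
    low_growth = (K0 - L0) < 0.01
    rng_cm = max(K0 - L0, 0.01)
    half = 0.5 * rng_cm * cfg.bound_scale
    asym_pad = 0.5 * cfg.bound_scale
    if low_growth:
        half = asym_pad  # widen asymptote bounds; the signal is near noise
    p0 = LG5Params(L0, K0, float(round(np.median(doy))), cfg.r0, cfg.theta0)
    lower = np.array([L0 - asym_pad, K0 - half, doy.min(), 1e-4, 0.05])
    upper = np.array([L0 + half, K0 + asym_pad, doy.max(), 1.0, 20.0])
    return StartSpec(params0=p0, lower=lower, upper=upper, low_growth=low_growth)


def _objective(doy, dbh, resid_sd, weights):
    def fun(x):
        return nll(x, doy, dbh, resid_sd=resid_sd, weights=weights)

    return fun


def numeric_hessian(fun, x, rel_step: float = 3e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function at x."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-2)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


_DUAL_ANNEALING_SEED_KW = (
    "rng" if "rng" in inspect.signature(optimize.dual_annealing).parameters else "seed"
)


def _run_method(method, fun, x0, bounds, cfg: CascadeConfig):
    if method == "L-BFGS-B":
        res = optimize.minimize(
            fun, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        # line-search stalls at extreme ftol still leave a usable optimum
        return res.x, res.fun, bool(np.isfinite(res.fun))
    if method == "Nelder-Mead":
        res = optimize.minimize(
            fun, x0, method="Nelder-Mead",
            options={"maxiter": 20000, "maxfev": 20000, "xatol": 1e-9, "fatol": 1e-11},
        )
        return res.x, res.fun, bool(np.isfinite(res.fun))
    if method == "BFGS":
        res = optimize.minimize(fun, x0, method="BFGS", options={"gtol": 1e-8})
        # BFGS line-search stalls still leave a usable (improved) point
        return res.x, res.fun, bool(np.isfinite(res.fun))
    if method == "SANN":
        res = optimize.dual_annealing(
            fun, bounds=bounds, x0=x0,
            maxfun=cfg.sann_maxfun, maxiter=1000,
            **{_DUAL_ANNEALING_SEED_KW: cfg.seed},
        )
        return res.x, res.fun, bool(np.isfinite(res.fun))
    raise ValueError(f"unknown method {method!r}")


def _make_result(method, weighted, x, f, ok, plain_fun) -> FitResult:
    params = LG5Params(*x)
    converged = bool(ok and np.isfinite(f) and params.is_valid())
    # scoring and uncertainty both use the plain likelihood: the weighting
    # is a fitting device, not a different model
    plain = plain_fun(np.asarray(x)) if converged else np.inf
    hess = numeric_hessian(plain_fun, np.asarray(x)) if converged else None
    return FitResult(
        method=method, weighted=weighted, params=params,
        nll=float(plain), objective=float(f), hessian=hess, converged=converged,
    )


def fit_cascade(doy, dbh, config: CascadeConfig | None = None) -> FitSet:
    """Run the full two-stage cascade and select the best model.

    Stage 1 is a bounded L-BFGS-B broad search (run unweighted and
    weighted); stage 2 restarts Nelder-Mead, BFGS and seeded annealing
    from the respective stage-1 optimum.  A failed stage 1 is retried
    once with doubled bound widths.
    """
    cfg = config or CascadeConfig()
    doy = np.asarray(doy, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    start = initial_values(doy, dbh, cfg)
    weights = make_weights(doy, cfg.weight_lambda)

    fits: list[FitResult] = []
    plain_fun = _objective(doy, dbh, cfg.resid_sd, None)
    for weighted in (False, True):
        fun = _objective(doy, dbh, cfg.resid_sd, weights) if weighted else plain_fun
        spec = start
        bounds = list(zip(spec.lower, spec.upper))
        # the domain guard returns +inf outside K>L, r>0, theta>0; silence
        # the inf arithmetic inside scipy's finite-difference gradients
        with np.errstate(invalid="ignore", over="ignore"):
            x1, f1, ok1 = _run_method("L-BFGS-B", fun, np.asarray(spec.params0), bounds, cfg)
            if not (ok1 and np.isfinite(f1)):
                logger.warning(
                    "stage-1 L-BFGS-B failed (weighted=%s); retrying with doubled bounds", weighted
                )
                spec = start.widened(2.0)
                bounds = list(zip(spec.lower, spec.upper))
                x1, f1, ok1 = _run_method("L-BFGS-B", fun, np.asarray(spec.params0), bounds, cfg)
            fits.append(_make_result("L-BFGS-B", weighted, x1, f1, ok1, plain_fun))
            x0 = x1 if np.isfinite(f1) else np.asarray(spec.params0)
            for method in ("Nelder-Mead", "BFGS", "SANN"):
                x, f, ok = _run_method(method, fun, x0, bounds, cfg)
                fits.append(_make_result(method, weighted, x, f, ok, plain_fun))

    fitset = FitSet(results=fits)
    try:
        best = select_best(fitset, tie_tol=cfg.tie_tol)
        fitset.best_index = fits.index(best)
    except ValueError:
        logger.warning("no converged fit for this series")
        fitset.best_index = -1
    return fitset


def select_best(fitset: FitSet, tie_tol: float = 1e-6) -> FitResult:
    """Minimal-nll fit; ties resolved Nelder-Mead > L-BFGS-B > BFGS > SANN,
    unweighted before weighted, so the choice is deterministic."""
    converged = [r for r in fitset.results if r.converged]
    if not converged:
        raise ValueError("no converged fit to select from")
    best_nll = min(r.nll for r in converged)
    tied = [r for r in converged if r.nll - best_nll <= tie_tol]
    return min(tied, key=lambda r: (_METHOD_RANK[r.method], r.weighted))


def param_ci(fit: FitResult) -> CIReport:
    """95% intervals: estimate +/- 2 * sqrt(diag(H^-1)) from the observed
    information.  A singular or non-positive-definite Hessian yields an
    unavailable report rather than an error."""
    est = np.asarray(fit.params, dtype=float)
    nan = np.full(5, np.nan)
    if fit.hessian is None or not np.all(np.isfinite(fit.hessian)):
        return CIReport(est, nan, nan, available=False, message="Hessian unavailable")
    eig = np.linalg.eigvalsh(fit.hessian)
    if eig.min() <= 0:
        return CIReport(
            est, nan, nan, available=False,
            message=f"Hessian not positive definite (min eigenvalue {eig.min():.3g})",
        )
    se = np.sqrt(np.diag(np.linalg.inv(fit.hessian)))
    return CIReport(est, est - 2.0 * se, est + 2.0 * se, available=True)


def subsample_series(doy, dbh, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the first and last points and n-2 interior points at evenly
    spaced (rounded-linspace) indices; index collisions shift to the
    nearest unused index."""
    doy = np.asarray(doy)
    dbh = np.asarray(dbh)
    N = len(doy)
    if not 3 <= n <= N:
        raise ValueError(f"subsample size {n} outside [3, {N}]")
    raw = np.round(np.linspace(0, N - 1, n)).astype(int)
    used: list[int] = []
    for idx in raw:
        if idx not in used:
            used.append(idx)
            continue
        for off in range(1, N):
            for cand in (idx + off, idx - off):
                if 0 <= cand < N and cand not in used:
                    used.append(cand)
                    break
            else:
                continue
            break
    idx = np.sort(np.asarray(used))
    return doy[idx], dbh[idx]


def frequency_analysis(doy, dbh, n_grid, config: CascadeConfig | None = None) -> pd.DataFrame:
    """Refit the cascade at reduced, evenly spaced sample sizes.

    Returns one row per n with the best-fit parameters and their 95% CIs —
    the sample-size sensitivity check for a measurement protocol.
    """
    cfg = config or CascadeConfig()
    rows = []
    for n in n_grid:
        if n < 6:
            raise ValueError("need at least 6 points per subsample")
        d, x = subsample_series(doy, dbh, int(n))
        fitset = fit_cascade(d, x, cfg)
        best = fitset.best
        ci = param_ci(best)
        row: dict = {"n": int(n), "method": best.label, "nll": best.nll}
        for k, name in enumerate(PARAM_NAMES):
            row[name] = best.params[k]
            row[f"{name}_lo"] = ci.lower95[k]
            row[f"{name}_hi"] = ci.upper95[k]
        rows.append(row)
    return pd.DataFrame(rows)
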