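"""Semi-parametric season start/end diameters (a, b).

The LG5 asymptotes L and K describe the *growth process* and may sit
outside the observed diameters, especially when growth starts or stops
abruptly.  The diameters a tree actually had at the season's boundaries
are estimated separately: the fitted curve is frozen and clipped,

    D_clip(t) = min(b, max(a, D(t))),

and (a, b) are chosen by maximum likelihood over a grid bounded by the
observed data (initial and final diameters are not allowed outside the
measurements).  A coarse grid is scored first; cells within the
chi-square cutoff of the maximum (2*(nll - nll_min) <= quantile, df=2
for the joint search by default) are kept and the search refocused on a
fine subgrid of their bounding box.  b - a is the annual growth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cascade import FitResult
from .growth import lg5_inverse, lg5_predict
from .likelihood import LOG_SQRT_2PI

logger = logging.getLogger(__name__)

__all__ = ["BoundsConfig", "BoundsEstimate", "clipped_predict", "estimate_ab", "annual_growth"]


@dataclass(frozen=True)
class BoundsConfig:
    resid_sd: float = 0.1
    coarse_grid: int = 50
    fine_grid: int = 50
    chi2_df: int = 2       # joint (a, b) region; set 1 for per-parameter profiling
    chi2_level: float = 0.95


@dataclass
class BoundsEstimate:
    a: float               # start-of-season diameter (cm)
    b: float               # end-of-season diameter (cm)
    t_a: float             # day the fitted curve crosses a
    t_b: float             # day the fitted curve crosses b
    nll_at_opt: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if not (self.a < self.b and self.t_a < self.t_b):
            raise ValueError(f"invalid bounds: a={self.a}, b={self.b}, t_a={self.t_a}, t_b={self.t_b}")


def clipped_predict(params, a: float, b: float, t) -> np.ndarray:
    """The fitted curve clipped to [a, b]: flat at a before its crossing,
    flat at b after, the LG5 curve in between."""
    L, K = params[0], params[1]
    if not (L < a < b < K):
        raise ValueError(f"need L < a < b < K for crossings; got L={L}, a={a}, b={b}, K={K}")
    return np.clip(lg5_predict(params, t), a, b)


def annual_growth(bounds: BoundsEstimate) -> float:
    """Total growth over the season: b - a (cm)."""
    return bounds.b - bounds.a


def _grid_nll(pred, dbh, a_vals, b_vals, resid_sd):
    """nll of the clipped model on an (a, b) grid, vectorized.

    Returns shape (len(a_vals), len(b_vals)); invalid cells (a >= b) are inf.
    """
    clipped = np.clip(pred[None, None, :], a_vals[:, None, None], b_vals[None, :, None])
    z = (dbh[None, None, :] - clipped) / resid_sd
    out = pred.size * (LOG_SQRT_2PI + np.log(resid_sd)) + 0.5 * np.sum(z * z, axis=-1)
    out[a_vals[:, None] >= b_vals[None, :]] = np.inf
    return out


def estimate_ab(doy, dbh, fit: FitResult, config: BoundsConfig | None = None) -> BoundsEstimate:
    """Two-stage grid search for the season's start/end diameters.

    Stage 1 scores a coarse grid a in [min(dbh), D(median doy)],
    b in [D(median doy), max(dbh)] (restricted to the open (L, K) interval
    so crossing days exist); stage 2 refines on the bounding box of the
    chi-square-retained cells.  If no grid cell is valid the estimate falls
    back to the data extremes clamped just inside (L, K), with a warning.
    """
    cfg = config or BoundsConfig()
    doy = np.asarray(doy, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    params = fit.params
    L, K = params.L, params.K
    pred = lg5_predict(params, doy)
    d_mid = float(lg5_predict(params, np.median(doy)))

    eps = 1e-9 * max(1.0, K - L)

    def crossings(a, b):
        a = min(max(a, L + eps), K - 2 * eps)
        b = max(min(b, K - eps), a + eps)
        t = lg5_inverse(params, [a, b])
        return float(a), float(b), float(t[0]), float(t[1])

    a_lo, a_hi = float(dbh.min()), d_mid
    b_lo, b_hi = d_mid, float(dbh.max())
    # restrict to diameters the frozen curve actually crosses
    a_lo, a_hi = max(a_lo, L + eps), min(a_hi, K - eps)
    b_lo, b_hi = max(b_lo, L + eps), min(b_hi, K - eps)
    if not (a_lo < a_hi and b_lo < b_hi):
        logger.warning("no valid (a, b) grid inside (L, K); falling back to data extremes")
        a, b, t_a, t_b = crossings(dbh.min(), dbh.max())
        z = (dbh - np.clip(pred, a, b)) / cfg.resid_sd
        f = dbh.size * (LOG_SQRT_2PI + np.log(cfg.resid_sd)) + 0.5 * float(np.sum(z * z))
        return BoundsEstimate(a, b, t_a, t_b, f, fallback=True)

    a_vals = np.linspace(a_lo, a_hi, cfg.coarse_grid)
    b_vals = np.linspace(b_lo, b_hi, cfg.coarse_grid)
    grid = _grid_nll(pred, dbh, a_vals, b_vals, cfg.resid_sd)
    nll_min = grid.min()

    cutoff = stats.chi2.ppf(cfg.chi2_level, df=cfg.chi2_df)
    keep = 2.0 * (grid - nll_min) <= cutoff
    ia, ib = np.where(keep)
    a_fine = np.linspace(a_vals[ia.min()], a_vals[ia.max()], cfg.fine_grid)
    b_fine = np.linspace(b_vals[ib.min()], b_vals[ib.max()], cfg.fine_grid)
    fine = _grid_nll(pred, dbh, a_fine, b_fine, cfg.resid_sd)
    i, j = np.unravel_index(np.argmin(fine), fine.shape)
    a, b, t_a, t_b = crossings(a_fine[i], b_fine[j])
    return BoundsEstimate(a, b, t_a, t_b, float(fine[i, j]), fallback=False)
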