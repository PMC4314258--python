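"""Gaussian fixed-scale negative log-likelihood for LG5 fits.

The objective minimized by every optimizer stage is

    nll(P) = -sum_i w_i * log phi(dbh_i; D_P(doy_i), sigma)

with phi the normal density and sigma a *fixed* residual scale (0.1 cm by
default).  sigma is not estimated: it only rescales the objective, so the
best-fit parameters are identical for any sigma.  The optional weight
vector up-weights early- and late-season points, w = 1 at the median day
rising linearly to 1 + lambda at the season ends, which pushes the
asymptotes toward the observed extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth import LG5Params, lg5_predict

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

__all__ = ["LikelihoodConfig", "make_weights", "nll", "perfect_fit_nll"]


@dataclass(frozen=True)
class LikelihoodConfig:
    resid_sd: float = 0.1          # residual scale sigma, cm
    weighted: bool = False
    weight_lambda: float = 1.0     # extreme-weight amplitude

    def __post_init__(self) -> None:
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be positive")
        if self.weight_lambda < 0:
            raise ValueError("weight_lambda must be non-negative")


def make_weights(doy, weight_lambda: float = 1.0) -> np.ndarray:
    """Per-observation weights emphasizing the season's extremes.

    w_i = 1 + lambda * |doy_i - median(doy)| / (0.5 * (max - min)); a
    degenerate season (max == min) gets unit weights.
    """
    doy = np.asarray(doy, dtype=float)
    if weight_lambda < 0:
        raise ValueError("weight_lambda must be non-negative")
    span = doy.max() - doy.min()
    if span <= 0:
        return np.ones_like(doy)
    return 1.0 + weight_lambda * np.abs(doy - np.median(doy)) / (0.5 * span)


def nll(params, doy, dbh, resid_sd: float = 0.1, weights=None) -> float:
    """Weighted Gaussian negative log-likelihood; lower is better.

    Invalid parameters or non-finite predictions return +inf so optimizers
    are pushed back into the valid domain (K > L, r > 0, theta > 0).
    """
    p = LG5Params(*np.asarray(params, dtype=float))
    if not p.is_valid():
        return np.inf
    doy = np.asarray(doy, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    pred = lg5_predict(p, doy)
    if not np.all(np.isfinite(pred)):
        return np.inf
    z = (dbh - pred) / resid_sd
    loglik = -(LOG_SQRT_2PI + np.log(resid_sd)) - 0.5 * z * z
    if weights is None:
        return float(-np.sum(loglik))
    return float(-np.sum(np.asarray(weights, dtype=float) * loglik))


def perfect_fit_nll(n: int, resid_sd: float = 0.1) -> float:
    """The nll floor when predictions equal observations exactly:
    -n * ln(1 / (sigma * sqrt(2 pi)))."""
    return -n * np.log(1.0 / (resid_sd * np.sqrt(2.0 * np.pi)))
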