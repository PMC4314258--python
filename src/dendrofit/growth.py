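"""The LG5 (five-parameter logistic / Richards) growth function.

The curve models cumulative stem diameter (DBH, cm) over the growing
season as a monotone sigmoid

    D(t) = L + (K - L) * [1 + (1/theta) * exp(-r * (t - doy_ip))]^(-theta)

with lower and upper asymptotes ``L`` and ``K`` (cm), inflection day
``doy_ip`` (real-valued day of year), rate ``r`` (day^-1) and asymmetry
``theta`` (dimensionless).  At ``theta = 1`` the curve is the symmetric
logistic; the inflection — the day of fastest growth — sits exactly at
``doy_ip`` for every ``theta``.  The derivative and inverse are closed
form, which downstream phenology and season-bound estimation rely on.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "LG5Params",
    "lg5_predict",
    "lg5_derivative",
    "lg5_inverse",
    "max_slope",
]


class LG5Params(NamedTuple):
    """The five growth-curve parameters.

    L : lower asymptote (cm)
    K : upper asymptote (cm); must exceed L
    doy_ip : inflection day (real-valued day of year)
    r : rate parameter (day^-1), > 0
    theta : asymmetry parameter (dimensionless), > 0
    """

    L: float
    K: float
    doy_ip: float
    r: float
    theta: float

    def validate(self) -> "LG5Params":
        if not np.all(np.isfinite(self)):
            raise ValueError(f"non-finite LG5 parameters: {self}")
        if self.K <= self.L:
            raise ValueError(f"upper asymptote K={self.K} must exceed L={self.L}")
        if self.r <= 0:
            raise ValueError(f"rate r={self.r} must be positive")
        if self.theta <= 0:
            raise ValueError(f"asymmetry theta={self.theta} must be positive")
        return self

    def is_valid(self) -> bool:
        return (
            bool(np.all(np.isfinite(self)))
            and self.K > self.L
            and self.r > 0
            and self.theta > 0
        )


def _as_params(params: Iterable[float]) -> LG5Params:
    p = LG5Params(*np.asarray(params, dtype=float))
    return p.validate()


def lg5_predict(params: Iterable[float], t) -> np.ndarray:
    """Predicted DBH (cm) at day(s) ``t``.

    Strictly increasing in ``t`` with ``L < D(t) < K`` for finite ``t``.
    """
    L, K, doy_ip, r, theta = _as_params(params)
    t = np.asarray(t, dtype=float)
    # u = (1/theta) exp(-r (t - doy_ip)); computed in log space to avoid
    # overflow far before the season start.
    log_u = -r * (t - doy_ip) - np.log(theta)
    return L + (K - L) * np.exp(-theta * np.logaddexp(0.0, log_u))


def lg5_derivative(params: Iterable[float], t) -> np.ndarray:
    """Analytic growth rate dD/dt (cm day^-1); positive everywhere.

    With u = (1/theta) exp(-r (t - doy_ip)):
    D'(t) = (K - L) * theta * r * u * (1 + u)^(-theta-1),
    maximal at t = doy_ip where D' = (K - L) * r * (1 + 1/theta)^-(theta+1).
    """
    L, K, doy_ip, r, theta = _as_params(params)
    t = np.asarray(t, dtype=float)
    log_u = -r * (t - doy_ip) - np.log(theta)
    log_1pu = np.logaddexp(0.0, log_u)
    return (K - L) * theta * r * np.exp(log_u - (theta + 1.0) * log_1pu)


def lg5_inverse(params: Iterable[float], y) -> np.ndarray:
    """Day at which the curve attains diameter ``y`` (must lie in (L, K)).

    Closed form: t = doy_ip - (1/r) * ln[theta * (((y-L)/(K-L))^(-1/theta) - 1)].
    """
    L, K, doy_ip, r, theta = _as_params(params)
    y = np.asarray(y, dtype=float)
    if np.any(y <= L) or np.any(y >= K):
        raise ValueError(
            f"diameter outside the open interval (L, K) = ({L}, {K}) has no finite preimage"
        )
    # frac^(-1/theta) - 1 = expm1(-log(frac)/theta); log(frac) computed via
    # log1p near 1 (y -> K) and plain log near 0 (y -> L) to keep precision
    # at both asymptotes
    frac = (y - L) / (K - L)
    with np.errstate(divide="ignore"):
        log_frac = np.where(frac < 0.5, np.log(frac), np.log1p((y - K) / (K - L)))
    return doy_ip - (np.log(theta) + np.log(np.expm1(-log_frac / theta))) / r


def max_slope(params: Iterable[float]) -> float:
    """Analytic maximum of the growth rate, attained at t = doy_ip."""
    L, K, _, r, theta = _as_params(params)
    return (K - L) * r * (1.0 + 1.0 / theta) ** (-(theta + 1.0))
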