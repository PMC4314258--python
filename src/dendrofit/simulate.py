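"""Seeded synthetic dendrometer series with known truth.

Emulates the measurement protocol behind the workflow: weekly caliper
readings over roughly days 110-300 of a temperate growing season,
sigmoid diameter growth of a few tenths of a cm, and Gaussian
observation noise at digital-caliper precision (0.003 cm, i.e. 0.03 mm
as two SDs of repeat measurements give).  Optional growth pauses model
drought responses as a *persistent* deficit: during a pause window a
fraction of the expected increment is simply not laid down and is never
recovered, so negative residuals mark halted allocation and later
positive residuals are only a return to trend.

The default truth (L=19.0, K=19.46 cm, doy_ip=170, r=0.06/day,
theta=1.5) mimics a 19-cm beech gaining 0.46 cm over the season.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth import LG5Params, lg5_predict
from .ingest import BandSeries

__all__ = ["Pause", "SimSpec", "simulate_tree", "simulate_stand", "write_truth_csv"]

DEFAULT_TRUTH = LG5Params(L=19.0, K=19.46, doy_ip=170.0, r=0.06, theta=1.5)


@dataclass(frozen=True)
class Pause:
    start_day: float
    length_days: float
    depth: float  # fraction of the expected increment lost, in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("pause depth must lie in [0, 1]")
        if self.length_days <= 0:
            raise ValueError("pause length must be positive")


@dataclass
class SimSpec:
    truth: LG5Params = DEFAULT_TRUTH
    bounds_truth: tuple[float, float] | None = None  # optional (a, b) clipping
    noise_sd: float = 0.003                          # cm, caliper precision
    sampling: np.ndarray = field(default_factory=lambda: np.arange(110, 301, 7))
    pauses: list[Pause] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.truth = LG5Params(*self.truth).validate()
        self.sampling = np.asarray(self.sampling, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bounds_truth is not None:
            a, b = self.bounds_truth
            if not (self.truth.L < a < b < self.truth.K):
                raise ValueError("bounds_truth must satisfy L < a < b < K")
        lo, hi = self.sampling.min(), self.sampling.max()
        for p in self.pauses:
            if not (lo <= p.start_day and p.start_day + p.length_days <= hi):
                raise ValueError("pause window must lie inside the sampling span")


def _expected(spec: SimSpec, t: np.ndarray) -> np.ndarray:
    d = lg5_predict(spec.truth, t)
    if spec.bounds_truth is not None:
        d = np.clip(d, *spec.bounds_truth)
    return d


def _pause_deficit(spec: SimSpec, t: np.ndarray) -> np.ndarray:
    """Lost growth by day t: depth x (expected increment over the elapsed
    part of each pause window); accumulates during the window and persists."""
    deficit = np.zeros_like(t, dtype=float)
    for p in spec.pauses:
        upto = np.minimum(t, p.start_day + p.length_days)
        active = upto > p.start_day
        gained = _expected(spec, np.maximum(upto, p.start_day)) - _expected(
            spec, np.full_like(t, p.start_day)
        )
        deficit += np.where(active, p.depth * gained, 0.0)
    return deficit


def simulate_tree(spec: SimSpec, tree_id: str = "sim-1", year: int = 2010) -> BandSeries:
    """One tree-year: clipped LG5 truth minus pause deficits plus noise;
    identical seed gives an identical series."""
    rng = np.random.default_rng(spec.seed)
    t = spec.sampling
    dbh = _expected(spec, t) - _pause_deficit(spec, t) + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return BandSeries(tree_id=tree_id, year=year, doy=t.copy(), dbh=dbh)


def simulate_stand(
    n_trees: int,
    template: SimSpec | None = None,
    shared_pauses: bool = True,
    seed: int = 0,
) -> tuple[list[BandSeries], list[SimSpec]]:
    """A stand of trees with jittered truths and (optionally) synchronized
    pauses; returns the series together with each tree's true spec.

    Per-tree truths jitter r and theta by +/-10% and shift L by +/-0.2 cm
    with K - L preserved; sub-seeds derive deterministically from ``seed``.
    """
    if n_trees < 2:
        raise ValueError("a stand needs at least two trees")
    template = template or SimSpec(seed=seed)
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=n_trees)
    series: list[BandSeries] = []
    specs: list[SimSpec] = []
    for i in range(n_trees):
        jit = np.random.default_rng(sub_seeds[i] + 1)
        tr = template.truth
        dL = jit.uniform(-0.2, 0.2)
        truth = LG5Params(
            L=tr.L + dL,
            K=tr.K + dL,  # K - L preserved
            doy_ip=tr.doy_ip,
            r=tr.r * (1.0 + jit.uniform(-0.1, 0.1)),
            theta=tr.theta * (1.0 + jit.uniform(-0.1, 0.1)),
        )
        bt = template.bounds_truth
        if bt is not None:
            bt = (bt[0] + dL, bt[1] + dL)
        spec = replace(
            template,
            truth=truth,
            bounds_truth=bt,
            pauses=list(template.pauses) if shared_pauses else [],
            seed=int(sub_seeds[i]),
        )
        series.append(simulate_tree(spec, tree_id=f"sim-{i + 1}"))
        specs.append(spec)
    return series, specs


def write_truth_csv(specs: list[SimSpec], path) -> None:
    """Sidecar of per-tree true parameters, bounds and pause windows."""
    rows = []
    for i, s in enumerate(specs):
        row = {
            "tree_id": f"sim-{i + 1}",
            "L": s.truth.L, "K": s.truth.K, "doy_ip": s.truth.doy_ip,
            "r": s.truth.r, "theta": s.truth.theta,
            "a": s.bounds_truth[0] if s.bounds_truth else np.nan,
            "b": s.bounds_truth[1] if s.bounds_truth else np.nan,
            "noise_sd": s.noise_sd,
            "seed": s.seed,
            "pauses": ";".join(f"{p.start_day}+{p.length_days}@{p.depth}" for p in s.pauses),
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
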