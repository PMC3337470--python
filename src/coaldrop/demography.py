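"""Piecewise-linear effective-population-size histories.

Time is measured in generations before present (t = 0 is the most recent
generation of the ancestral population).  Ne(t) interpolates linearly
between anchors and is constant beyond the last anchor, so the coalescence
rate is always bounded away from zero and waiting-time draws terminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NeTrajectory",
    "ne_at",
    "integrated_inverse_ne",
    "cumulative_inverse_ne",
    "time_for_integral",
    "draw_waiting_time",
    "CATTLE_NE",
]

_SLOPE_EPS = 1e-14


@dataclass(frozen=True)
class NeTrajectory:
    """Effective population size as a piecewise-linear function of time.

    Parameters
    ----------
    times
        Anchor times in generations before present, strictly increasing,
        starting at 0.
    sizes
        Effective population size at each anchor; all positive.
    """

    times: tuple[float, ...]
    sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.sizes) or not self.times:
            raise ValueError("times and sizes must be equal-length and non-empty")
        if self.times[0] != 0:
            raise ValueError("first anchor time must be 0")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("anchor times must be strictly increasing")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("all Ne values must be positive")

    @classmethod
    def from_anchors(
        cls, anchors: Iterable[tuple[float, float]], generation_interval: float = 1.0
    ) -> "NeTrajectory":
        """Build from (time, Ne) pairs; times are divided by the generation
        interval (anchors given in years convert to generations)."""
        pairs = sorted(anchors)
        if generation_interval <= 0:
            raise ValueError("generation_interval must be positive")
        times = tuple(t / generation_interval for t, _ in pairs)
        sizes = tuple(float(s) for _, s in pairs)
        return cls(times, sizes)

    def anchors(self) -> list[tuple[float, float]]:
        return list(zip(self.times, self.sizes))


def ne_at(traj: NeTrajectory, t):
    """Ne(t): linear interpolation between anchors, constant past the last.

    Accepts a scalar or array; negative times are a domain error.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time before present must be non-negative")
    out = np.interp(arr, traj.times, traj.sizes)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def _segment_integral(n0: float, n1: float, dt: float) -> float:
    # closed-form integral of 1/Ne over one linear piece of length dt
    if dt <= 0:
        return 0.0
    m = (n1 - n0) / dt
    if abs(m) < _SLOPE_EPS * max(n0, n1):
        return dt / n0
    return math.log(n1 / n0) / m


def integrated_inverse_ne(traj: NeTrajectory, t0: float, t1: float) -> float:
    """Return the integral of dt / Ne(t) over [t0, t1].

    On a linear piece with slope m this is log(Ne(t1)/Ne(t0)) / m; on flat
    pieces it reduces to (t1 - t0) / Ne.
    """
    if t0 < 0:
        raise ValueError("t0 must be non-negative")
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    if t1 == t0:
        return 0.0
    cuts = [t for t in traj.times if t0 < t < t1]
    grid = [t0, *cuts, t1]
    total = 0.0
    for a, b in zip(grid[:-1], grid[1:]):
        total += _segment_integral(ne_at(traj, a), ne_at(traj, b), b - a)
    return total


@lru_cache(maxsize=64)
def _anchor_tables(traj: NeTrajectory):
    """Vectorization tables: anchor times/sizes/slopes and the cumulative
    integral of 1/Ne at each anchor."""
    times = np.asarray(traj.times)
    sizes = np.asarray(traj.sizes)
    cum = np.zeros(times.size)
    for i in range(times.size - 1):
        cum[i + 1] = cum[i] + _segment_integral(
            sizes[i], sizes[i + 1], times[i + 1] - times[i]
        )
    slopes = np.zeros(times.size)
    if times.size > 1:
        slopes[:-1] = np.diff(sizes) / np.diff(times)
    return times, sizes, slopes, cum


def cumulative_inverse_ne(traj: NeTrajectory, t) -> np.ndarray:
    """Vectorized integral of 1/Ne over [0, t] for an array of times."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time before present must be non-negative")
    times, sizes, slopes, cum = _anchor_tables(traj)
    idx = np.minimum(np.searchsorted(times, t, side="right") - 1, times.size - 1)
    dt = t - times[idx]
    n0 = sizes[idx]
    m = slopes[idx]
    flat = np.abs(m) < _SLOPE_EPS * n0
    with np.errstate(divide="ignore", invalid="ignore"):
        sloped = np.log1p(m * dt / n0) / m
    return cum[idx] + np.where(flat, dt / n0, sloped)


def time_for_integral(traj: NeTrajectory, t0: float, target: float) -> float:
    """Return t1 >= t0 such that the integral of 1/Ne over [t0, t1] equals
    ``target``.  Inverse of :func:`integrated_inverse_ne` in its second
    endpoint; always solvable because Ne is bounded above.
    """
    if target < 0:
        raise ValueError("target integral must be non-negative")
    if target == 0:
        return t0
    t = t0
    remaining = target
    times = traj.times
    # walk the anchor segments that lie above t
    for i in range(len(times)):
        if times[i] <= t:
            continue
        seg_end = times[i]
        cap = _segment_integral(ne_at(traj, t), ne_at(traj, seg_end), seg_end - t)
        if remaining <= cap:
            return _invert_on_segment(traj, t, seg_end, remaining)
        remaining -= cap
        t = seg_end
    # beyond the last anchor Ne is constant
    return t + remaining * traj.sizes[-1]


def _invert_on_segment(traj: NeTrajectory, a: float, b: float, target: float) -> float:
    na = ne_at(traj, a)
    nb = ne_at(traj, b)
    m = (nb - na) / (b - a)
    if abs(m) < _SLOPE_EPS * max(na, nb):
        return a + target * na
    return a + na * math.expm1(m * target) / m


def draw_waiting_time(
    traj: NeTrajectory, t_now: float, pair_rate: float, rng: np.random.Generator
) -> float:
    """Draw the waiting time to the next coalescence under Ne(t).

    The hazard at time t is ``pair_rate / (2 Ne(t))`` (diploid Wright-Fisher
    pair rate 1/(2Ne)); the waiting time is obtained by inverting the
    integrated hazard against a standard-exponential draw.
    """
    if t_now < 0:
        raise ValueError("t_now must be non-negative")
    if pair_rate < 1:
        raise ValueError("pair_rate must be >= 1")
    u = rng.exponential()
    return time_for_integral(traj, t_now, 2.0 * u / pair_rate) - t_now


#: Default declining-Ne history typical of an intensively selected cattle
#: population: 100 now, 1256 at 1000, 4350 at 10,000 and 43,500 at 100,000
#: generations before present, linear in between, constant beyond.
CATTLE_NE = NeTrajectory(
    times=(0.0, 1000.0, 10_000.0, 100_000.0),
    sizes=(100.0, 1256.0, 4350.0, 43_500.0),
)
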