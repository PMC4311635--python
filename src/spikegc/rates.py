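"""Continuous instantaneous firing rates from discrete spike trains.

A spike train is converted into a continuous rate series in three steps:

1. the piecewise rate ``r(t) = 1/ISI`` on each interspike interval;
2. the local average rate ``f(t) = (1/dT) * integral of r over [t, t+dT]``
   with ``dT = delta * mean ISI`` of the train (``delta`` defaults to 0.25,
   keeping the averaging window much smaller than the mean ISI);
3. smoothing: a shape-preserving piecewise-cubic interpolant (PCHIP)
   through ``f`` knots spaced ``dT`` apart, evaluated on a uniform grid
   and clamped at zero.

The resulting per-trial rate matrix (neurons x samples) feeds both the
non-negative factorization and the sliding-window connectivity stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "RateSeries",
    "RateMatrix",
    "WindowSpec",
    "piecewise_rate",
    "instantaneous_rate",
    "build_rate_matrix",
    "sliding_windows",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one neuron within one trial."""

    neuron_id: int | str
    times: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError(
                    f"neuron {self.neuron_id}: spike times must be strictly increasing"
                )
            if times[0] < self.t_start - 1e-12 or times[-1] > self.t_end + 1e-12:
                raise ValueError(
                    f"neuron {self.neuron_id}: spikes outside trial bounds "
                    f"[{self.t_start}, {self.t_end}]"
                )
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def shifted(self, delta: float) -> "SpikeTrain":
        return SpikeTrain(
            self.neuron_id, self.times + delta, self.t_start + delta, self.t_end + delta
        )


@dataclass(frozen=True)
class RateSeries:
    """Non-negative instantaneous firing rate (spikes/s) on a uniform grid."""

    neuron_id: int | str
    grid_t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise ValueError("rate values must be finite")
        if np.any(values < 0):
            raise ValueError("rate values must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.grid_t0 + self.dt * np.arange(self.values.size)


@dataclass(frozen=True)
class RateMatrix:
    """m neurons x n samples of non-negative rate on one common grid."""

    neuron_ids: list
    grid_t0: float
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "neuron_ids", list(self.neuron_ids))
        if values.ndim != 2 or values.shape[0] != len(self.neuron_ids):
            raise ValueError("values must be (len(neuron_ids), n_samples)")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.grid_t0 + self.dt * np.arange(self.n_samples)

    @property
    def duration(self) -> float:
        return self.dt * (self.n_samples - 1)


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry: 0.5-s windows advanced in 0.125-s steps."""

    width: float = 0.5
    step: float = 0.125

    def __post_init__(self):
        if not (0 < self.step <= self.width):
            raise ValueError("require 0 < step <= width")


def piecewise_rate(train: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
    """Step-function rate 1/ISI on each interspike interval.

    Returns ``(breaks, rates)`` where ``rates[k]`` holds on
    ``[breaks[k], breaks[k+1])``. Requires at least two spikes.
    """
    if train.n_spikes < 2:
        raise ValueError("piecewise rate needs >= 2 spikes")
    isi = np.diff(train.times)
    return train.times.copy(), 1.0 / isi


def _local_average_rate(times: np.ndarray, d_t: float, at: np.ndarray) -> np.ndarray:
    """Mean of the step rate over a centered full-width d_t window.

    The cumulative integral of the step rate through spike ``i`` equals
    ``i`` spikes, so it is piecewise linear with knots ``(times, 0..K-1)``.
    Windows near the span's ends are shifted inward so they never collapse
    (the spiking span always exceeds d_t for d_t a fraction of the mean ISI);
    centering keeps the boundary mass loss symmetric and small.
    """
    counts = np.arange(times.size, dtype=float)
    lo = np.clip(at - d_t / 2, times[0], times[-1] - d_t)
    hi = lo + d_t
    return (np.interp(hi, times, counts) - np.interp(lo, times, counts)) / d_t


def instantaneous_rate(
    train: SpikeTrain, delta: float = 0.25, dt: float = 0.01
) -> RateSeries:
    """Continuous instantaneous firing rate of one spike train.

    Parameters
    ----------
    train : SpikeTrain
    delta : averaging window as a fraction of the train's mean ISI.
    dt : output grid spacing in seconds.

    Trains with fewer than three spikes cannot support the interpolated
    construction; they fall back to a constant rate ``n_spikes/duration``
    (logged), keeping every neuron representable in the rate matrix.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (0 < delta < 1):
        raise ValueError("delta must lie in (0, 1)")
    n = int(np.floor((train.t_end - train.t_start) / dt + 1e-9)) + 1
    grid = train.t_start + dt * np.arange(n)

    if train.n_spikes < 3:
        rate = train.n_spikes / (train.t_end - train.t_start)
        logger.warning(
            "neuron %s: %d spike(s) < 3, using constant-rate fallback %.3f Hz",
            train.neuron_id, train.n_spikes, rate,
        )
        return RateSeries(train.neuron_id, train.t_start, dt, np.full(n, rate))

    times = train.times
    mean_isi = float(np.mean(np.diff(times)))
    d_t = delta * mean_isi

    # f is piecewise linear with corners half a window on either side of each
    # spike (the cumulative spike-count integral is piecewise linear), so
    # knots at exactly those corners let the interpolant carry f's full mass
    knots_t = np.unique(np.concatenate([times, times - d_t / 2, times + d_t / 2]))
    knots_t = knots_t[(knots_t >= times[0]) & (knots_t <= times[-1])]
    knots_f = _local_average_rate(times, d_t, knots_t)

    spline = PchipInterpolator(knots_t, knots_f)
    values = np.empty(n)
    inside = (grid >= knots_t[0]) & (grid <= knots_t[-1])
    values[inside] = spline(grid[inside])
    # Before the first / after the last spike the rate is held at the nearest
    # knot value, capped so each empty edge gap carries at most half a spike
    # of mass: the interspike intervals integrate to K-1 spikes and the
    # boundary spikes own the remaining mass, which keeps the trial integral
    # consistent with the spike count.
    head_gap = times[0] - train.t_start
    tail_gap = train.t_end - times[-1]
    head = knots_f[0] if head_gap <= 0 else min(knots_f[0], 0.5 / head_gap)
    tail = knots_f[-1] if tail_gap <= 0 else min(knots_f[-1], 0.5 / tail_gap)
    values[grid < knots_t[0]] = head
    values[grid > knots_t[-1]] = tail
    np.maximum(values, 0.0, out=values)
    return RateSeries(train.neuron_id, train.t_start, dt, values)


def build_rate_matrix(
    trains: list[SpikeTrain], dt: float = 0.01, delta: float = 0.25
) -> RateMatrix:
    """Stack per-neuron rate series (input order preserved) on a common grid."""
    if not trains:
        raise ValueError("need at least one spike train")
    t0, t1 = trains[0].t_start, trains[0].t_end
    for tr in trains:
        if abs(tr.t_start - t0) > 1e-9 or abs(tr.t_end - t1) > 1e-9:
            raise ValueError(
                f"neuron {tr.neuron_id}: trial bounds ({tr.t_start}, {tr.t_end}) "
                f"differ from ({t0}, {t1})"
            )
    series = [instantaneous_rate(tr, delta=delta, dt=dt) for tr in trains]
    values = np.vstack([s.values for s in series])
    return RateMatrix([tr.neuron_id for tr in trains], t0, dt, values)


def sliding_windows(
    matrix: RateMatrix, spec: WindowSpec = WindowSpec(), rt: float | None = None
) -> list[tuple[float, np.ndarray]]:
    """Half-open moving windows over a rate matrix.

    Windows cover ``[start, start+width)``, starting at the grid origin and
    advancing by ``spec.step`` while the window fits inside the trial.
    Returns ``(center, submatrix)`` pairs; centers are reported relative to
    ``rt`` when given (the trial's reference time).
    """
    t0 = matrix.grid_t0
    t_end = t0 + matrix.duration
    if matrix.duration + 1e-9 < spec.width:
        warnings.warn("trial shorter than window width: no windows emitted")
        return []
    times = matrix.times
    out = []
    k = 0
    while True:
        start = t0 + k * spec.step
        if start + spec.width > t_end + 1e-9:
            break
        mask = (times >= start - 1e-12) & (times < start + spec.width - 1e-12)
        center = start + spec.width / 2 - (rt if rt is not None else 0.0)
        out.append((center, matrix.values[:, mask]))
        k += 1
    return out
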