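"""Shared containers and numerics for dynamic-imaging kinetic analysis.

This module holds the two sampling containers every other module speaks in —
:class:`FrameSchedule` (when each dynamic frame was acquired) and
:class:`TimeActivityCurve` (concentration vs. time) — plus the fine-grid
convolution engine used by both the PET and CT-perfusion forward models.

Conventions
-----------
* All times are in **seconds**; rate constants elsewhere in the package are
  per-minute (as conventionally printed), converted internally.
* Dynamic measurements are *frame averages*: the model value reported for a
  frame is the time-average of the instantaneous curve over that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "ConvolutionGrid",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered acquisition intervals of a dynamic scan.

    Parameters
    ----------
    start, end
        Per-frame start/end times in seconds.  Starts must be strictly
        increasing and frames must never overlap (contiguous or gapped is
        fine).
    """

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("start/end must be equal-length 1-D arrays")
        if not np.all(end > start):
            raise ValueError("every frame must have end > start")
        if start.size > 1:
            if not np.all(np.diff(start) > 0):
                raise ValueError("frame starts must be strictly increasing")
            if np.any(start[1:] < end[:-1] - 1e-9):
                raise ValueError("frames must not overlap")

    @classmethod
    def from_durations(cls, durations: Sequence[float], t_first: float = 0.0) -> "FrameSchedule":
        """Contiguous schedule from a list of frame durations (seconds)."""
        d = np.asarray(durations, dtype=float)
        edges = t_first + np.concatenate([[0.0], np.cumsum(d)])
        return cls(start=edges[:-1], end=edges[1:])

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def duration(self) -> np.ndarray:
        """Frame durations in seconds."""
        return self.end - self.start

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times in seconds."""
        return 0.5 * (self.start + self.end)

    @property
    def span_end(self) -> float:
        return float(self.end[-1])

    def to_csv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, np.column_stack([self.start, self.end]),
                   delimiter=",", header="start_s,end_s", comments="")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "FrameSchedule":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(start=arr[:, 0], end=arr[:, 1])


@dataclass(frozen=True)
class TimeActivityCurve:
    """A sampled concentration-vs-time series.

    ``times`` are in seconds and must be non-decreasing; ``values`` carry
    whatever concentration unit the context defines (``units`` is a free-form
    label).  Linear interpolation with zero extension to the left is used
    when a curve is evaluated off its samples.
    """

    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise ValueError("times/values must be equal-length 1-D arrays")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be sorted")

    def __call__(self, t: Union[float, np.ndarray]) -> np.ndarray:
        return np.interp(t, self.times, self.values, left=0.0, right=self.values[-1])

    @property
    def span_end(self) -> float:
        return float(self.times[-1])

    def to_csv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter=",", header="time_s,value", comments="")

    @classmethod
    def from_csv(cls, path: Union[str, Path], units: str = "") -> "TimeActivityCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(times=arr[:, 0], values=arr[:, 1], units=units)


# ---------------------------------------------------------------------------
# Fast convolution on a fine uniform grid
# ---------------------------------------------------------------------------

def _expconv(lam: float, a: np.ndarray, dt: float) -> np.ndarray:
    """Convolution of a piecewise-linear signal with ``exp(-lam*t)``.

    Exact for the piecewise-linear interpolant of ``a`` on a uniform grid of
    spacing ``dt``; evaluated in O(n) through a first-order recursion
    (realised with :func:`scipy.signal.lfilter`).  ``lam`` is per the same
    time unit as ``dt``.  ``lam == 0`` degenerates to the running integral.
    """
    a = np.asarray(a, dtype=float)
    n = a.size
    if n < 2:
        return np.zeros_like(a)
    u = lam * dt
    if u < 1e-12:
        return cumulative_trapezoid(a, dx=dt, initial=0.0)
    E = np.exp(-u)
    # interval contribution: I = a0*(P - Q) + a1*Q with
    #   P = (1 - E)/lam,  Q = (u - 1 + E)/(lam*u)
    P = -np.expm1(-u) / lam
    if u < 1e-3:  # series for u - 1 + e^-u to dodge cancellation
        Q = dt * (0.5 - u / 6.0 + u * u / 24.0)
    else:
        Q = (u - 1.0 + E) / (lam * u)
    c = a[:-1] * (P - Q) + a[1:] * Q
    out = np.empty(n)
    out[0] = 0.0
    out[1:] = lfilter([1.0], [1.0, -E], c)
    return out


class ConvolutionGrid:
    """Fine uniform time grid bound to a schedule and an arterial input.

    Precomputes the input samples, their running integral and the
    frame-averaging weights so that repeated forward-model evaluations during
    fitting cost a handful of O(n) passes each.

    Parameters
    ----------
    schedule
        Frames over which model output is averaged.
    aif
        Arterial input as a :class:`TimeActivityCurve` or a callable of time
        (seconds).  A sampled curve must cover the schedule span.
    dt
        Grid spacing in seconds.  If omitted, the coarsest of
        ``0.5, 0.25, 0.2, 0.1`` that lands every frame boundary on the grid
        is chosen.
    """

    def __init__(self, schedule: FrameSchedule,
                 aif: Union[TimeActivityCurve, Callable[[np.ndarray], np.ndarray]],
                 dt: float | None = None) -> None:
        if isinstance(aif, TimeActivityCurve) and aif.span_end < schedule.span_end - 1e-6:
            raise ValueError(
                f"schedule extends to {schedule.span_end:g} s but the AIF is only "
                f"sampled to {aif.span_end:g} s")
        if dt is None:
            dt = self._choose_dt(schedule)
        self.dt = float(dt)
        self.schedule = schedule
        n = int(round(schedule.span_end / dt)) + 1
        self.t = np.arange(n) * dt
        self.a = np.asarray(aif(self.t), dtype=float)
        self.a_cumint = cumulative_trapezoid(self.a, dx=dt, initial=0.0)
        self._frame_w = self._frame_weights(schedule, self.t, dt)
        self._exp_cache: dict[float, np.ndarray] = {}

    @staticmethod
    def _choose_dt(schedule: FrameSchedule) -> float:
        edges = np.concatenate([schedule.start, schedule.end])
        for cand in (0.5, 0.25, 0.2, 0.1):
            if np.allclose(np.round(edges / cand) * cand, edges, atol=1e-6):
                return cand
        return 0.1

    @staticmethod
    def _frame_weights(schedule: FrameSchedule, t: np.ndarray, dt: float) -> np.ndarray:
        """(n_frames, n_grid) trapezoid frame-averaging matrix."""
        W = np.zeros((schedule.n_frames, t.size))
        for k, (s, e) in enumerate(zip(schedule.start, schedule.end)):
            i0 = int(round(s / dt))
            i1 = int(round(e / dt))
            if not (abs(i0 * dt - s) < 1e-6 and abs(i1 * dt - e) < 1e-6):
                # boundary off-grid: snap (documented; sub-dt discrepancy)
                i0, i1 = int(np.floor(s / dt)), int(np.ceil(e / dt))
            i1 = min(i1, t.size - 1)
            w = np.full(i1 - i0 + 1, dt)
            w[0] = w[-1] = dt / 2.0
            W[k, i0:i1 + 1] = w / w.sum()
        return W

    # -- building blocks for impulse-response convolutions ------------------

    def shifted(self, y: np.ndarray, delay: float) -> np.ndarray:
        """Evaluate a grid-sampled function at ``t - delay`` (zero before 0)."""
        if delay == 0.0:
            return y
        return np.interp(self.t - delay, self.t, y, left=0.0)

    def box(self, d0: float, d1: float) -> np.ndarray:
        """Convolution of the input with a unit box on ``[d0, d1)`` (seconds)."""
        hi = np.interp(self.t - d0, self.t, self.a_cumint, left=0.0)
        lo = np.interp(self.t - d1, self.t, self.a_cumint, left=0.0)
        return hi - lo

    def expdecay(self, lam_per_s: float, delay: float = 0.0) -> np.ndarray:
        """Convolution of the input with ``exp(-lam*(t-delay))`` for t>=delay."""
        key = round(float(lam_per_s), 12)
        y = self._exp_cache.get(key)
        if y is None:
            y = _expconv(lam_per_s, self.a, self.dt)
            if len(self._exp_cache) < 64:
                self._exp_cache[key] = y
        return self.shifted(y, delay)

    def frame_average(self, y: np.ndarray) -> np.ndarray:
        """Average a grid-sampled curve over each frame of the schedule."""
        return self._frame_w @ y
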