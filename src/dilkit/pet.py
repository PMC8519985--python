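"""Flow-modified two-tissue-compartment (F2TC) model for dynamic PSMA-PET.

The F2TC impulse residue function prepends an explicit vascular delivery
phase to the reversible two-tissue compartment model: tracer arriving at
``t0`` transits the vasculature for a window ``W`` at flow ``F``, after which
exchange with the free and bound tissue compartments is governed by the rate
constants ``K1`` (influx, mL/min/g), ``k2`` (efflux, 1/min), ``k3`` (binding,
1/min) and ``k4`` (dissociation, 1/min):

    H(t) = 0                                   t < t0
    H(t) = F                                   t0 <= t < t0 + W
    H(t) = K1 * [ (k3+k4-a) e^{-a t'} + (b-k3-k4) e^{-b t'} ] / (b - a)

with ``t' = t - t0 - W`` and ``a, b = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 -
4 k2 k4)]/2``.  A measured tissue curve is the frame-averaged convolution of
the arterial input with ``H``.

Derived quantities follow the standard identities: net uptake rate constant
``Ki = K1 k3/(k2+k3)`` and distribution volume ``DV = (K1/k2)(1 + k3/k4)``
(the vascular window contributes ``F*W`` of tracer-residence area but is
excluded from DV, which describes the exchangeable compartments only).

Times in this module are in seconds (``W``, ``t0``, schedules); rate
constants are per-minute as conventionally printed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Callable, Union

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.stats import qmc

from .core import ConvolutionGrid, FrameSchedule, TimeActivityCurve

__all__ = [
    "F2TCParams", "FitOptions", "FitResult",
    "f2tc_irf", "f2tc_forward", "fit_f2tc",
    "ki_of", "dv_of", "suv", "suv_early",
]


@dataclass(frozen=True)
class F2TCParams:
    """F2TC kinetic parameter vector.

    F : blood flow, mL/min/g.  W : vascular transit window, seconds.
    K1 : influx rate constant, mL/min/g (K1 <= F: single-pass extraction
    cannot exceed unity).  k2, k3, k4 : 1/min.  t0 : bolus arrival delay
    relative to the arterial input, seconds.
    """

    F: float
    W: float
    K1: float
    k2: float
    k3: float
    k4: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("F", "W", "K1", "k2", "k3", "k4", "t0"):
            v = getattr(self, name)
            if not (0 <= v < np.inf):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.K1 > self.F * (1 + 1e-9) + 1e-15:
            raise ValueError(f"K1 ({self.K1}) must not exceed F ({self.F})")


def _roots(k2: float, k3: float, k4: float) -> tuple[float, float]:
    """Eigenvalue pair (alpha <= beta, per-minute) of the tissue system."""
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    r = np.sqrt(max(disc, 0.0))
    return 0.5 * (s - r), 0.5 * (s + r)


def f2tc_irf(p: F2TCParams, t: Union[float, np.ndarray]) -> np.ndarray:
    """Impulse residue function H(t) in mL/min/g at time ``t`` (seconds).

    The repeated-eigenvalue case is handled by its analytic limit
    ``K1 e^{-a t'} (1 + (k3+k4-a) t')``.
    """
    t = np.asarray(t, dtype=float)
    tp_min = (t - p.t0 - p.W) / 60.0  # time past the vascular window, minutes
    alpha, beta = _roots(p.k2, p.k3, p.k4)
    if beta - alpha > 1e-10:
        wa = (p.k3 + p.k4 - alpha) / (beta - alpha)
        wb = (beta - p.k3 - p.k4) / (beta - alpha)
        tissue = p.K1 * (wa * np.exp(-alpha * np.clip(tp_min, 0, None))
                         + wb * np.exp(-beta * np.clip(tp_min, 0, None)))
    else:
        tc = np.clip(tp_min, 0, None)
        tissue = p.K1 * np.exp(-alpha * tc) * (1.0 + (p.k3 + p.k4 - alpha) * tc)
    out = np.where(t < p.t0, 0.0, np.where(tp_min < 0, p.F, tissue))
    return out


def f2tc_forward(p: F2TCParams,
                 aif: Union[TimeActivityCurve, Callable],
                 schedule: FrameSchedule,
                 dt: float | None = None,
                 grid: ConvolutionGrid | None = None) -> TimeActivityCurve:
    """Frame-averaged tissue curve: convolution of the AIF with the F2TC IRF.

    Returns a curve sampled at the frame mid-times whose values are the
    time-averages over each frame.  ``grid`` may carry a prebuilt
    :class:`ConvolutionGrid` (schedule + AIF) to amortise setup across many
    evaluations; otherwise one is built from ``aif``/``dt``.
    """
    if grid is None:
        grid = ConvolutionGrid(schedule, aif, dt)
    y = _f2tc_forward_grid(p, grid)
    return TimeActivityCurve(times=schedule.mid, values=grid.frame_average(y))


def _f2tc_forward_grid(p: F2TCParams, grid: ConvolutionGrid) -> np.ndarray:
    """Instantaneous tissue curve on the fine grid (before frame averaging)."""
    alpha, beta = _roots(p.k2, p.k3, p.k4)
    if beta - alpha < 1e-9:  # nudge off the (measure-zero) repeated root
        beta = alpha + 1e-9
    wa = (p.k3 + p.k4 - alpha) / (beta - alpha)
    wb = (beta - p.k3 - p.k4) / (beta - alpha)
    d = p.t0 + p.W
    y = p.K1 * (wa * grid.expdecay(alpha / 60.0, d) + wb * grid.expdecay(beta / 60.0, d))
    if p.W > 0:
        y = y + p.F * grid.box(p.t0, d)
    return y / 60.0  # rates are per-minute, grid time is seconds


def ki_of(p: F2TCParams) -> float:
    """Net uptake rate constant Ki = K1*k3/(k2+k3), mL/min/g."""
    if p.k2 + p.k3 <= 0:
        raise ValueError("Ki undefined when k2 + k3 = 0")
    return p.K1 * p.k3 / (p.k2 + p.k3)


def dv_of(p: F2TCParams) -> float:
    """Distribution volume DV = (K1/k2)*(1 + k3/k4), mL/g."""
    if p.k2 <= 0 or p.k4 <= 0:
        raise ValueError("DV undefined when k2 or k4 is zero")
    return (p.K1 / p.k2) * (1.0 + p.k3 / p.k4)


def suv(activity_conc, injected_mbq: float, weight_kg: float):
    """Standardized uptake value: concentration / (dose / body weight).

    ``activity_conc`` and the dose must share the activity unit (e.g. both
    MBq-based); with concentration in MBq/mL the result is in g/mL assuming
    1 g/mL tissue density.
    """
    if injected_mbq <= 0 or weight_kg <= 0:
        raise ValueError("injected dose and body weight must be positive")
    return np.asarray(activity_conc) / (injected_mbq / (weight_kg * 1000.0))


def suv_early(tac: TimeActivityCurve, schedule: FrameSchedule,
              injected_mbq: float, weight_kg: float) -> float:
    """Early SUV: mean of the final four frame values, as SUV.

    On the 28-frame 22-min schedule the final four frames are exactly those
    starting at >= 10 min post-injection.
    """
    if schedule.n_frames < 4:
        raise ValueError("need at least 4 frames for the early-SUV average")
    if tac.values.size != schedule.n_frames:
        raise ValueError("TAC length does not match the schedule")
    return float(suv(np.mean(tac.values[-4:]), injected_mbq, weight_kg))


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

# Variable projection: the model is linear in (F, K1), so only the shape
# parameters [W, t0, k2, k3, k4] are optimised nonlinearly; at each
# evaluation the amplitudes are solved by non-negative least squares in the
# basis {b1+b2, b1} (b1 = vascular box, b2 = tissue response), whose
# coefficients (K1, F-K1) make the K1 <= F constraint plain non-negativity.
_LO = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
_HI = np.array([30.0, 60.0, 3.0, 3.0, 3.0])
_X0 = np.array([10.0, 1.0, 0.5, 0.10, 0.10])
_XSCALE = np.array([10.0, 10.0, 1.0, 0.3, 0.3])
_AMP_MAX = 3.0  # mL/min/g bound on F and K1


@dataclass(frozen=True)
class FitOptions:
    """Options for the nonlinear least-squares estimators.

    ``n_starts`` Latin-hypercube initial points (seeded by ``seed``) are run
    in addition to one fixed mid-range start; the lowest-RSS solution wins.
    """

    n_starts: int = 5
    seed: int = 0
    xtol: float = 1e-10
    ftol: float = 1e-10
    max_nfev: int = 600


@dataclass(frozen=True)
class FitResult:
    """Outcome of a compartmental fit.

    ``converged`` False marks the parameters unreliable; ``degenerate``
    marks an (all-zero) input that was not meaningfully fit.  ``ki``/``dv``
    are the derived quantities of the fitted vector (``dv`` is None when
    undefined, i.e. k2 or k4 at zero).
    """

    params: F2TCParams
    ki: float | None
    dv: float | None
    rss: float
    converged: bool
    n_starts: int
    degenerate: bool = False

    def to_json(self, path: Union[str, Path]) -> None:
        d = {"params": asdict(self.params), "ki": self.ki, "dv": self.dv,
             "rss": self.rss, "converged": self.converged,
             "n_starts": self.n_starts, "degenerate": self.degenerate}
        Path(path).write_text(json.dumps(d, indent=2))


def _starts(lo: np.ndarray, hi: np.ndarray, x0: np.ndarray,
            n_starts: int, seed: int) -> np.ndarray:
    pts = [x0]
    if n_starts > 0:
        sampler = qmc.LatinHypercube(d=lo.size, seed=seed)
        u = sampler.random(n_starts)
        # keep starts off the exact bounds so no rate begins frozen at zero
        pts.append(lo + (0.05 + 0.85 * u) * (hi - lo))
    return np.vstack(pts) if n_starts > 0 else np.asarray(pts)


def fit_f2tc(tac: TimeActivityCurve,
             aif: Union[TimeActivityCurve, Callable],
             schedule: FrameSchedule,
             opts: FitOptions | None = None,
             grid: ConvolutionGrid | None = None) -> FitResult:
    """Weighted multi-start NLLS fit of the F2TC model to a tissue curve.

    Residuals are weighted by sqrt(frame duration), matching a noise
    variance inversely proportional to frame length.  The shape parameters
    (W in [0, 30] s, t0 in [0, 60] s, k2/k3/k4 in [0, 3] /min) are optimised
    by bounded multi-start trust-region least squares; at each evaluation
    the amplitudes F and K1 (capped at 3 mL/min/g, with K1 <= F) are
    profiled out by non-negative linear least squares (variable
    projection).
    """
    opts = opts or FitOptions()
    y = np.asarray(tac.values, dtype=float)
    if schedule.n_frames < 10:
        raise ValueError("need at least 10 frames to fit the F2TC model")
    if y.size != schedule.n_frames:
        raise ValueError("TAC length does not match the schedule")
    if np.max(np.abs(y)) == 0.0:
        zero = F2TCParams(0, 0, 0, 0, 0, 0, 0)
        return FitResult(zero, ki=0.0, dv=None, rss=0.0, converged=False,
                         n_starts=0, degenerate=True)

    if grid is None:
        grid = ConvolutionGrid(schedule, aif)
    sw = np.sqrt(schedule.duration / schedule.duration.mean())
    yw = y * sw

    def bases(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        W, t0, k2, k3, k4 = x
        alpha, beta = _roots(k2, k3, k4)
        if beta - alpha < 1e-9:
            beta = alpha + 1e-9
        wa = (k3 + k4 - alpha) / (beta - alpha)
        wb = (beta - k3 - k4) / (beta - alpha)
        d = t0 + W
        b2 = (wa * grid.expdecay(alpha / 60.0, d)
              + wb * grid.expdecay(beta / 60.0, d)) / 60.0
        b1 = grid.box(t0, d) / 60.0 if W > 0 else np.zeros_like(b2)
        return grid.frame_average(b1) * sw, grid.frame_average(b2) * sw

    def amplitudes(x: np.ndarray) -> tuple[float, float, np.ndarray]:
        b1, b2 = bases(x)
        A = np.column_stack([b1 + b2, b1])  # coefficients (K1, F - K1) >= 0
        coef, _ = nnls(A, yw)
        return float(coef[0]), float(coef[0] + coef[1]), A @ coef - yw

    def resid(x: np.ndarray) -> np.ndarray:
        return amplitudes(x)[2]

    best = None
    for x0 in _starts(_LO, _HI, _X0, opts.n_starts, opts.seed):
        try:
            sol = least_squares(resid, x0, bounds=(_LO, _HI), method="trf",
                                xtol=opts.xtol, ftol=opts.ftol, gtol=1e-12,
                                x_scale=_XSCALE, max_nfev=opts.max_nfev)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        zero = F2TCParams(0, 0, 0, 0, 0, 0, 0)
        return FitResult(zero, ki=None, dv=None, rss=np.inf, converged=False,
                         n_starts=opts.n_starts)
    k1, f, _ = amplitudes(best.x)
    k1, f = min(k1, _AMP_MAX), min(f, _AMP_MAX)
    W, t0, k2, k3, k4 = best.x
    p = F2TCParams(F=f, W=W, K1=min(k1, f), k2=k2, k3=k3, k4=k4, t0=t0)
    ki = ki_of(p) if p.k2 + p.k3 > 0 else None
    try:
        dv = dv_of(p)
    except ValueError:
        dv = None
    rss = float(2.0 * best.cost)
    return FitResult(p, ki=ki, dv=dv, rss=rss,
                     converged=bool(best.success and np.isfinite(rss)),
                     n_starts=opts.n_starts + 1)
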