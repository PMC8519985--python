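"""Adiabatic tissue-homogeneity (Johnson-Wilson) model for CT perfusion.

Dynamic contrast-enhanced CT is analysed by indicator-dilution
deconvolution: the tissue enhancement curve is ``BF * (AIF (*) R)``, with
the flow expressed per mL of tissue (BF/100, density 1 g/mL) so that tissue
and arterial curves share one concentration unit.  The impulse residue
function R of the adiabatic tissue-homogeneity model is

    R(t) = 0                                        t < T0
    R(t) = 1                                        T0 <= t < T0 + Tc
    R(t) = E * exp(-E*BF*(t - T0 - Tc)/(60*Ve))     otherwise

``BF`` is blood flow (mL/min/100 g), ``Tc`` the capillary transit time (s),
``E`` the extraction fraction, ``Ve`` the interstitial distribution volume
(mL/100 g) and ``T0`` the contrast arrival delay (s).  Derived maps follow
the central-volume and Crone-Renkin identities: BV = BF*Tc/60 (mL/100 g),
MTT = Tc (s) and PS = -BF*ln(1-E) (mL/min/100 g).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Union

import numpy as np
from scipy.optimize import least_squares

from .core import ConvolutionGrid, FrameSchedule, TimeActivityCurve
from .pet import FitOptions, _starts

__all__ = [
    "ATHParams", "ATHFitResult",
    "ath_irf", "ath_forward", "fit_ath",
    "bv_of", "mtt_of", "ps_of",
]


@dataclass(frozen=True)
class ATHParams:
    """Adiabatic tissue-homogeneity parameter vector (units in module doc)."""

    BF: float
    Tc: float
    E: float
    Ve: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("BF", "Tc", "Ve", "t0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.E < 1.0:
            raise ValueError(f"extraction fraction must be in [0, 1), got {self.E}")
        if self.E > 0 and self.Ve <= 0:
            raise ValueError("Ve must be positive when E > 0")


def ath_irf(p: ATHParams, t: Union[float, np.ndarray]) -> np.ndarray:
    """Impulse residue fraction R(t) at time ``t`` in seconds."""
    t = np.asarray(t, dtype=float)
    tp = t - p.t0 - p.Tc
    if p.E > 0:
        k = p.E * p.BF / (60.0 * p.Ve)  # per second
        tail = p.E * np.exp(-k * np.clip(tp, 0, None))
    else:
        tail = np.zeros_like(tp)
    return np.where(t < p.t0, 0.0, np.where(tp < 0, 1.0, tail))


def ath_forward(p: ATHParams,
                aif: Union[TimeActivityCurve, Callable],
                schedule: FrameSchedule,
                dt: float | None = None,
                grid: ConvolutionGrid | None = None) -> TimeActivityCurve:
    """Frame-averaged tissue enhancement: BF-scaled convolution with R."""
    if grid is None:
        grid = ConvolutionGrid(schedule, aif, dt)
    y = _ath_forward_grid(p, grid)
    return TimeActivityCurve(times=schedule.mid, values=grid.frame_average(y))


def _ath_forward_grid(p: ATHParams, grid: ConvolutionGrid) -> np.ndarray:
    d = p.t0 + p.Tc
    y = grid.box(p.t0, d) if p.Tc > 0 else np.zeros_like(grid.t)
    if p.E > 0:
        k = p.E * p.BF / (60.0 * p.Ve)
        y = y + p.E * grid.expdecay(k, d)
    # BF is mL/min/100 g: per-second and per-gram (density 1 g/mL) scaling
    return (p.BF / 6000.0) * y


def bv_of(p: ATHParams) -> float:
    """Blood volume BV = BF*Tc/60, mL/100 g (central-volume identity)."""
    return p.BF * p.Tc / 60.0


def mtt_of(p: ATHParams) -> float:
    """Mean transit time, defined here as the capillary transit time Tc (s)."""
    return p.Tc


def ps_of(bf: float, e: float) -> float:
    """Permeability-surface product PS = -BF*ln(1-E), mL/min/100 g."""
    if not 0.0 <= e < 1.0:
        raise ValueError("extraction fraction must be in [0, 1)")
    return -bf * np.log1p(-e)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

# Variable projection: BF is linear, so the nonlinear fit runs over
# [Tc, E, kadb, t0] where kadb = E*BF/(60*Ve) (1/s) is the interstitial
# washout rate; Ve is recovered from the fitted kadb and BF afterwards.
_LO = np.array([0.0, 0.0, 0.0, 0.0])
_HI = np.array([30.0, 0.95, 5.0, 20.0])
_X0 = np.array([8.0, 0.3, 0.02, 4.0])
_XSCALE = np.array([10.0, 0.3, 0.02, 5.0])
_BF_MAX = 300.0
_VE_BOUNDS = (1.0, 60.0)


@dataclass(frozen=True)
class ATHFitResult:
    """Fitted ATH parameters with derived BV/MTT/PS and diagnostics."""

    params: ATHParams
    bv: float
    mtt: float
    ps: float
    rss: float
    converged: bool
    n_starts: int
    degenerate: bool = False

    def to_json(self, path: Union[str, Path]) -> None:
        d = {"params": asdict(self.params), "bv": self.bv, "mtt": self.mtt,
             "ps": self.ps, "rss": self.rss, "converged": self.converged,
             "n_starts": self.n_starts, "degenerate": self.degenerate}
        Path(path).write_text(json.dumps(d, indent=2))


def fit_ath(curve: TimeActivityCurve,
            aif: Union[TimeActivityCurve, Callable],
            schedule: FrameSchedule,
            opts: FitOptions | None = None,
            grid: ConvolutionGrid | None = None) -> ATHFitResult:
    """Weighted multi-start NLLS fit of the ATH model to an enhancement curve.

    Bounds: BF in [0, 300] mL/min/100 g, Tc in [0, 30] s, E in [0, 0.95],
    Ve in [1, 60] mL/100 g, T0 in [0, 20] s.  Residual weighting, the
    multi-start strategy and the variable-projection treatment of the
    linear amplitude (BF) mirror the PET estimator.
    """
    opts = opts or FitOptions()
    y = np.asarray(curve.values, dtype=float)
    if y.size != schedule.n_frames:
        raise ValueError("curve length does not match the schedule")
    if np.max(np.abs(y)) == 0.0:
        zero = ATHParams(0, 0, 0, 1.0, 0)
        return ATHFitResult(zero, bv=0.0, mtt=0.0, ps=0.0, rss=0.0,
                            converged=False, n_starts=0, degenerate=True)
    if grid is None:
        grid = ConvolutionGrid(schedule, aif)
    sw = np.sqrt(schedule.duration / schedule.duration.mean())
    yw = y * sw

    def basis(x: np.ndarray) -> np.ndarray:
        tc, e, kadb, t0 = x
        d = t0 + tc
        b = grid.box(t0, d) if tc > 0 else np.zeros_like(grid.t)
        if e > 0:
            b = b + e * grid.expdecay(kadb, d)
        return grid.frame_average(b / 6000.0) * sw

    def amplitude(x: np.ndarray) -> tuple[float, np.ndarray]:
        b = basis(x)
        denom = float(b @ b)
        bf = max(float(b @ yw) / denom, 0.0) if denom > 0 else 0.0
        return bf, bf * b - yw

    def resid(x: np.ndarray) -> np.ndarray:
        return amplitude(x)[1]

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
        zero = ATHParams(0, 0, 0, 1.0, 0)
        return ATHFitResult(zero, 0.0, 0.0, 0.0, rss=np.inf, converged=False,
                            n_starts=opts.n_starts)
    bf, _ = amplitude(best.x)
    bf = min(bf, _BF_MAX)
    tc, e, kadb, t0 = best.x
    if e > 0 and kadb > 0 and bf > 0:
        ve = float(np.clip(e * bf / (60.0 * kadb), *_VE_BOUNDS))
    else:
        ve = _VE_BOUNDS[0]
    p = ATHParams(BF=bf, Tc=tc, E=e, Ve=ve, t0=t0)
    rss = float(2.0 * best.cost)
    return ATHFitResult(p, bv=bv_of(p), mtt=mtt_of(p), ps=ps_of(p.BF, p.E),
                        rss=rss, converged=bool(best.success and np.isfinite(rss)),
                        n_starts=opts.n_starts + 1)
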