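"""Digital-phantom simulation of the dynamic PET + CT-perfusion study.

The generators here stand in for the clinical acquisitions so that every
downstream stage — map fitting, screening, classification, cross-validation
— is testable without patient data.  They emulate the study conditions:

* the 28-frame, 22-min dynamic PET framing (11x10 s, 5x20 s, 4x40 s,
  4x60 s, 4x180 s) and the two-phase CT-perfusion sampling (2.8 s over the
  first minute, 15 s over the next two);
* lesion (DIL) vs non-lesion kinetic contrast anchored to the reported
  voxel-median parameter values of the two tissue classes;
* a 15-patient cohort whose pooled in-prostate voxel count at full
  geometry is close to the ~49k voxels of the study.

Two tiers of synthesis are provided.  ``simulate_study``/``make_cohort``
generate image-level phantoms (4-D dynamic volumes driven by the F2TC and
ATH forward models plus frame-weighted Gaussian noise) for exercising the
voxel-wise estimators.  ``simulate_voxel_table`` draws per-voxel parametric
feature values directly from class medians (patient, class and voxel-level
log-normal variation) for exercising the statistical selection machinery at
scale without per-voxel refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConvolutionGrid, FrameSchedule, TimeActivityCurve
from .ctp import ATHParams, _ath_forward_grid, bv_of, ps_of
from .pet import F2TCParams, _f2tc_forward_grid, dv_of, ki_of
from .stats import PARAM_NAMES, VoxelTable

__all__ = [
    "pet_frame_schedule", "ctp_frame_schedule",
    "AIFParams", "make_aif", "default_pet_aif_params", "default_ctp_aif_params",
    "f2tc_rates_from_macro", "extraction_from_ps",
    "dil_reference_f2tc", "nondil_reference_f2tc",
    "dil_reference_ath", "nondil_reference_ath",
    "TissueClassSpec", "reference_class_specs",
    "Geometry", "PhantomStudy", "simulate_study", "make_cohort",
    "DEFAULT_CLASS_MEDIANS", "class_medians_with_contrast",
    "simulate_voxel_table",
]

#: Cohort dosimetry defaults: injected activity (MBq) and body weight (kg).
INJECTED_MBQ = 325.0
WEIGHT_KG = 88.8

#: Reported class-median SUVs used to calibrate the synthetic activity scale.
_SUV_EARLY_DIL = 2.53
_SUV_LATE_DIL = 1.55
_SUV_LATE_NONDIL = 0.67

#: Late static acquisition window, seconds post-injection.
LATE_WINDOW = (7200.0, 8100.0)


def pet_frame_schedule() -> FrameSchedule:
    """The 28-frame 22-min dynamic PET schedule, starting at injection."""
    durations = [10.0] * 11 + [20.0] * 5 + [40.0] * 4 + [60.0] * 4 + [180.0] * 4
    return FrameSchedule.from_durations(durations)


def ctp_frame_schedule() -> FrameSchedule:
    """Two-phase 3-min CT-perfusion sampling: 2.8 s then 15 s intervals.

    Phase 1 holds 21 contiguous 2.8-s frames (to 58.8 s, the last multiple
    of 2.8 s within the first minute); phase 2 appends eight 15-s frames.
    """
    durations = [2.8] * 21 + [15.0] * 8
    return FrameSchedule.from_durations(durations)


# ---------------------------------------------------------------------------
# Arterial input functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AIFParams:
    """Parametric arterial input curve.

    ``model`` selects the functional form: ``"pet_bolus"`` is a
    tri-exponential bolus (linear-rise-times-exponential delivery term plus
    two washout exponentials); ``"ctp_bolus"`` is a gamma-variate contrast
    bolus with a delayed, scaled gamma-variate recirculation term.  The
    curve is identically zero before the arrival delay ``delay`` (s) and
    clamped non-negative.
    """

    model: str
    amplitudes: tuple
    rates: tuple
    delay: float
    recirc_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("pet_bolus", "ctp_bolus"):
            raise ValueError(f"unknown AIF model {self.model!r}")
        if any((not np.isfinite(r)) or r < 0 for r in self.rates):
            raise ValueError("AIF rate terms must be finite and non-negative")
        if any((not np.isfinite(a)) or a < 0 for a in self.amplitudes):
            raise ValueError("AIF amplitudes must be finite and non-negative")
        if self.delay < 0 or self.recirc_delay < 0:
            raise ValueError("delays must be non-negative")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tp = t - self.delay
        if self.model == "pet_bolus":
            a1, a2, a3 = self.amplitudes
            l1, l2, l3 = self.rates
            c = ((a1 * tp - a2 - a3) * np.exp(-l1 * np.clip(tp, 0, None))
                 + a2 * np.exp(-l2 * np.clip(tp, 0, None))
                 + a3 * np.exp(-l3 * np.clip(tp, 0, None)))
        else:
            a1, a2 = self.amplitudes
            al1, b1, al2, b2 = self.rates
            c = _gamma_variate(tp, a1, al1, b1)
            c = c + _gamma_variate(tp - self.recirc_delay, a2, al2, b2)
        return np.where(tp < 0, 0.0, np.maximum(c, 0.0))


def _gamma_variate(tp: np.ndarray, amp: float, alpha: float, beta: float) -> np.ndarray:
    """Gamma-variate bolus with peak ``amp`` at ``alpha*beta`` seconds."""
    tpk = alpha * beta
    x = np.clip(tp, 0.0, None) / tpk if tpk > 0 else np.zeros_like(tp)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = amp * np.where(x > 0, np.exp(alpha * (np.log(x) + 1.0 - x)), 0.0)
    return g


def make_aif(params: AIFParams, times) -> TimeActivityCurve:
    """Evaluate a parametric AIF at the given times (seconds)."""
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValueError("times must be sorted and non-negative")
    return TimeActivityCurve(times=times, values=params(times))


@lru_cache(maxsize=None)
def _pet_aif_scale() -> float:
    """Activity scale making the lesion-reference early SUV hit its median."""
    base = _unscaled_pet_aif()
    sched = pet_frame_schedule()
    grid = ConvolutionGrid(sched, base, dt=0.5)
    vals = grid.frame_average(_f2tc_forward_grid(dil_reference_f2tc(), grid))
    suv_early_unscaled = float(np.mean(vals[-4:])) / (INJECTED_MBQ / (WEIGHT_KG * 1e3))
    return _SUV_EARLY_DIL / suv_early_unscaled


def _unscaled_pet_aif() -> AIFParams:
    # peak ~60 s post-injection (15 s arrival + 45 s rise), washout half-times
    # of ~1.4 min and ~46 min
    return AIFParams(model="pet_bolus", amplitudes=(1.0, 3.0, 1.5),
                     rates=(1.0 / 45.0, 1.0 / 120.0, 1.0 / 4000.0), delay=15.0)


def default_pet_aif_params() -> AIFParams:
    """Default PET arterial input, calibrated to the cohort activity scale."""
    s = _pet_aif_scale()
    base = _unscaled_pet_aif()
    return replace(base, amplitudes=tuple(s * a for a in base.amplitudes))


def default_ctp_aif_params() -> AIFParams:
    """Default contrast bolus: gamma-variate with recirculation.

    Peak enhancement 100 (arbitrary concentration units) ~10.5 s after an
    8-s arrival; a 20%-amplitude recirculation bump follows 25 s later.
    """
    return AIFParams(model="ctp_bolus", amplitudes=(100.0, 20.0),
                     rates=(3.0, 3.5, 2.5, 8.0), delay=8.0, recirc_delay=25.0)


# ---------------------------------------------------------------------------
# Reference tissue classes
# ---------------------------------------------------------------------------

def f2tc_rates_from_macro(k1: float, k4: float, ki: float, dv: float) -> tuple[float, float]:
    """Solve (k2, k3) from the macro identities Ki = K1*k3/(k2+k3) and
    DV = (K1/k2)*(1 + k3/k4) given K1 and k4."""
    if not (0 < ki < k1):
        raise ValueError("need 0 < Ki < K1")
    denom = dv - k1 * ki / ((k1 - ki) * k4)
    if denom <= 0:
        raise ValueError("inconsistent macro parameters (DV too small)")
    k2 = k1 / denom
    k3 = ki * k2 / (k1 - ki)
    return k2, k3


def extraction_from_ps(ps: float, bf: float) -> float:
    """Invert the Crone-Renkin identity: E = 1 - exp(-PS/BF)."""
    if bf <= 0:
        raise ValueError("BF must be positive")
    return float(-np.expm1(-ps / bf))


def dil_reference_f2tc() -> F2TCParams:
    """Lesion-class F2TC reference set (class voxel medians).

    K1 and k4 are the reported medians; k2 and k3 close the reported Ki and
    DV medians; the vascular phase re-expresses the reported perfusion
    medians per gram (F = BF/100 at density 1 g/mL, W = MTT).
    """
    k2, k3 = f2tc_rates_from_macro(0.236, 0.085, 0.055, 2.29)
    return F2TCParams(F=0.5658, W=8.94, K1=0.236, k2=k2, k3=k3, k4=0.085, t0=0.0)


def nondil_reference_f2tc() -> F2TCParams:
    """Non-lesion-class F2TC reference set (see :func:`dil_reference_f2tc`)."""
    k2, k3 = f2tc_rates_from_macro(0.187, 0.130, 0.036, 1.17)
    return F2TCParams(F=0.4643, W=8.07, K1=0.187, k2=k2, k3=k3, k4=0.130, t0=0.0)


def dil_reference_ath() -> ATHParams:
    """Lesion-class perfusion reference: BF/MTT medians, E closing PS."""
    return ATHParams(BF=56.58, Tc=8.94, E=extraction_from_ps(24.39, 56.58),
                     Ve=15.0, t0=2.0)


def nondil_reference_ath() -> ATHParams:
    return ATHParams(BF=46.43, Tc=8.07, E=extraction_from_ps(19.44, 46.43),
                     Ve=15.0, t0=2.0)


@dataclass(frozen=True)
class TissueClassSpec:
    """Generating parameters of one tissue class.

    ``late_scale`` multiplies the forward-model concentration in the
    2-h window before SUV conversion (absorbing unmodelled late-binding
    accumulation); ``param_jitter`` is the voxel-level log-normal sigma
    applied to the kinetic parameters.
    """

    label: str
    f2tc: F2TCParams
    ath: ATHParams
    late_scale: float = 1.0
    param_jitter: float = 0.25


@lru_cache(maxsize=None)
def _late_scales() -> tuple[float, float]:
    """Late-uptake scales making the class-reference late SUVs hit their medians."""
    aif = default_pet_aif_params()
    sched = FrameSchedule(start=np.array([LATE_WINDOW[0]]), end=np.array([LATE_WINDOW[1]]))
    grid = ConvolutionGrid(sched, aif, dt=2.0)
    denom = INJECTED_MBQ / (WEIGHT_KG * 1e3)
    out = []
    for p, target in ((dil_reference_f2tc(), _SUV_LATE_DIL),
                      (nondil_reference_f2tc(), _SUV_LATE_NONDIL)):
        model = float(grid.frame_average(_f2tc_forward_grid(p, grid))[0]) / denom
        out.append(target / model)
    return tuple(out)


def reference_class_specs(param_jitter: float = 0.25) -> tuple[TissueClassSpec, TissueClassSpec]:
    """The two study tissue classes at their reported median kinetics."""
    s_dil, s_non = _late_scales()
    dil = TissueClassSpec("DIL", dil_reference_f2tc(), dil_reference_ath(),
                          late_scale=s_dil, param_jitter=param_jitter)
    non = TissueClassSpec("non-DIL", nondil_reference_f2tc(), nondil_reference_ath(),
                          late_scale=s_non, param_jitter=param_jitter)
    return dil, non


# ---------------------------------------------------------------------------
# Geometry and image-level phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Voxel grid with an ellipsoidal prostate and an ellipsoidal lesion.

    Default: a 26x26x12 grid at 2x2x3.27 mm spacing holding a prostate
    ellipsoid of semi-axes (12, 12, 5) voxels (~3000 voxels, so a
    15-patient cohort pools ~45k in-prostate voxels) with a lesion of
    semi-axes (5, 5, 3.4) voxels (~12% of the prostate) offset from centre.
    """

    shape: tuple = (26, 26, 12)
    spacing: tuple = (2.0, 2.0, 3.27)
    prostate_semiaxes: tuple = (12.0, 12.0, 5.0)
    dil_semiaxes: tuple = (5.0, 5.0, 3.4)
    dil_offset: tuple = (4.0, 0.0, 0.0)

    def scaled(self, f: float) -> "Geometry":
        """Geometry shrunk/grown by a linear factor (grid resized to fit)."""
        pa = tuple(a * f for a in self.prostate_semiaxes)
        da = tuple(a * f for a in self.dil_semiaxes)
        off = tuple(o * f for o in self.dil_offset)
        shape = tuple(2 * math.ceil(a) + 2 for a in pa)
        return Geometry(shape=shape, spacing=self.spacing, prostate_semiaxes=pa,
                        dil_semiaxes=da, dil_offset=off)

    def labels(self) -> np.ndarray:
        """Label volume: 0 background, 1 non-lesion prostate, 2 lesion."""
        idx = np.indices(self.shape, dtype=float)
        centre = [(n - 1) / 2.0 for n in self.shape]
        d_pro = sum(((idx[a] - centre[a]) / self.prostate_semiaxes[a]) ** 2
                    for a in range(3))
        d_dil = sum(((idx[a] - centre[a] - self.dil_offset[a]) / self.dil_semiaxes[a]) ** 2
                    for a in range(3))
        lab = np.zeros(self.shape, dtype=np.int8)
        lab[d_pro <= 1.0] = 1
        dil = d_dil <= 1.0
        if np.any(dil & (lab == 0)):
            raise ValueError("lesion region extends outside the prostate")
        lab[dil] = 2
        return lab


@dataclass
class PhantomStudy:
    """One synthetic patient: dynamic volumes, inputs, truth maps, masks."""

    patient_id: str
    geometry: Geometry
    labels: np.ndarray                 # 0 bg, 1 non-lesion, 2 lesion
    pet: np.ndarray                    # (nx, ny, nz, 28)
    pet_schedule: FrameSchedule
    ctp: np.ndarray                    # (nx, ny, nz, 29)
    ctp_schedule: FrameSchedule
    suv_late: np.ndarray               # (nx, ny, nz), g/mL
    pet_aif: TimeActivityCurve
    ctp_aif: TimeActivityCurve
    pet_aif_params: AIFParams
    ctp_aif_params: AIFParams
    truth: dict                        # name -> (nx, ny, nz) float map
    seed: int
    noise_scale: float
    injected_mbq: float = INJECTED_MBQ
    weight_kg: float = WEIGHT_KG

    @property
    def prostate_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def dil_mask(self) -> np.ndarray:
        return self.labels == 2


def _jitter_f2tc(p: F2TCParams, sigma: float, rng: np.random.Generator) -> F2TCParams:
    if sigma == 0:
        return p
    g = np.exp(sigma * rng.standard_normal(6))
    f, w, k1 = p.F * g[0], p.W * g[1], p.K1 * g[2]
    return F2TCParams(F=f, W=w, K1=min(k1, f), k2=p.k2 * g[3],
                      k3=p.k3 * g[4], k4=p.k4 * g[5], t0=p.t0)


def _jitter_ath(p: ATHParams, sigma: float, rng: np.random.Generator) -> ATHParams:
    if sigma == 0:
        return p
    g = np.exp(sigma * rng.standard_normal(4))
    return ATHParams(BF=p.BF * g[0], Tc=p.Tc * g[1],
                     E=min(p.E * g[2], 0.93), Ve=p.Ve * g[3], t0=p.t0)


def _frame_noise(values: np.ndarray, durations_s: np.ndarray,
                 noise_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-zero Gaussian frame noise with variance proportional to
    value/duration.

    The SD is ``noise_scale * sqrt(value/dur) * sqrt(mean(value)*mean(dur))``
    (means over the frames of each curve), i.e. the standard frame-weighted
    proxy made unit-invariant: ``noise_scale`` is the relative noise of an
    average-intensity, average-duration frame.  Values are clamped at zero
    after noise addition.
    """
    v = np.clip(values, 0.0, None)
    ref = np.sqrt(v.mean(axis=-1, keepdims=True) * durations_s.mean())
    sd = noise_scale * np.sqrt(v / durations_s) * ref
    return np.clip(values + sd * rng.standard_normal(values.shape), 0.0, None)


def simulate_study(dil_spec: TissueClassSpec, nondil_spec: TissueClassSpec,
                   geometry: Geometry | None = None, noise_scale: float = 0.0,
                   seed: int = 0, *, patient_id: str = "P00",
                   pet_aif_params: AIFParams | None = None,
                   ctp_aif_params: AIFParams | None = None,
                   injected_mbq: float = INJECTED_MBQ,
                   weight_kg: float = WEIGHT_KG) -> PhantomStudy:
    """Generate one synthetic patient study.

    Each in-prostate voxel gets class parameters (with voxel-level
    log-normal jitter per the class spec), its PET and CTP curves are the
    frame-averaged forward models, and frame noise with variance
    proportional to value/duration is added and clamped at zero.  The late
    SUV volume evaluates the PET forward model over the 120-135 min window.
    Regeneration with the same seed is bit-for-bit reproducible.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if dil_spec.f2tc == nondil_spec.f2tc and dil_spec.ath == nondil_spec.ath \
            and dil_spec.late_scale == nondil_spec.late_scale:
        raise ValueError("lesion and non-lesion specs must differ in at least one parameter")
    geometry = geometry or Geometry()
    labels = geometry.labels()  # raises if lesion leaves the prostate
    rng = np.random.default_rng(int(seed))

    pet_sched = pet_frame_schedule()
    ctp_sched = ctp_frame_schedule()
    late_sched = FrameSchedule(start=np.array([LATE_WINDOW[0]]),
                               end=np.array([LATE_WINDOW[1]]))
    pet_aifp = pet_aif_params or default_pet_aif_params()
    ctp_aifp = ctp_aif_params or default_ctp_aif_params()
    grid_pet = ConvolutionGrid(pet_sched, pet_aifp, dt=0.5)
    grid_ctp = ConvolutionGrid(ctp_sched, ctp_aifp, dt=0.2)
    grid_late = ConvolutionGrid(late_sched, pet_aifp, dt=2.0)
    suv_denom = injected_mbq / (weight_kg * 1e3)

    shape = geometry.shape
    pet4d = np.zeros(shape + (pet_sched.n_frames,))
    ctp4d = np.zeros(shape + (ctp_sched.n_frames,))
    suv_late_vol = np.zeros(shape)
    truth = {name: np.full(shape, np.nan) for name in PARAM_NAMES}

    coords = np.argwhere(labels > 0)
    cache: dict[tuple, tuple] = {}
    for i, j, k in coords:
        spec = dil_spec if labels[i, j, k] == 2 else nondil_spec
        if spec.param_jitter == 0:
            key = (spec.label,)
            hit = cache.get(key)
            if hit is not None:
                f2, ath, pet_y, ctp_y, late_c = hit
            else:
                f2, ath = spec.f2tc, spec.ath
                pet_y = grid_pet.frame_average(_f2tc_forward_grid(f2, grid_pet))
                ctp_y = grid_ctp.frame_average(_ath_forward_grid(ath, grid_ctp))
                late_c = float(grid_late.frame_average(_f2tc_forward_grid(f2, grid_late))[0])
                cache[key] = (f2, ath, pet_y, ctp_y, late_c)
        else:
            f2 = _jitter_f2tc(spec.f2tc, spec.param_jitter, rng)
            ath = _jitter_ath(spec.ath, spec.param_jitter, rng)
            pet_y = grid_pet.frame_average(_f2tc_forward_grid(f2, grid_pet))
            ctp_y = grid_ctp.frame_average(_ath_forward_grid(ath, grid_ctp))
            late_c = float(grid_late.frame_average(_f2tc_forward_grid(f2, grid_late))[0])
        pet4d[i, j, k] = pet_y
        ctp4d[i, j, k] = ctp_y
        suv_late_vol[i, j, k] = late_c * spec.late_scale / suv_denom
        truth["K1"][i, j, k] = f2.K1
        truth["k2"][i, j, k] = f2.k2
        truth["k3"][i, j, k] = f2.k3
        truth["k4"][i, j, k] = f2.k4
        truth["Ki"][i, j, k] = ki_of(f2) if f2.k2 + f2.k3 > 0 else 0.0
        truth["DV"][i, j, k] = dv_of(f2) if f2.k2 > 0 and f2.k4 > 0 else np.nan
        truth["SUV_Early"][i, j, k] = float(np.mean(pet_y[-4:])) / suv_denom
        truth["SUV_Late"][i, j, k] = suv_late_vol[i, j, k]
        truth["BF"][i, j, k] = ath.BF
        truth["BV"][i, j, k] = bv_of(ath)
        truth["MTT"][i, j, k] = ath.Tc
        truth["PS"][i, j, k] = ps_of(ath.BF, ath.E)
        truth["T0"][i, j, k] = ath.t0

    if noise_scale > 0:
        mask = labels > 0
        pet4d[mask] = _frame_noise(pet4d[mask], pet_sched.duration, noise_scale, rng)
        ctp4d[mask] = _frame_noise(ctp4d[mask], ctp_sched.duration, noise_scale, rng)
        # late static acquisition: relative noise reduced by its length
        # versus an average dynamic frame
        late_rel = noise_scale * np.sqrt(pet_sched.duration.mean()
                                         / (LATE_WINDOW[1] - LATE_WINDOW[0]))
        lv = suv_late_vol[mask]
        suv_late_vol[mask] = np.clip(
            lv * (1.0 + late_rel * rng.standard_normal(lv.shape)), 0.0, None)

    return PhantomStudy(
        patient_id=patient_id, geometry=geometry, labels=labels,
        pet=pet4d, pet_schedule=pet_sched, ctp=ctp4d, ctp_schedule=ctp_sched,
        suv_late=suv_late_vol,
        pet_aif=TimeActivityCurve(grid_pet.t, grid_pet.a, units="MBq/mL"),
        ctp_aif=TimeActivityCurve(grid_ctp.t, grid_ctp.a, units="a.u."),
        pet_aif_params=pet_aifp, ctp_aif_params=ctp_aifp,
        truth=truth, seed=int(seed), noise_scale=noise_scale,
        injected_mbq=injected_mbq, weight_kg=weight_kg)


def _scale_spec(spec: TissueClassSpec, factors: dict) -> TissueClassSpec:
    f2 = spec.f2tc
    k1 = f2.K1 * factors["K1"]
    f = f2.F * factors["F"]
    f2j = F2TCParams(F=f, W=f2.W * factors["W"], K1=min(k1, f),
                     k2=f2.k2 * factors["k2"], k3=f2.k3 * factors["k3"],
                     k4=f2.k4 * factors["k4"], t0=f2.t0)
    a = spec.ath
    athj = ATHParams(BF=a.BF * factors["BF"], Tc=a.Tc * factors["Tc"],
                     E=min(a.E * factors["E"], 0.93), Ve=a.Ve * factors["Ve"],
                     t0=a.t0)
    return replace(spec, f2tc=f2j, ath=athj,
                   late_scale=spec.late_scale * factors["late"])


_PATIENT_FACTOR_KEYS = ("F", "W", "K1", "k2", "k3", "k4",
                        "BF", "Tc", "E", "Ve", "late")


def make_cohort(n_patients: int = 15,
                dil_spec: TissueClassSpec | None = None,
                nondil_spec: TissueClassSpec | None = None,
                geometry: Geometry | None = None,
                noise_scale: float = 0.1,
                patient_jitter: float = 0.1,
                seed: int = 0,
                seeds: Sequence[int] | None = None,
                **study_kwargs) -> list[PhantomStudy]:
    """Generate a cohort of phantom patients.

    Patients differ through a multiplicative log-normal jitter
    (``patient_jitter``) on the class parameter sets.  The jitter factor of
    each parameter is shared between the two tissue classes of a patient —
    a patient-level effect — so the paired class contrast is preserved, as
    the signed-rank design assumes.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if seeds is None:
        seeds = [int(s) for s in
                 np.random.SeedSequence(int(seed)).generate_state(n_patients) % (2**31)]
    elif len(seeds) < n_patients:
        raise ValueError(f"got {len(seeds)} seeds for {n_patients} patients")
    if dil_spec is None or nondil_spec is None:
        d, n = reference_class_specs()
        dil_spec = dil_spec or d
        nondil_spec = nondil_spec or n
    studies = []
    for p in range(n_patients):
        rng = np.random.default_rng(seeds[p])
        factors = {key: float(np.exp(patient_jitter * rng.standard_normal()))
                   for key in _PATIENT_FACTOR_KEYS}
        study = simulate_study(
            _scale_spec(dil_spec, factors), _scale_spec(nondil_spec, factors),
            geometry=geometry, noise_scale=noise_scale,
            seed=seeds[p], patient_id=f"P{p:02d}", **study_kwargs)
        studies.append(study)
    return studies


# ---------------------------------------------------------------------------
# Feature-level voxel tables
# ---------------------------------------------------------------------------

def _default_medians() -> pd.DataFrame:
    """Reported class voxel medians of the 13 parametric maps.

    k2, k3 and T0 did not separate the classes in the study and carry no
    reported medians; they are given equal class medians here.
    """
    data = {
        "K1": (0.236, 0.187), "k2": (0.20, 0.20), "k3": (0.050, 0.050),
        "k4": (0.085, 0.130), "Ki": (0.055, 0.036), "DV": (2.29, 1.17),
        "SUV_Early": (2.53, 1.78), "SUV_Late": (1.55, 0.67),
        "BF": (56.58, 46.43), "BV": (8.92, 5.83), "MTT": (8.94, 8.07),
        "PS": (24.39, 19.44), "T0": (2.0, 2.0),
    }
    return pd.DataFrame(data, index=["dil", "nondil"]).T


DEFAULT_CLASS_MEDIANS = _default_medians()


def class_medians_with_contrast(features: Sequence[str],
                                base: pd.DataFrame | None = None) -> pd.DataFrame:
    """Class medians whose contrast is confined to ``features``.

    Every other parameter takes the non-lesion median in both classes.
    """
    base = (base if base is not None else DEFAULT_CLASS_MEDIANS).copy()
    for name in base.index:
        if name not in features:
            base.loc[name, "dil"] = base.loc[name, "nondil"]
    return base


def simulate_voxel_table(n_patients: int = 15,
                         voxels_per_patient: int = 600,
                         dil_fraction: float = 0.12,
                         class_medians: pd.DataFrame | None = None,
                         patient_sigma: float = 0.12,
                         class_sigma: float = 0.03,
                         voxel_sigma: float = 0.35,
                         seed: int = 0) -> VoxelTable:
    """Draw a voxel feature table directly from class medians.

    Each feature value is log-normal about its class median with three
    nested variation scales: a patient effect (shared by both classes of a
    patient, sigma ``patient_sigma``), a small class-by-patient effect
    (``class_sigma``), and voxel-level spread (``voxel_sigma``, the scale
    that sets class separability).  Features are drawn independently —
    deterministic identities between maps (e.g. BV = BF*MTT/60) are not
    enforced at voxel level.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    med = class_medians if class_medians is not None else DEFAULT_CLASS_MEDIANS
    med = med.loc[list(PARAM_NAMES)]
    rng = np.random.default_rng(int(seed))
    n_dil = max(int(round(dil_fraction * voxels_per_patient)), 1)
    n_non = max(voxels_per_patient - n_dil, 1)
    nf = len(PARAM_NAMES)
    frames = []
    for p in range(n_patients):
        pf = np.exp(patient_sigma * rng.standard_normal(nf))
        for label, n_vox, col in ((1, n_dil, "dil"), (0, n_non, "nondil")):
            centre = med[col].to_numpy() * pf * np.exp(
                class_sigma * rng.standard_normal(nf))
            vals = centre * np.exp(voxel_sigma * rng.standard_normal((n_vox, nf)))
            df = pd.DataFrame(vals, columns=list(PARAM_NAMES))
            df.insert(0, "patient", f"P{p:02d}")
            df.insert(1, "label", label)
            frames.append(df)
    return VoxelTable(df=pd.concat(frames, ignore_index=True))
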