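"""Voxel-wise orchestration: TAC smoothing and parametric-map production.

For each phantom patient this module smooths the dynamic PET volume with an
in-slice 3x3 mean filter, then runs the F2TC and ATH estimators on every
in-prostate voxel to produce the 13 parametric maps (K1, k2, k3, k4, Ki,
DV, SUV_Early, SUV_Late, BF, BV, MTT, PS, T0).  Background voxels are NaN
in every map; per-voxel non-convergence is propagated as flags, never as an
abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ConvolutionGrid, TimeActivityCurve
from .ctp import fit_ath
from .pet import FitOptions, fit_f2tc, suv, suv_early
from .stats import PARAM_NAMES, VoxelTable
from .synthetic import PhantomStudy

__all__ = ["ParametricMapSet", "MapOptions", "smooth_tac_3x3", "build_maps",
           "voxel_table_from_maps"]


def smooth_tac_3x3(volume: np.ndarray) -> np.ndarray:
    """In-slice 3x3 mean filter applied frame-by-frame to a 4-D volume.

    Each voxel's frame value becomes the mean over its 3x3 in-slice
    neighbourhood (no across-slice mixing); at volume edges the kernel
    shrinks to the available in-slice neighbours.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, frame) volume")
    kernel = np.ones((3, 3, 1, 1))
    num = ndimage.convolve(vol, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones(vol.shape[:2] + (1, 1)), kernel,
                           mode="constant", cval=0.0)
    return num / den


@dataclass(frozen=True)
class MapOptions:
    """Options for voxel-wise map production.

    Map fitting defaults to a single extra restart per voxel (the
    deterministic start plus one seeded Latin-hypercube point): on
    frame-averaged voxel data this almost always reaches the global optimum
    and keeps whole-prostate fitting tractable; raise ``n_starts`` for
    tougher noise levels.
    """

    smooth: bool = True
    n_starts: int = 1
    seed: int = 0
    xtol: float = 1e-10
    ftol: float = 1e-10


@dataclass
class ParametricMapSet:
    """The 13 per-voxel parametric maps of one patient on a shared grid."""

    maps: dict
    pet_converged: np.ndarray
    ctp_converged: np.ndarray
    spacing: tuple
    mask: np.ndarray

    def __post_init__(self) -> None:
        if set(self.maps) != set(PARAM_NAMES):
            raise ValueError(f"expected exactly the maps {PARAM_NAMES}")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1 or self.mask.shape not in shapes:
            raise ValueError("all maps must share one grid")


def build_maps(study: PhantomStudy, opts: MapOptions | None = None) -> ParametricMapSet:
    """Fit every in-prostate voxel of a phantom study.

    Runs optional smoothing, then per voxel: the F2TC fit on the PET TAC,
    the ATH fit on the CTP curve, the early-SUV average, and the late-SUV
    lookup.  Voxels are visited in a fixed (C-order) sequence so output is
    run-to-run identical for a given seed.
    """
    opts = opts or MapOptions()
    pet_vol = smooth_tac_3x3(study.pet) if opts.smooth else study.pet
    ctp_vol = smooth_tac_3x3(study.ctp) if opts.smooth else study.ctp
    fit_opts = FitOptions(n_starts=opts.n_starts, seed=opts.seed,
                          xtol=opts.xtol, ftol=opts.ftol)
    grid_pet = ConvolutionGrid(study.pet_schedule, study.pet_aif, dt=0.5)
    grid_ctp = ConvolutionGrid(study.ctp_schedule, study.ctp_aif, dt=0.2)

    shape = study.labels.shape
    maps = {name: np.full(shape, np.nan) for name in PARAM_NAMES}
    pet_ok = np.zeros(shape, dtype=bool)
    ctp_ok = np.zeros(shape, dtype=bool)

    mids_pet = study.pet_schedule.mid
    mids_ctp = study.ctp_schedule.mid
    for i, j, k in np.argwhere(study.labels > 0):
        tac = TimeActivityCurve(mids_pet, pet_vol[i, j, k])
        fr = fit_f2tc(tac, study.pet_aif, study.pet_schedule, fit_opts, grid=grid_pet)
        p = fr.params
        maps["K1"][i, j, k] = p.K1
        maps["k2"][i, j, k] = p.k2
        maps["k3"][i, j, k] = p.k3
        maps["k4"][i, j, k] = p.k4
        maps["Ki"][i, j, k] = fr.ki if fr.ki is not None else np.nan
        maps["DV"][i, j, k] = fr.dv if fr.dv is not None else np.nan
        maps["SUV_Early"][i, j, k] = suv_early(tac, study.pet_schedule,
                                               study.injected_mbq, study.weight_kg)
        pet_ok[i, j, k] = fr.converged

        curve = TimeActivityCurve(mids_ctp, ctp_vol[i, j, k])
        cr = fit_ath(curve, study.ctp_aif, study.ctp_schedule, fit_opts, grid=grid_ctp)
        maps["BF"][i, j, k] = cr.params.BF
        maps["BV"][i, j, k] = cr.bv
        maps["MTT"][i, j, k] = cr.mtt
        maps["PS"][i, j, k] = cr.ps
        maps["T0"][i, j, k] = cr.params.t0
        ctp_ok[i, j, k] = cr.converged

    maps["SUV_Late"] = np.where(study.labels > 0, study.suv_late, np.nan)
    return ParametricMapSet(maps=maps, pet_converged=pet_ok, ctp_converged=ctp_ok,
                            spacing=study.geometry.spacing, mask=study.labels > 0)


def voxel_table_from_maps(studies, map_sets=None, source: str = "fit",
                          opts: MapOptions | None = None) -> VoxelTable:
    """Pool per-voxel map values of a cohort into a classifier table.

    ``source="fit"`` fits maps with :func:`build_maps` (or accepts prebuilt
    ``map_sets``); ``source="truth"`` reads the generator's stored truth
    maps instead, bypassing estimation.  Voxel indices are kept as i/j/k
    columns so probabilities can be painted back onto the grid.
    """
    if source not in ("fit", "truth"):
        raise ValueError("source must be 'fit' or 'truth'")
    rows = []
    for idx, study in enumerate(studies):
        if source == "truth":
            maps = study.truth
        else:
            ms = map_sets[idx] if map_sets is not None else build_maps(study, opts)
            maps = ms.maps
        coords = np.argwhere(study.labels > 0)
        ii, jj, kk = coords.T
        df = pd.DataFrame({name: maps[name][ii, jj, kk] for name in PARAM_NAMES})
        df.insert(0, "patient", study.patient_id)
        df.insert(1, "label", (study.labels[ii, jj, kk] == 2).astype(int))
        df["i"], df["j"], df["k"] = ii, jj, kk
        rows.append(df)
    df = pd.concat(rows, ignore_index=True)
    df = df.dropna(subset=list(PARAM_NAMES)).reset_index(drop=True)
    return VoxelTable(df=df)
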