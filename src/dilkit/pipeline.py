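"""End-to-end driver, configuration, volume I/O and provenance.

``run_pipeline`` ties the stages together: simulate a phantom cohort,
produce per-voxel parametric values (fitted maps or generator truth),
screen parameters, select a model by backward elimination, cross-validate
the candidate models patient-wise, and score detected lesion masks against
the ground truth with Dice.  All randomness flows from the single master
seed in :class:`StudyConfig` (per-patient seeds are spawned from it), so a
given configuration is bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .evaluate import CVReport, detect_dil_mask, dice, lopo_cv
from .maps import MapOptions, voxel_table_from_maps
from .stats import VoxelTable, backward_eliminate, screen_parameters
from .synthetic import Geometry, make_cohort, reference_class_specs

__all__ = ["StudyConfig", "PipelineResult", "run_pipeline",
           "save_volume", "load_volume", "load_study_volumes",
           "MODEL_FEATURES"]

logger = logging.getLogger("dilkit")

#: Feature sets of the named lesion-detection models.
MODEL_FEATURES = {
    "ki_k4": ("Ki", "k4"),
    "bf_mtt": ("BF", "MTT"),
    "suv_early": ("SUV_Early",),
    "suv_late": ("SUV_Late",),
}


# ---------------------------------------------------------------------------
# NIfTI volume I/O
# ---------------------------------------------------------------------------

def save_volume(path: Union[str, Path], volume: np.ndarray, spacing) -> None:
    """Write a 3-D/4-D volume as NIfTI-1 with voxel spacing in the header."""
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(np.asarray(volume), affine)
    img.header.set_zooms(tuple(spacing) + (1.0,) * (volume.ndim - 3))
    nib.save(img, str(path))


def load_volume(path: Union[str, Path]) -> tuple[np.ndarray, tuple]:
    """Read a NIfTI volume; returns (array, (dx, dy, dz) spacing in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


def load_study_volumes(paths) -> list[tuple[np.ndarray, tuple]]:
    """Load several volumes of one study, enforcing a common voxel spacing."""
    out = [load_volume(p) for p in paths]
    spacings = {tuple(np.round(s, 6)) for _, s in out}
    if len(spacings) > 1:
        raise ValueError(f"voxel spacing mismatch across study volumes: {spacings}")
    grids = {v.shape[:3] for v, _ in out}
    if len(grids) > 1:
        raise ValueError(f"grid mismatch across study volumes: {grids}")
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Declarative configuration of one pipeline run.

    ``geometry_scale`` shrinks the full-size phantom geometry linearly
    (the default 0.45 keeps whole-cohort voxel-wise fitting minutes-scale);
    ``table_source`` selects fitted maps (``"fit"``) or generator truth
    maps (``"truth"``) as the classifier input; ``models`` lists named
    models (keys of :data:`MODEL_FEATURES`) and/or ``"auto"`` for the
    screen + backward-elimination selection.
    """

    n_patients: int = 15
    geometry_scale: float = 0.45
    noise_scale: float = 0.1
    patient_jitter: float = 0.1
    param_jitter: float = 0.25
    table_source: str = "fit"
    smooth: bool = True
    fit_starts: int = 1
    models: tuple = ("auto", "ki_k4", "bf_mtt", "suv_early", "suv_late")
    threshold: float = 0.5
    seed: int = 0
    output_dir: str | None = None
    save_maps: bool = False

    def __post_init__(self) -> None:
        if self.table_source not in ("fit", "truth"):
            raise ValueError("table_source must be 'fit' or 'truth'")
        unknown = [m for m in self.models
                   if m != "auto" and m not in MODEL_FEATURES]
        if unknown:
            raise ValueError(f"unknown models: {unknown}")
        object.__setattr__(self, "models", tuple(self.models))

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(d["models"])
        return d

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything a pipeline run produced."""

    config: StudyConfig
    table: VoxelTable
    screen: "pd.DataFrame"
    selected_features: tuple
    reports: dict                      # model name -> CVReport
    provenance: dict

    def report_json(self) -> str:
        """Canonical JSON of all CV reports (used for determinism checks)."""
        payload = {}
        for name, rep in self.reports.items():
            payload[name] = {
                "features": list(rep.model_features),
                "summary": {k: dict(v) for k, v in rep.summary.iterrows()},
                "folds": rep.folds.drop(columns=["features"]).to_dict(orient="list"),
            }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _provenance(config: StudyConfig) -> dict:
    import pandas
    import scipy
    return {
        "dilkit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "nibabel": nib.__version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
    }


def run_pipeline(config: StudyConfig | None = None) -> PipelineResult:
    """Run the full phantom study: simulate, map, screen, select, validate."""
    import pandas as pd  # noqa: F401  (type reference in PipelineResult)

    config = config or StudyConfig()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None and not out_dir.exists():
        out_dir.mkdir(parents=True)
        logger.info("created output directory %s", out_dir)

    logger.info("stage 1/5: simulating %d phantoms (seed %d)",
                config.n_patients, config.seed)
    dil, non = reference_class_specs(param_jitter=config.param_jitter)
    geometry = Geometry().scaled(config.geometry_scale)
    try:
        studies = make_cohort(
            n_patients=config.n_patients, dil_spec=dil, nondil_spec=non,
            geometry=geometry, noise_scale=config.noise_scale,
            patient_jitter=config.patient_jitter, seed=config.seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    logger.info("stage 2/5: building voxel table (source=%s)", config.table_source)
    try:
        opts = MapOptions(smooth=config.smooth, n_starts=config.fit_starts,
                          seed=config.seed)
        table = voxel_table_from_maps(studies, source=config.table_source, opts=opts)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'maps' failed: {exc}") from exc

    logger.info("stage 3/5: screening parameters")
    try:
        screen = screen_parameters(table)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'screen' failed: {exc}") from exc

    logger.info("stage 4/5: model selection (screen survivors: %s)", screen.passed)
    try:
        if screen.passed:
            selected = backward_eliminate(table, screen.passed).features
        else:
            selected = ()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'select' failed: {exc}") from exc

    logger.info("stage 5/5: leave-one-patient-out cross-validation")
    try:
        reports: dict[str, CVReport] = {}
        for model in config.models:
            feats = selected if model == "auto" else MODEL_FEATURES[model]
            if not feats:
                continue
            rep = lopo_cv(table, feats, threshold=config.threshold)
            _attach_dice(rep, table, studies, config.threshold)
            reports[model] = rep
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'validate' failed: {exc}") from exc

    prov = _provenance(config)
    result = PipelineResult(config=config, table=table, screen=screen.table,
                            selected_features=tuple(selected), reports=reports,
                            provenance=prov)
    if out_dir is not None:
        (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2))
        (out_dir / "cv_report.json").write_text(result.report_json())
        screen.table.to_csv(out_dir / "screen.csv")
        for name, rep in reports.items():
            rep.to_csv(out_dir / f"cv_folds_{name}.csv")
        if config.save_maps:
            for study in studies:
                save_volume(out_dir / f"{study.patient_id}_labels.nii",
                            study.labels.astype(np.int16), study.geometry.spacing)
    return result


def _attach_dice(report: CVReport, table: VoxelTable, studies, threshold: float) -> None:
    """Per-fold Dice of the detected lesion mask against the truth mask."""
    by_id = {s.patient_id: s for s in studies}
    if not {"i", "j", "k"}.issubset(table.df.columns):
        return
    dices = []
    for pid in report.folds["patient"]:
        study = by_id[pid]
        idx, proba = report.probabilities[pid]
        sub = table.df.loc[idx]
        prob_map = np.full(study.labels.shape, np.nan)
        prob_map[sub["i"], sub["j"], sub["k"]] = proba
        detected = detect_dil_mask(prob_map, threshold)
        dices.append(dice(detected, study.labels == 2))
    report.folds["dice"] = dices
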