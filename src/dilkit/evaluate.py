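"""Cross-validated diagnostic performance of lesion-detection models.

Implements leave-one-patient-out cross-validation of a fixed-feature
logistic model, the Mann-Whitney formulation of ROC AUC, confusion-matrix
rates (error rate, false-positive rate, false-negative rate), probability
thresholding into a detected-lesion mask, and the Dice similarity
coefficient against a reference mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

from .stats import VoxelTable, logistic_fit, screen_parameters, backward_eliminate

__all__ = ["CVReport", "roc_auc", "confusion_rates", "lopo_cv",
           "dice", "detect_dil_mask"]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    AUC = P(random positive outscores a random negative), ties counted 1/2;
    computed from midranks, so it is invariant under any strictly monotone
    transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_rates(pred_labels, true_labels) -> tuple[float, float, float]:
    """(ER, FPR, FNR): error rate, false-positive rate, false-negative rate.

    ER = (FP+FN)/N, FPR = FP/(FP+TN), FNR = FN/(FN+TP); a rate with an
    empty denominator is returned as NaN.
    """
    p = np.asarray(pred_labels).astype(int)
    t = np.asarray(true_labels).astype(int)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and labels must be non-empty and matching")
    fp = int(np.sum((p == 1) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    tn = int(np.sum((p == 0) & (t == 0)))
    tp = int(np.sum((p == 1) & (t == 1)))
    er = (fp + fn) / p.size
    fpr = fp / (fp + tn) if fp + tn else np.nan
    fnr = fn / (fn + tp) if fn + tp else np.nan
    return er, fpr, fnr


@dataclass
class CVReport:
    """Leave-one-patient-out cross-validation report.

    ``folds`` holds one row per held-out patient (er/fpr/fnr/auc/dice;
    ``auc_defined`` False marks single-class folds excluded from the AUC
    aggregate).  ``summary`` carries mean, SD and SE over folds.  Fold
    probabilities are kept for downstream mask building.
    """

    model_features: tuple
    folds: pd.DataFrame
    probabilities: dict = field(repr=False, default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        rows = {}
        for metric in ("er", "fpr", "fnr", "auc", "dice"):
            if metric not in self.folds:
                continue
            vals = self.folds[metric]
            if metric == "auc":
                vals = vals[self.folds["auc_defined"]]
            vals = vals.dropna()
            if vals.empty:
                continue
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows[metric] = {"mean": float(vals.mean()), "sd": sd,
                            "se": sd / np.sqrt(len(vals)), "n_folds": len(vals)}
        return pd.DataFrame(rows).T

    def to_json(self, path: Union[str, Path]) -> None:
        d = {"model_features": list(self.model_features),
             "folds": self.folds.to_dict(orient="list"),
             "summary": {k: dict(v) for k, v in self.summary.iterrows()}}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.folds.to_csv(path, index=False)


def lopo_cv(table: VoxelTable, features: Sequence[str], threshold: float = 0.5,
            refit_selection: bool = False, screen_m: int | None = None) -> CVReport:
    """Leave-one-patient-out cross-validation of a logistic model.

    For each patient, coefficients are refit on all other patients' voxels
    with the fixed feature set (or, with ``refit_selection``, the screen
    and backward elimination are re-run within the fold), the held-out
    voxels are scored, rates use the probability threshold, and AUC uses
    the raw probabilities.  A held-out patient with a single class has no
    defined AUC: the fold is flagged and excluded from AUC aggregation.
    """
    patients = table.patients
    if len(patients) < 3:
        raise ValueError("leave-one-patient-out needs at least 3 patients")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be within [0, 1]")
    rows = []
    probs = {}
    for pid in patients:
        held = table.df["patient"] == pid
        train = VoxelTable(df=table.df[~held].reset_index(drop=True),
                           features=table.features)
        if refit_selection:
            survivors = screen_parameters(train, m=screen_m).passed
            model = backward_eliminate(train, survivors or list(features))
            used = model.features
        else:
            model = logistic_fit(train, features)
            used = tuple(features)
        test_df = table.df[held]
        proba = model.predict_proba(test_df)
        y = test_df["label"].to_numpy()
        er, fpr, fnr = confusion_rates((proba >= threshold).astype(int), y)
        auc_defined = len(np.unique(y)) == 2
        auc = roc_auc(proba, y) if auc_defined else np.nan
        rows.append({"patient": pid, "features": ",".join(used), "er": er,
                     "fpr": fpr, "fnr": fnr, "auc": auc,
                     "auc_defined": auc_defined, "dice": np.nan})
        probs[pid] = (test_df.index.to_numpy(), proba)
    return CVReport(model_features=tuple(features), folds=pd.DataFrame(rows),
                    probabilities=probs)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A^B| / (|A|+|B|); two empty masks -> 1."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(a & b) / denom)


def detect_dil_mask(probability_map: np.ndarray, threshold: float = 0.5,
                    largest_component: bool = False) -> np.ndarray:
    """Threshold a voxel probability map into a detected-lesion mask.

    NaN probabilities (background) never enter the mask.  With
    ``largest_component`` the mask is reduced to its largest
    26-connected component.
    """
    prob = np.asarray(probability_map, dtype=float)
    finite = np.isfinite(prob)
    if np.any((prob[finite] < 0) | (prob[finite] > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = finite & (prob >= threshold)
    if largest_component and mask.any():
        structure = np.ones((3,) * mask.ndim, dtype=bool)
        lab, n = ndimage.label(mask, structure=structure)
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    return mask
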