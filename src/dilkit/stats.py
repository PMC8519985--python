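"""Parameter screening and voxel-wise logistic classification.

The selection machinery mirrors how kinetic parameters are winnowed into a
lesion-detection model: each of the 13 parametric maps is first screened by
a paired Wilcoxon signed-rank test on per-patient ROI medians (Bonferroni
corrected over the 13 comparisons), after which the survivors enter a
voxel-wise multivariable logistic regression whose features are pruned by
backward elimination on Wald p-values.

The signed-rank test is implemented exactly (full sign-permutation
distribution via dynamic programming, zeros dropped, ties mid-ranked) for
up to 25 pairs and by normal approximation with continuity and tie
corrections beyond that.  The logistic model is fit by iteratively
reweighted least squares on internally z-scored features, with an L2-ridge
fallback when the classes are completely separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "PARAM_NAMES", "VoxelTable", "ScreenResult", "LogisticModel",
    "wilcoxon_signed_rank", "screen_parameters",
    "logistic_fit", "backward_eliminate",
]

#: The 13 parametric-map names, in canonical order.
PARAM_NAMES = ("K1", "k2", "k3", "k4", "Ki", "DV", "SUV_Early", "SUV_Late",
               "BF", "BV", "MTT", "PS", "T0")


@dataclass
class VoxelTable:
    """Per-voxel feature table feeding the classifier.

    ``df`` holds one row per prostate voxel with columns ``patient``,
    ``label`` (1 = lesion, 0 = non-lesion), one column per parametric map,
    and optionally ``i``/``j``/``k`` voxel indices for mapping
    probabilities back onto the image grid.
    """

    df: pd.DataFrame
    features: tuple = PARAM_NAMES

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        missing = [c for c in ("patient", "label", *self.features)
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"voxel table missing columns: {missing}")
        if self.df[list(self.features)].isna().any().any():
            raise ValueError("voxel table has missing feature values")
        if self.df["patient"].nunique() < 2:
            raise ValueError("need at least two patients")
        if set(self.df["label"].unique()) != {0, 1}:
            raise ValueError("both class labels (0 and 1) must be present")

    @property
    def patients(self) -> list:
        return list(pd.unique(self.df["patient"]))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided exact p from the sign-permutation distribution.

    ``ranks2`` are the (midrank) ranks doubled to integers; ``w2`` is the
    doubled positive-rank sum.  The 2^n sign assignments are aggregated by a
    polynomial-product dynamic programme over achievable rank sums.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    n_all = counts.sum()
    p_le = counts[:w2 + 1].sum() / n_all
    p_ge = counts[w2:].sum() / n_all
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(diffs: Sequence[float], exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are discarded (Wilcoxon's rule) and tied absolute
    differences receive mid-ranks.  The exact permutation distribution is
    used for up to ``exact_max_n`` non-zero pairs; above that, a normal
    approximation with continuity and tie corrections.  All differences
    zero returns p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("diffs must be a non-empty 1-D sequence")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))  # midranks; multiples of 0.5
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2.0 * ranks).astype(int)
        return _exact_signed_rank_p(ranks2, int(round(2.0 * w_pos)))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = np.sum(tie_counts**3 - tie_counts) / 48.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    if sd == 0:
        return 1.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / sd
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


@dataclass(frozen=True)
class ScreenResult:
    """Per-parameter screening outcome at Bonferroni-adjusted P < alpha."""

    table: pd.DataFrame  # index: parameter; columns: p_raw, p_adjusted, passed
    m: int
    alpha: float = 0.05

    @property
    def passed(self) -> list:
        return list(self.table.index[self.table["passed"]])


def screen_parameters(table: VoxelTable, m: int | None = None,
                      alpha: float = 0.05) -> ScreenResult:
    """Wilcoxon screen of every feature on paired per-patient ROI medians.

    For each feature, each patient contributes one lesion-ROI median and one
    non-lesion median; the paired differences enter the signed-rank test and
    raw p-values are Bonferroni-adjusted over ``m`` comparisons (default:
    the number of features, 13 for the full map set).
    """
    if m is None:
        m = len(table.features)
    if m < 1:
        raise ValueError("comparison count m must be >= 1")
    med = table.df.groupby(["patient", "label"], sort=True)[list(table.features)].median()
    rows = {}
    for name in table.features:
        wide = med[name].unstack("label")
        if wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)].tolist()
            raise ValueError(f"patients missing one ROI for {name}: {bad}")
        p_raw = wilcoxon_signed_rank((wide[1] - wide[0]).to_numpy())
        p_adj = min(1.0, p_raw * m)
        rows[name] = (p_raw, p_adj, p_adj < alpha)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["p_raw", "p_adjusted", "passed"])
    return ScreenResult(table=df, m=m, alpha=alpha)


# ---------------------------------------------------------------------------
# Logistic regression (IRLS) and backward elimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticModel:
    """Fitted voxel-wise logistic classifier on z-scored features.

    Coefficients are on the standardized scale; ``predict_proba`` applies
    the stored feature means/scales, so the model can score raw tables.
    ``ridged`` flags the L2 fallback used under complete separation.
    """

    features: tuple
    intercept: float
    coef: np.ndarray
    se: np.ndarray            # intercept first, then features
    p_values: pd.Series       # Wald, per feature (intercept excluded)
    intercept_p: float
    loglik: float
    converged: bool
    ridged: bool
    feature_means: np.ndarray
    feature_scales: np.ndarray
    n_obs: int

    def linear_score(self, df: pd.DataFrame) -> np.ndarray:
        X = df[list(self.features)].to_numpy(dtype=float)
        Z = (X - self.feature_means) / self.feature_scales
        return self.intercept + Z @ self.coef

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        eta = np.clip(self.linear_score(df), -700, 700)
        return 1.0 / (1.0 + np.exp(-eta))


def _irls(Z: np.ndarray, y: np.ndarray, ridge: float = 0.0,
          max_iter: int = 100, tol: float = 1e-10):
    """Newton/IRLS for logistic ML with optional L2 penalty on slopes.

    Step-halving keeps the penalised log-likelihood non-decreasing.
    Returns (beta, cov, loglik, converged).
    """
    n, p = Z.shape
    X = np.column_stack([np.ones(n), Z])
    pen = np.zeros(p + 1)
    pen[1:] = ridge
    beta = np.zeros(p + 1)
    prev = -np.inf
    converged = False

    def loglik_of(b):
        eta = np.clip(X @ b, -700, 700)
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (pen * b * b).sum())

    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X.T * w) @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, None, loglik_of(beta), False
        ll_cur = loglik_of(beta)
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            if loglik_of(cand) >= ll_cur - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        cur = loglik_of(beta)
        if abs(cur - prev) < tol * (1.0 + abs(cur)):
            converged = True
            break
        prev = cur
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (X.T * w) @ X + np.diag(pen)
    cov = np.linalg.inv(H)
    return beta, cov, loglik_of(beta), converged


def logistic_fit(table: VoxelTable, features: Sequence[str],
                 ridge_fallback: float = 1e-3) -> LogisticModel:
    """Maximum-likelihood logistic regression of label on selected features.

    Features are z-scored internally; coefficients and Wald p-values are on
    the standardized scale.  A rank-deficient design raises; complete
    separation (detected by runaway coefficients) triggers a declared
    L2-ridge refit with penalty ``ridge_fallback * n`` on the slopes.
    """
    features = tuple(features)
    if not features:
        raise ValueError("need at least one feature")
    unknown = [f for f in features if f not in table.df.columns]
    if unknown:
        raise ValueError(f"unknown features: {unknown}")
    X = table.df[list(features)].to_numpy(dtype=float)
    y = table.df["label"].to_numpy(dtype=float)
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    if np.any(scales == 0):
        const = [f for f, s in zip(features, scales) if s == 0]
        raise ValueError(f"constant feature columns: {const}")
    Z = (X - means) / scales
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(Z)), Z])) < Z.shape[1] + 1:
        raise ValueError("design matrix is rank deficient after standardization")

    beta, cov, ll, converged = _irls(Z, y)
    ridged = False
    if cov is None or not converged or np.max(np.abs(beta)) > 15.0:
        beta, cov, ll, converged = _irls(Z, y, ridge=ridge_fallback * len(y))
        ridged = True
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    return LogisticModel(
        features=features, intercept=float(beta[0]), coef=beta[1:].copy(),
        se=se, p_values=pd.Series(p[1:], index=list(features)),
        intercept_p=float(p[0]), loglik=ll, converged=converged,
        ridged=ridged, feature_means=means, feature_scales=scales,
        n_obs=len(y))


def backward_eliminate(table: VoxelTable, candidates: Sequence[str],
                       p_remove: float = 0.05) -> LogisticModel:
    """Backward elimination on Wald p-values.

    Starting from ``candidates``, repeatedly drop the feature with the
    largest Wald p-value while any exceeds ``p_remove``, refitting at each
    step; stops when all retained features are significant or only one
    feature remains (the model is never emptied).
    """
    current = list(candidates)
    if not current:
        raise ValueError("no candidate features to eliminate from")
    model = logistic_fit(table, current)
    while len(current) > 1:
        worst = model.p_values.idxmax()
        if model.p_values[worst] <= p_remove:
            break
        current.remove(worst)
        model = logistic_fit(table, current)
    return model
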