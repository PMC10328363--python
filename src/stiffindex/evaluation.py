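"""Model evaluation: confusion metrics, the DeLong test for correlated ROC
curves, and the biomarker collinearity report.

The DeLong test compares the AUCs of two scoring rules evaluated on the
same participants. Each participant contributes a placement value (the
fraction of opposite-class participants they outrank, ties counting 1/2);
the empirical covariance of placement values across the two rules yields
the variance of the paired AUC difference, and z = dAUC / sqrt(var) is
referred to the standard normal (two-sided, no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screening import rank_auc


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


def confusion_metrics(predicted_class, true_class) -> ConfusionMetrics:
    """Standard 2x2 counts and derived ratios (positive class = 1)."""
    pred = np.asarray(predicted_class, dtype=int)
    true = np.asarray(true_class, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("predicted and true vectors must have equal length")
    if len(np.unique(true)) < 2:
        raise ValueError("both classes must be present in the truth vector")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / len(true),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
    )


@dataclass(frozen=True)
class ModelComparison:
    auc_a: float
    auc_b: float
    delong_z: float
    delong_p: float
    n: int
    degenerate: bool = False  # zero variance of the AUC difference


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-positive and per-negative placement values and the AUC.

    Midrank formulation: V10[i] = P_hat(score_i > score_neg) + 0.5 P_hat(=),
    V01[j] likewise against the positives.
    """
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (ranks[m:] - neg_ranks) / m
    auc = float(np.mean(v10))
    return v10, v01, auc


def delong_variance_components(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its placement-value vectors for one scoring rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    v10, v01, auc = _placements(scores, labels)
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> ModelComparison:
    """Paired comparison of two AUCs on the same participants.

    Returns z = (AUC_a - AUC_b)/SE and the two-sided normal p-value. Equal
    estimated AUCs report z = 0, p = 1 (including the degenerate identical-
    scores case); a zero-variance difference with unequal AUCs is flagged
    with an undefined p.
    """
    labels = np.asarray(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores and labels must be aligned on the same participants")
    auc_a, v10_a, v01_a = delong_variance_components(scores_a, labels)
    auc_b, v10_b, v01_b = delong_variance_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    if m < 2 or n < 2:
        raise ValueError("need at least two participants per class")
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return ModelComparison(auc_a, auc_b, 0.0, 1.0, len(labels), degenerate=True)
        return ModelComparison(
            auc_a, auc_b, np.nan, np.nan, len(labels), degenerate=True
        )
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return ModelComparison(auc_a, auc_b, float(z), float(min(p, 1.0)), len(labels))


def auc_variance(scores, labels) -> float:
    """DeLong variance of a single AUC (no pairing term)."""
    _, v10, v01 = delong_variance_components(scores, labels)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def collinearity_matrix(
    analysis: pd.DataFrame, biomarkers: list[str] | tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations between biomarkers (complete cases).

    Diagonal is exactly 1; a zero-variance column yields missing entries
    for its pairs.
    """
    if biomarkers is None:
        from .cohort import BIOMARKERS

        biomarkers = BIOMARKERS
    if len(biomarkers) < 2:
        raise ValueError("need at least two biomarkers")
    sub = analysis[list(biomarkers)].dropna()
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    zero_var = sub.std(ddof=0) == 0
    for col in corr.columns[zero_var]:
        corr.loc[col, :] = np.nan
        corr.loc[:, col] = np.nan
    return corr


def sanity_check_auc(scores, labels) -> float:
    """AUC used throughout evaluation (rank formulation, ties at 1/2)."""
    return rank_auc(scores, labels)
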