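"""Cutoff calibration against reader labels and cohort-level statistics.

The DCVV score separates subjects that readers call visually venous-asymmetric
(VVA) from those they do not.  :func:`roc_youden` sweeps every achievable
cutoff (midpoints between consecutive sorted unique scores, plus the two
extremes), and picks the one maximizing the Youden index J = sensitivity +
specificity - 1.  A subject is called positive when its score is strictly
greater than the cutoff, the same rule :func:`classify_vva` applies.

Group comparisons use the pooled-variance Student t-test (recomputable from
printed mean/SD/n summaries), Pearson's chi-square without continuity
correction, and Pearson's correlation coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

__all__ = [
    "CutoffCalibration",
    "roc_youden",
    "confusion_metrics",
    "confusion_metrics_from_counts",
    "ttest_from_summary",
    "chi_square",
    "pearson_r",
    "pooled_mean",
    "classify_vva",
]

logger = logging.getLogger(__name__)


@dataclass
class CutoffCalibration:
    """ROC sweep with the Youden-optimal operating point."""

    roc_points: list = field(default_factory=list)  # (cutoff, sensitivity, specificity)
    best_cutoff: float = 0.0
    youden_j: float = 0.0
    sensitivity: float = 0.0
    specificity: float = 0.0
    accuracy: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


def roc_youden(scores, labels) -> CutoffCalibration:
    """Calibrate the score cutoff by maximizing the Youden index.

    ``labels`` are binary (1 = positive class).  Candidate cutoffs are the
    midpoints between consecutive sorted unique scores plus -inf/+inf;
    positives are scores strictly greater than the cutoff.  Ties in J are
    broken toward the smallest cutoff.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D arrays of equal length")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both classes must be present")

    uniq = np.unique(scores)
    candidates = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    points = []
    best = None
    for c in candidates:
        sens = float(np.sum(pos_scores > c)) / n_pos
        spec = float(np.sum(neg_scores <= c)) / n_neg
        points.append((float(c), sens, spec))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    j, cutoff, sens, spec = best
    prevalence = n_pos / labels.size
    acc = confusion_metrics(sens, spec, prevalence)
    return CutoffCalibration(roc_points=points, best_cutoff=cutoff, youden_j=j,
                             sensitivity=sens, specificity=spec, accuracy=acc)


def confusion_metrics(sens: float, spec: float, prevalence: float) -> float:
    """Accuracy from sensitivity, specificity and prevalence."""
    for name, v in (("sensitivity", sens), ("specificity", spec),
                    ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    return sens * prevalence + spec * (1.0 - prevalence)


def confusion_metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity, specificity and accuracy from a confusion table."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must have at least one subject")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + fn + tn + fp)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries; returns (t, df, two-tailed p).

    Pooled-variance Student's t by default (df = n1+n2-2); Welch's unequal
    variance version with ``welch=True``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=not welch)
    if welch:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square of an r x c contingency table (no Yates correction).

    Returns (statistic, df, p).  Logs a warning when any expected count is
    below 5 (the asymptotic p-value is then optimistic).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin: chi-square undefined")
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected < 5):
        logger.warning("chi-square: %d expected counts < 5; asymptotic p is approximate",
                       int(np.sum(expected < 5)))
    return float(chi2), int(dof), float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-tailed t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def pooled_mean(groups) -> float:
    """Sample-size weighted mean of (mean, n) group summaries."""
    groups = list(groups)
    if not groups or any(n < 1 for _, n in groups):
        raise ValueError("each group needs n >= 1")
    total_n = sum(n for _, n in groups)
    return sum(m * n for m, n in groups) / total_n


def classify_vva(dcvv: float, cutoff: float) -> str:
    """Label a subject from its DCVV: 'VVA' iff dcvv > cutoff (tie -> 'no VVA')."""
    if dcvv < 0:
        raise ValueError("DCVV must be non-negative")
    if math.isnan(dcvv) or math.isnan(cutoff):
        raise ValueError("DCVV/cutoff must be numbers")
    return "VVA" if dcvv > cutoff else "no VVA"
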