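"""Validation statistics for presence/absence predictions.

Threshold-based: sensitivity (proportion of presences predicted present),
specificity (proportion of absences predicted absent) and their sum minus one,
the True Skill Statistic (TSS), at a fixed probability threshold (0.5 for
balanced training data).  Threshold-free: the AUC, computed by Mann-Whitney
rank counting with ties counted one half, which equals trapezoidal ROC
integration.  Values across folds and replicate datasets are averaged with a
Student-t 95% confidence interval.  The residual semivariogram is the
classical spatial-autocorrelation diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata, t as student_t

from .errors import MetricError, VariogramError

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "IntervalSummary",
    "confusion_at_threshold",
    "sensitivity",
    "specificity",
    "tss",
    "auc",
    "metric_set",
    "summarize",
    "semivariogram",
]

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ConfusionCounts:
    """Confusion counts predicting presence iff score >= threshold.

    A score exactly at the threshold counts as a predicted presence (fixed
    convention, relevant when a shrunk model predicts exactly 0.5).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise MetricError("scores and labels must have equal length")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise MetricError("scores must be probabilities in [0, 1]")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fn == 0:
        raise MetricError("sensitivity undefined: no presences in labels")
    return counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    if counts.tn + counts.fp == 0:
        raise MetricError("specificity undefined: no absences in labels")
    return counts.tn / (counts.tn + counts.fp)


def tss(counts: ConfusionCounts) -> float:
    """True Skill Statistic: sensitivity + specificity - 1, in [-1, 1]."""
    return sensitivity(counts) + specificity(counts) - 1.0


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise MetricError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    tss: float
    auc: float


def metric_set(
    scores: np.ndarray, labels: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> MetricSet:
    counts = confusion_at_threshold(scores, labels, threshold)
    sen = sensitivity(counts)
    spe = specificity(counts)
    return MetricSet(sensitivity=sen, specificity=spe, tss=sen + spe - 1.0, auc=auc(scores, labels))


@dataclass(frozen=True)
class IntervalSummary:
    """Mean with a Student-t 95% confidence interval over pooled values."""

    mean: float
    ci_low: float
    ci_high: float
    n: int
    ci_defined: bool = True


def summarize(values, confidence: float = 0.95) -> IntervalSummary:
    """Mean and t-interval across pooled fold-by-replicate metric values.

    The pooled values are treated as exchangeable; with a single value the CI
    is flagged undefined.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise MetricError("summarize requires at least one value")
    m = float(v.mean())
    if v.size < 2:
        return IntervalSummary(m, float("nan"), float("nan"), 1, ci_defined=False)
    se = float(v.std(ddof=1)) / np.sqrt(v.size)
    tq = student_t.ppf(0.5 + confidence / 2.0, v.size - 1)
    return IntervalSummary(m, m - tq * se, m + tq * se, int(v.size))


def semivariogram(
    residuals: np.ndarray, coords: np.ndarray, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical semivariogram of residuals over equal-width distance bins.

    Returns (bin centers, semivariance, pair counts); bins with no pairs get
    NaN semivariance.  Semivariance in bin b is half the mean squared
    residual difference over point pairs whose separation falls in b.
    """
    r = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    if r.size < 2:
        raise VariogramError("need at least two points")
    if xy.shape != (r.size, 2):
        raise VariogramError("coords must be (n, 2)")
    d = pdist(xy)
    dmax = d.max()
    if dmax == 0:
        raise VariogramError("all points coincident")
    sq = 0.5 * pdist(r[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, dmax, n_bins + 1)
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    gamma = np.full(n_bins, np.nan)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sq, minlength=n_bins)
    nonzero = counts > 0
    gamma[nonzero] = sums[nonzero] / counts[nonzero]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, gamma, counts
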