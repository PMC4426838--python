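"""Evaluation operations: ROC/AUC, confusion counting with the
at-or-above-threshold convention, balanced-accuracy threshold sweeps,
cross-validation folds, the binomial sign test and the minor-allele-frequency
shift diagnostic for suspected mislabeled negatives.

Conventions used throughout: a score at or above the threshold counts as a
positive prediction; AUC is the Mann-Whitney statistic (ties contribute one
half); the optimal sweep threshold maximizes balanced accuracy, taking the
smallest threshold on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .variant_data import LABEL_CONTROL, LabeledDataset

__all__ = [
    "ConfusionCounts",
    "SweepResult",
    "confusion_at_threshold",
    "balanced_accuracy",
    "roc_auc",
    "threshold_sweep",
    "kfold_cv",
    "sign_test",
    "maf_shift",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SweepResult:
    """Per-threshold balanced accuracy and false-positive rate, with the
    optimum (smallest threshold achieving the maximal balanced accuracy)."""

    thresholds: np.ndarray
    balanced_accuracy: np.ndarray
    fpr: np.ndarray
    optimal_threshold: float
    counts_at_optimum: ConfusionCounts


def _check_scores_labels(scores, labels, need_both=True):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D vectors")
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be +1/-1")
    if need_both and (not (y == 1).any() or not (y == -1).any()):
        raise ValueError("both classes must be present")
    return s, y


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Count the confusion table predicting positive iff score >= threshold."""
    s, y = _check_scores_labels(scores, labels, need_both=False)
    pred_pos = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & (y == 1))),
        fp=int(np.sum(pred_pos & (y == -1))),
        tn=int(np.sum(~pred_pos & (y == -1))),
        fn=int(np.sum(~pred_pos & (y == 1))),
    )


def balanced_accuracy(c: ConfusionCounts) -> float:
    """(sensitivity + specificity) / 2."""
    n_pos = c.tp + c.fn
    n_neg = c.tn + c.fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("balanced accuracy needs at least one example per class")
    return (c.tp / n_pos + c.tn / n_neg) / 2.0


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic
    P(s+ > s-) + 0.5 P(s+ = s-), computed from midranks."""
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = s.size - n_pos
    ranks = stats.rankdata(s)  # midranks handle ties
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def threshold_sweep(scores: Sequence[float], labels: Sequence[int]) -> SweepResult:
    """Evaluate every distinct score as a threshold (plus a sentinel above
    the maximum). This grid is exact: no finer grid changes any count."""
    s, y = _check_scores_labels(scores, labels)
    thresholds = np.unique(s)
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)
    bacc = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    counts = []
    n_neg = int(np.sum(y == -1))
    for i, thr in enumerate(thresholds):
        c = confusion_at_threshold(s, y, thr)
        counts.append(c)
        bacc[i] = balanced_accuracy(c)
        fpr[i] = c.fp / n_neg
    best = int(np.argmax(bacc))  # argmax takes the first (smallest) on ties
    return SweepResult(
        thresholds=thresholds,
        balanced_accuracy=bacc,
        fpr=fpr,
        optimal_threshold=float(thresholds[best]),
        counts_at_optimum=counts[best],
    )


def kfold_cv(
    n: int | LabeledDataset,
    k: int = 5,
    stratified: bool = False,
    labels: Sequence[int] | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold split of range(n): per-fold (train, test) indices.

    ``n`` may be a :class:`LabeledDataset`, in which case its length (and,
    for stratified folds, its labels) are used. Stratified folds preserve
    the class ratio (within one example); identical seeds give identical
    folds.
    """
    if isinstance(n, LabeledDataset):
        if labels is None:
            labels = n.labels
        n = len(n)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k examples")
    idx = np.arange(n)
    if stratified:
        if labels is None:
            raise ValueError("stratified folds require labels")
        y = np.asarray(labels)
        if np.min(np.bincount((y == 1).astype(int), minlength=2)) < k:
            raise ValueError("each class must have at least k members")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(idx, y)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(idx)]


def sign_test(wins: int, n: int) -> float:
    """One-sided binomial sign test: P(X >= wins) for X ~ Binomial(n, 1/2).

    Ties are excluded before calling; ``wins`` counts comparisons where the
    first method beat the second.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= wins <= n:
        raise ValueError("wins must lie in [0, n]")
    return float(stats.binom.sf(wins - 1, n, 0.5))


def maf_shift(
    records: pd.DataFrame,
    variants: LabeledDataset,
    cutoff: float,
    n_bins: int = 25,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Minor-allele-frequency shift between confident false positives and
    neutral predictions among labeled negatives.

    Labeled negatives are split at the posterior cutoff: posterior >=
    cutoff -> false positive, otherwise neutral. Returns the two
    normalized MAF histograms (``n_bins`` equal bins on [0, 0.5], each
    summing to 1) and mean_shift = mean MAF(neutral) - mean MAF(false
    positive); a positive shift means false positives concentrate at lower
    frequencies, the signature of mislabeled true positives among the
    controls.

    ``records`` must align row-for-row with ``variants``.
    """
    if len(records) != len(variants):
        raise ValueError("records misaligned with variants")
    labels = variants.labels
    maf = variants.df["maf"].to_numpy()
    post = records["posterior"].to_numpy()
    neg = (labels == LABEL_CONTROL) & ~np.isnan(maf) & ~np.isnan(post)
    fp_mask = neg & (post >= cutoff)
    tn_mask = neg & (post < cutoff)
    if not fp_mask.any():
        raise ValueError("no false positives at this cutoff")
    if not tn_mask.any():
        raise ValueError("no neutral predictions at this cutoff")
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    fp_hist = np.histogram(maf[fp_mask], bins=edges)[0].astype(float)
    tn_hist = np.histogram(maf[tn_mask], bins=edges)[0].astype(float)
    fp_hist /= fp_hist.sum()
    tn_hist /= tn_hist.sum()
    mean_shift = float(np.mean(maf[tn_mask]) - np.mean(maf[fp_mask]))
    return fp_hist, tn_hist, mean_shift
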