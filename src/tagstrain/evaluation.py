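"""Validation harness: confusion statistics, ROC/AUC, and k-fold calibration.

Segments are the analysis unit.  Each record carries a ground-truth label
(infarcted / healthy, e.g. from late-gadolinium-enhancement reads) and a
score — the H-spread reduction percentage assigned by the detection stage
(healthy-flagged segments carry 0).  The harness:

* counts confusion cells and the footnote rates TPR = TP/(TP+FN) and
  FPR = FP/(TN+FP) (NaN when the denominator is 0);
* sweeps score thresholds into a ROC curve with trapezoidal AUC and a
  stratified-bootstrap 95% CI;
* selects the reduction threshold alpha from a grid (10, 20, ..., 100 by
  default) as the value whose binary decision rule maximises AUC on a
  training set, ties broken toward the smaller (more sensitive) alpha;
* runs repeated k-fold cross-validation per slice level, selecting alpha
  on the training folds and scoring the held-out folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve

from .detection import DEFAULT_ALPHAS

__all__ = [
    "LabeledSegmentSet",
    "ConfusionCounts",
    "ROCResult",
    "KFoldResult",
    "DEFAULT_ALPHA_GRID",
    "confusion",
    "roc",
    "select_alpha",
    "kfold",
]

logger = logging.getLogger(__name__)

#: candidate H-spread reduction thresholds (percent)
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(float(a) for a in range(10, 101, 10))


@dataclass
class LabeledSegmentSet:
    """Ground-truth labels and detection scores for a set of segments."""

    table: pd.DataFrame  # columns: participant_id, slice_level, segment_id, truth, score

    REQUIRED = ("participant_id", "slice_level", "segment_id", "truth", "score")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.table["score"] < 0).any():
            raise ValueError("scores (reduction %) must be >= 0")
        dup = self.table.duplicated(["participant_id", "segment_id"])
        if dup.any():
            raise ValueError("one record per (participant, segment) required")
        self.table = self.table.reset_index(drop=True)

    def by_slice(self, slice_level: str) -> "LabeledSegmentSet":
        sub = self.table[self.table["slice_level"] == slice_level]
        return LabeledSegmentSet(sub.reset_index(drop=True))

    @property
    def truth(self) -> np.ndarray:
        return self.table["truth"].to_numpy(dtype=bool)

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN with the footnote rates; NaN where undefined."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        """TPR = TP / (TP + FN); NaN when no positive truth exists."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def one_minus_specificity(self) -> float:
        """FPR = FP / (TN + FP); NaN when no negative truth exists."""
        denom = self.tn + self.fp
        return self.fp / denom if denom else float("nan")

    def rates_display(self) -> tuple[float, float]:
        """(TPR, FPR) rounded to 2 decimals as reported in summary tables."""
        return (round(self.sensitivity, 2), round(self.one_minus_specificity, 2))


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci95: tuple[float, float]


@dataclass
class KFoldResult:
    """Per-slice outcome of repeated k-fold calibration."""

    slice_level: str
    alpha_correct: float  # modal training-fold selection
    alphas_selected: list[float]  # one per (repeat, fold)
    test_aucs: list[float]  # one per (repeat, fold) with both classes held out
    mean_auc: float
    confusion_at_alpha: ConfusionCounts  # whole slice set at alpha_correct


# -- operations ---------------------------------------------------------------


def confusion(predictions: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact confusion counts of boolean predictions against boolean truth."""
    predictions = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must cover the same segments")
    return ConfusionCounts(
        tp=int(np.sum(predictions & truth)),
        tn=int(np.sum(~predictions & ~truth)),
        fp=int(np.sum(predictions & ~truth)),
        fn=int(np.sum(~predictions & truth)),
    )


def roc(
    labels: np.ndarray,
    scores: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> ROCResult:
    """ROC curve over all distinct score thresholds (predict positive when
    score >= threshold), trapezoidal AUC, stratified-bootstrap 95% CI."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    ci = (float("nan"), float("nan"))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pos = np.nonzero(labels)[0]
        neg = np.nonzero(~labels)[0]
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
            )
            boot[b] = roc_auc_score(labels[idx], scores[idx])
        ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=area, ci95=ci)


def _binary_auc(labels: np.ndarray, predictions: np.ndarray) -> float:
    """AUC of a hard binary decision = (TPR + TNR) / 2 (balanced accuracy)."""
    return float(roc_auc_score(labels, predictions.astype(float)))


def select_alpha(
    labels: np.ndarray,
    scores: np.ndarray,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    fallback: float | None = None,
) -> float:
    """Grid-search the reduction threshold maximising decision AUC.

    Evaluates the hard rule *infarcted iff score >= alpha* for each grid
    value and returns the alpha with the highest AUC; ties break toward
    the smaller (more sensitive) alpha.  A single-class training set falls
    back to ``fallback`` (required in that case) with a warning.
    """
    if len(alpha_grid) == 0:
        raise ValueError("alpha grid must be nonempty")
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        if fallback is None:
            raise ValueError("single-class training set and no fallback alpha")
        warnings.warn(
            f"single-class training set: falling back to alpha={fallback}",
            stacklevel=2,
        )
        return float(fallback)
    grid = sorted(float(a) for a in alpha_grid)
    aucs = [_binary_auc(labels, scores >= a) for a in grid]
    best = int(np.argmax(aucs))  # argmax returns the first (smallest alpha) tie
    if aucs.count(max(aucs)) > 1:
        logger.info("alpha tie at AUC=%.4f; choosing smallest alpha %.0f",
                    max(aucs), grid[best])
    return grid[best]


def kfold(
    data: LabeledSegmentSet,
    k: int = 5,
    repeats: int = 10,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    seed: int = 0,
    test_fraction: float | None = None,
    by_participant: bool = False,
) -> dict[str, KFoldResult]:
    """Repeated k-fold calibration and testing, per slice level.

    For each repeat the slice's segments are shuffled and split into ``k``
    folds (or, with ``test_fraction``, into random test subsets of that
    fraction); alpha is selected on the training portion and the held-out
    portion is scored by the hard rule at that alpha.  Folds whose test
    part lacks one of the classes contribute their selected alpha but no
    test AUC.  ``by_participant`` groups folds by participant to prevent
    within-patient leakage.  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    results: dict[str, KFoldResult] = {}
    for lvl in ("basal", "midventricular", "apical"):
        sub = data.by_slice(lvl)
        if len(sub) == 0:
            continue
        labels, scores = sub.truth, sub.scores
        if labels.all() or not labels.any():
            raise ValueError(f"slice {lvl}: only one class present in the whole set")
        units = (
            sub.table["participant_id"].to_numpy()
            if by_participant
            else np.arange(len(sub))
        )
        unique_units = np.unique(units)
        alphas_sel: list[float] = []
        test_aucs: list[float] = []
        for _ in range(repeats):
            perm = rng.permutation(unique_units)
            if test_fraction is not None:
                n_test = max(1, int(round(test_fraction * len(perm))))
                folds = [perm[i : i + n_test] for i in range(0, len(perm), n_test)][:k]
            else:
                folds = np.array_split(perm, k)
            for fold_units in folds:
                test_sel = np.isin(units, fold_units)
                train_sel = ~test_sel
                a = select_alpha(
                    labels[train_sel],
                    scores[train_sel],
                    alpha_grid,
                    fallback=DEFAULT_ALPHAS[lvl],
                )
                alphas_sel.append(a)
                t_lab = labels[test_sel]
                if t_lab.all() or not t_lab.any():
                    logger.info("slice %s: single-class test fold skipped for AUC", lvl)
                    continue
                test_aucs.append(_binary_auc(t_lab, scores[test_sel] >= a))
        vals, counts = np.unique(alphas_sel, return_counts=True)
        alpha_correct = float(vals[np.argmax(counts)])
        results[lvl] = KFoldResult(
            slice_level=lvl,
            alpha_correct=alpha_correct,
            alphas_selected=alphas_sel,
            test_aucs=test_aucs,
            mean_auc=float(np.mean(test_aucs)) if test_aucs else float("nan"),
            confusion_at_alpha=confusion(scores >= alpha_correct, labels),
        )
    return results
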