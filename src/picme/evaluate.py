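"""Half-split validation, ROC/AUC and confusion-matrix metrics.

The validation protocol randomizes each class, puts half of it (the extra
sample of an odd class goes to training) into a training set, and splits
the remaining half into four equal class-stratified test folds.  The model
is trained once on the training half; a ROC curve and AUC are computed on
each of the four folds and the four AUCs averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from picme.errors import DegenerateDataError, InputError
from picme.models import (
    NEGATIVE,
    POSITIVE,
    LabeledDataset,
    RFSpec,
    SVMSpec,
    TrainedModel,
    grid_search_svm,
    train_rf,
)


@dataclass
class SplitSpec:
    """Reproducible record of one half-split: training rows + 4 test folds."""

    seed: int
    train_index: np.ndarray
    test_folds: list[np.ndarray]


@dataclass
class CVResult:
    fold_rocs: list[tuple[np.ndarray, np.ndarray, np.ndarray]]  # (fpr, tpr, thresholds)
    fold_aucs: list[float]
    mean_auc: float
    split: SplitSpec
    fold_metrics: list[dict] = field(default_factory=list)

    def to_report(self) -> dict:
        return {
            "seed": self.split.seed,
            "n_train": int(len(self.split.train_index)),
            "fold_sizes": [int(len(f)) for f in self.split.test_folds],
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "fold_metrics": self.fold_metrics,
        }


def roc_auc(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], float]:
    """ROC curve (all distinct thresholds) and tie-corrected rank AUC.

    AUC is the probability that a random positive outscores a random
    negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return (fpr, tpr, thr), auc


def half_split(y: np.ndarray, seed: int) -> SplitSpec:
    """Class-stratified half split; the held-out half becomes 4 stratified folds."""
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = (len(idx) + 1) // 2  # odd class: extra sample trains
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    folds: list[list[int]] = [[] for _ in range(4)]
    for part in test_parts:
        for j, i in enumerate(part):
            folds[j % 4].append(i)
    if any(len(f) == 0 for f in folds):
        raise DegenerateDataError("need at least 8 eligible rows per class for 4 folds")
    return SplitSpec(
        seed=seed,
        train_index=np.sort(np.concatenate(train_parts)),
        test_folds=[np.sort(np.array(f, dtype=int)) for f in folds],
    )


def _train_for_spec(data: LabeledDataset, model_spec, seed: int) -> TrainedModel:
    if isinstance(model_spec, RFSpec):
        return train_rf(data, RFSpec(model_spec.n_trees, model_spec.mtry, seed))
    if isinstance(model_spec, SVMSpec):
        return grid_search_svm(data, model_spec, seed)
    raise InputError(f"unknown model spec {type(model_spec).__name__}")


def half_split_cv(
    data: LabeledDataset, model_spec, seed: int = 0, threshold: float = 0.5
) -> CVResult:
    """Train once on the training half, evaluate ROC/AUC on each of 4 folds.

    Also records confusion metrics per fold at the given score threshold.
    Fully reproducible from the seed.
    """
    # canonical row order: results depend on the seed, never on input order
    elig = (
        data.eligible()
        .sort_values(["id1", "id2"], kind="mergesort")
        .reset_index(drop=True)
    )
    y = (elig["label"] == POSITIVE).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("both classes required")
    if min(np.bincount(y)) < 8:
        raise DegenerateDataError("need at least 8 eligible rows per class")
    split = half_split(y, seed)
    train_data = LabeledDataset(elig.iloc[split.train_index])
    model = _train_for_spec(train_data, model_spec, seed)

    from picme.models import MODEL_FEATURES  # local to keep module deps flat

    fold_rocs, fold_aucs, fold_metrics = [], [], []
    for fold in split.test_folds:
        X = elig.iloc[fold][MODEL_FEATURES].to_numpy(dtype=float)
        y_fold = y[fold]
        scores = model.score_rows(X)
        roc, auc = roc_auc(scores, y_fold)
        fold_rocs.append(roc)
        fold_aucs.append(auc)
        calls = (scores > threshold).astype(int)
        counts = ConfusionCounts(
            tp=int(np.sum((calls == 1) & (y_fold == 1))),
            tn=int(np.sum((calls == 0) & (y_fold == 0))),
            fp=int(np.sum((calls == 1) & (y_fold == 0))),
            fn=int(np.sum((calls == 0) & (y_fold == 1))),
        )
        fold_metrics.append(confusion_metrics(counts))
    return CVResult(
        fold_rocs=fold_rocs,
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        split=split,
        fold_metrics=fold_metrics,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise InputError("confusion counts must not all be zero")


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, PPV, NPV and MCC from a 2x2 confusion matrix.

    accuracy = (TP+TN)/(TP+FP+TN+FN); PPV = TP/(TP+FP); NPV = TN/(TN+FN);
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A zero MCC denominator yields MCC = 0 with ``mcc_undefined`` flagged;
    an empty PPV/NPV denominator yields NaN.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc, undefined = 0.0, True
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
        undefined = False
    return {
        "accuracy": accuracy,
        "ppv": ppv,
        "npv": npv,
        "mcc": float(mcc),
        "mcc_undefined": undefined,
    }


def compare_models(aucs_a, aucs_b) -> dict:
    """Paired Wilcoxon signed-rank comparison of two matched AUC lists."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired AUC lists must be 1-D and of equal length")
    if len(a) < 2:
        raise InputError("need at least 2 paired observations")
    diffs = a - b
    if np.all(diffs == 0):
        return {"statistic": 0.0, "pvalue": 1.0, "all_ties": True, "method": "wilcoxon"}
    res = stats.wilcoxon(a, b, alternative="two-sided")
    # two-sided scipy reports min(T+, T-); report T+ (rank-sum of positive diffs)
    t_plus = float(stats.wilcoxon(a, b, alternative="greater").statistic)
    return {
        "statistic": t_plus,
        "pvalue": float(res.pvalue),
        "all_ties": False,
        "method": "wilcoxon",
    }


def mann_whitney_u(x, y, alternative: str = "two-sided") -> dict:
    """Unpaired Mann-Whitney U test (feature-distribution comparisons)."""
    res = stats.mannwhitneyu(x, y, alternative=alternative)
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue), "method": "mannwhitneyu"}
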