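"""Random-forest (primary) and RBF-SVM (comparison) classifiers.

Both consume the four model features (ss, iccb, mmf, eld).  The
twilight-zone flag is a hard pre-filter, not a model input: after
filtering it is constant and carries no information.  Paralog is the
positive class, isoform the negative class.

The RF uses 500 trees with mtry equal to the number of model features.
The SVM standardizes features on the training rows, then picks (C, gamma)
by cross-validated accuracy on a coarse 21 x 19 decade-spaced grid
(C in 1e-5..1e15, gamma in 1e-15..1e3) followed by progressively finer
re-grids around the running optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from picme.errors import DegenerateDataError, InputError
from picme.features import MODEL_FEATURES

POSITIVE, NEGATIVE = "paralog", "isoform"
MODEL_FORMAT_VERSION = 1


@dataclass
class LabeledDataset:
    """Feature rows with class labels; only twilight-passing rows are eligible."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id1", "id2", "tz_pass", "label", *MODEL_FEATURES}
        missing = required - set(self.frame.columns)
        if missing:
            raise InputError(f"feature table missing columns {sorted(missing)}")
        keys = [tuple(sorted(k)) for k in zip(self.frame["id1"], self.frame["id2"])]
        if len(set(keys)) != len(keys):
            raise InputError("duplicate pair keys in dataset")

    def eligible(self) -> pd.DataFrame:
        return self.frame[self.frame["tz_pass"].astype(bool)]

    def Xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and 0/1 labels (paralog = 1) for eligible rows."""
        elig = self.eligible()
        unknown = set(elig["label"]) - {POSITIVE, NEGATIVE}
        if unknown:
            raise InputError(f"unlabeled or unknown labels in training data: {unknown}")
        X = elig[MODEL_FEATURES].to_numpy(dtype=float)
        y = (elig["label"] == POSITIVE).to_numpy(dtype=int)
        return X, y


@dataclass(frozen=True)
class RFSpec:
    n_trees: int = 500
    mtry: int = len(MODEL_FEATURES)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InputError("n_trees must be >= 1")
        if not 1 <= self.mtry <= len(MODEL_FEATURES):
            raise InputError(f"mtry must be in [1, {len(MODEL_FEATURES)}]")


@dataclass(frozen=True)
class SVMSpec:
    c_grid: tuple[float, ...] = tuple(np.logspace(-5, 15, 21))
    g_grid: tuple[float, ...] = tuple(np.logspace(-15, 3, 19))
    refine_rounds: int = 2
    cv_folds: int = 5

    def __post_init__(self) -> None:
        for name, grid in (("C", self.c_grid), ("g", self.g_grid)):
            arr = np.asarray(grid, dtype=float)
            if arr.ndim != 1 or len(arr) < 2:
                raise InputError(f"{name} grid must hold at least 2 points")
            if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise InputError(f"{name} grid must be positive and strictly increasing")


@dataclass
class TrainedModel:
    kind: str  # "rf" | "svm"
    estimator: object
    feature_names: list[str]
    scaler: StandardScaler | None = None
    params: dict = field(default_factory=dict)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.scaler.transform(X) if self.scaler is not None else X

    def score_rows(self, X: np.ndarray) -> np.ndarray:
        """Paralog score in [0, 1] per row."""
        Xt = self.transform(np.asarray(X, dtype=float))
        if self.kind == "rf":
            pos = list(self.estimator.classes_).index(1)
            return self.estimator.predict_proba(Xt)[:, pos]
        margins = self.estimator.decision_function(Xt)
        # Platt-style squash with fixed slope: ROC/AUC need only the ranking
        return 1.0 / (1.0 + np.exp(-margins))


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training data must contain both classes")


def train_rf(data: LabeledDataset, spec: RFSpec = RFSpec()) -> TrainedModel:
    """Fit the random forest; score = (approximately) fraction of trees voting paralog."""
    X, y = data.Xy()
    _check_two_classes(y)
    if min(np.bincount(y)) < 2:
        raise DegenerateDataError("need at least 2 rows per class")
    rf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.mtry,
        random_state=spec.seed,
    )
    rf.fit(X, y)
    return TrainedModel(
        kind="rf",
        estimator=rf,
        feature_names=list(MODEL_FEATURES),
        params={"n_trees": spec.n_trees, "mtry": spec.mtry, "seed": spec.seed},
    )


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float, folds, seed: int
) -> float:
    correct = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, test_idx in folds:
            clf = SVC(kernel="rbf", C=C, gamma=gamma, max_iter=5_000, random_state=seed)
            clf.fit(X[train_idx], y[train_idx])
            correct += int(np.sum(clf.predict(X[test_idx]) == y[test_idx]))
    return correct / len(y)


def _draw_folds(y: np.ndarray, n_folds: int, seed: int):
    """Stratified folds; redrawn with the next seed if a fold degenerates."""
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        if all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
            for tr, te in folds
        ):
            return folds
    raise DegenerateDataError("could not draw stratified CV folds with both classes")


def grid_search_svm(
    data: LabeledDataset, spec: SVMSpec = SVMSpec(), seed: int = 0
) -> TrainedModel:
    """Two-stage (C, gamma) grid search maximizing internal CV accuracy.

    Stage 1 scans the full coarse grid; each refinement round re-grids one
    current grid-spacing either side of the optimum at 10x resolution.
    Ties break toward smaller C, then smaller gamma.
    """
    X_raw, y = data.Xy()
    _check_two_classes(y)
    if min(np.bincount(y)) < 10:
        raise DegenerateDataError("grid search needs at least 10 rows per class")
    scaler = StandardScaler().fit(X_raw)
    X = scaler.transform(X_raw)
    folds = _draw_folds(y, spec.cv_folds, seed)

    def scan(c_values: np.ndarray, g_values: np.ndarray):
        best = (-np.inf, np.inf, np.inf)  # (accuracy, C, g) with min-C/min-g ties
        for C in c_values:
            for g in g_values:
                acc = _cv_accuracy(X, y, C, g, folds, seed)
                if acc > best[0] + 1e-12:
                    best = (acc, C, g)
        return best

    c_grid = np.asarray(spec.c_grid, dtype=float)
    g_grid = np.asarray(spec.g_grid, dtype=float)
    c_step = np.mean(np.diff(np.log10(c_grid)))
    g_step = np.mean(np.diff(np.log10(g_grid)))
    acc, C_best, g_best = scan(c_grid, g_grid)
    for _ in range(spec.refine_rounds):
        c_grid = np.logspace(
            np.log10(C_best) - c_step, np.log10(C_best) + c_step, len(spec.c_grid)
        )
        g_grid = np.logspace(
            np.log10(g_best) - g_step, np.log10(g_best) + g_step, len(spec.g_grid)
        )
        c_step /= 10.0
        g_step /= 10.0
        acc2, C2, g2 = scan(c_grid, g_grid)
        if acc2 >= acc:
            acc, C_best, g_best = acc2, C2, g2

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        final = SVC(
            kernel="rbf", C=C_best, gamma=g_best, max_iter=5_000, random_state=seed
        )
        final.fit(X, y)
    return TrainedModel(
        kind="svm",
        estimator=final,
        feature_names=list(MODEL_FEATURES),
        scaler=scaler,
        params={"C": float(C_best), "g": float(g_best), "cv_accuracy": float(acc), "seed": seed},
    )


def train_svm_fixed(
    data: LabeledDataset, C: float = 1.0, gamma: float = 0.25, seed: int = 0
) -> TrainedModel:
    """SVM at a fixed (C, gamma) without grid search (baseline/comparison use)."""
    X_raw, y = data.Xy()
    _check_two_classes(y)
    scaler = StandardScaler().fit(X_raw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = SVC(kernel="rbf", C=C, gamma=gamma, max_iter=5_000, random_state=seed)
        clf.fit(scaler.transform(X_raw), y)
    return TrainedModel(
        kind="svm",
        estimator=clf,
        feature_names=list(MODEL_FEATURES),
        scaler=scaler,
        params={"C": C, "g": gamma, "seed": seed},
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Score probe rows; sub-twilight rows are reported unclassifiable.

    Returns a frame with columns id1, id2, score, call where call is
    paralog (score > 0.5), isoform (score <= 0.5) or unclassifiable.
    """
    if model.feature_names != list(MODEL_FEATURES):
        raise InputError(
            f"model was trained on features {model.feature_names}, "
            f"expected {list(MODEL_FEATURES)}"
        )
    missing = [c for c in ("id1", "id2", "tz_pass", *MODEL_FEATURES) if c not in features.columns]
    if missing:
        raise InputError(f"probe table missing columns {missing}")
    out = features[["id1", "id2"]].copy()
    out["score"] = np.nan
    out["call"] = "unclassifiable"
    mask = features["tz_pass"].astype(bool).to_numpy()
    if mask.any():
        scores = model.score_rows(features.loc[mask, MODEL_FEATURES].to_numpy(dtype=float))
        out.loc[mask, "score"] = scores
        out.loc[mask, "call"] = np.where(scores > 0.5, POSITIVE, NEGATIVE)
    return out


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": model.kind,
            "feature_names": model.feature_names,
            "estimator": model.estimator,
            "scaler": model.scaler,
            "params": model.params,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise InputError(f"unsupported model file version in {path}")
    return TrainedModel(
        kind=blob["kind"],
        estimator=blob["estimator"],
        feature_names=blob["feature_names"],
        scaler=blob["scaler"],
        params=blob["params"],
    )
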