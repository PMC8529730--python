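"""Model/Results surface over the classifiers.

``ParalogIsoformClassifier`` is built from a feature frame (or straight
from simulation parameters); ``fit`` returns a ``ClassifierResults``
carrying the trained estimator, its hyperparameters, feature importances
and a text ``summary``, with ``predict`` and ``evaluate`` (half-split
cross-validation) hanging off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from picme.errors import InputError
from picme.evaluate import CVResult, half_split_cv
from picme.features import MODEL_FEATURES
from picme.models import (
    LabeledDataset,
    RFSpec,
    SVMSpec,
    TrainedModel,
    grid_search_svm,
    predict as _predict,
    train_rf,
)


class ParalogIsoformClassifier:
    """Paralog-vs-isoform classification model on the five-feature table.

    Parameters
    ----------
    features : pandas.DataFrame
        Columns id1, id2, ss, iccb, mmf, eld, tz_pass, label.  Rows with
        ``tz_pass`` False sit below the twilight-zone similarity cutoff
        and are excluded from fitting and scoring.
    """

    def __init__(self, features: pd.DataFrame):
        self.data = LabeledDataset(features)

    @classmethod
    def from_feature_frame(cls, features: pd.DataFrame) -> "ParalogIsoformClassifier":
        return cls(features)

    @classmethod
    def from_simulation(cls, params=None, **kwargs) -> "ParalogIsoformClassifier":
        """Build the model directly from the synthetic benchmark generator."""
        from picme.pipeline import simulated_feature_table
        from picme.simulate import SimParams

        if params is None:
            params = SimParams(**kwargs)
        return cls(simulated_feature_table(params))

    def fit(self, method: str = "rf", seed: int = 0, spec=None) -> "ClassifierResults":
        """Train the requested classifier on all eligible rows."""
        if method == "rf":
            spec = spec or RFSpec(seed=seed)
            model = train_rf(self.data, spec)
        elif method == "svm":
            spec = spec or SVMSpec()
            model = grid_search_svm(self.data, spec, seed=seed)
        else:
            raise InputError(f"unknown method {method!r}; use 'rf' or 'svm'")
        return ClassifierResults(model=self, trained=model, method=method, seed=seed, spec=spec)

    def evaluate(self, method: str = "rf", seed: int = 0, spec=None) -> CVResult:
        """Half-split / four-test-fold cross-validation on this data."""
        if spec is None:
            spec = RFSpec(seed=seed) if method == "rf" else SVMSpec()
        return half_split_cv(self.data, spec, seed=seed)


@dataclass
class ClassifierResults:
    model: ParalogIsoformClassifier
    trained: TrainedModel
    method: str
    seed: int
    spec: object = field(repr=False, default=None)

    @property
    def feature_importances(self) -> pd.Series | None:
        """Gini importances (random forest only)."""
        if self.trained.kind != "rf":
            return None
        return pd.Series(
            self.trained.estimator.feature_importances_, index=MODEL_FEATURES
        )

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Score probe pairs; returns id1, id2, score, call."""
        return _predict(self.trained, features)

    def evaluate(self, seed: int | None = None) -> CVResult:
        spec = self.spec if self.spec is not None else (
            RFSpec(seed=self.seed) if self.method == "rf" else SVMSpec()
        )
        return half_split_cv(self.model.data, spec, seed=self.seed if seed is None else seed)

    def summary(self) -> str:
        elig = self.model.data.eligible()
        n_pos = int((elig["label"] == "paralog").sum())
        n_neg = int((elig["label"] == "isoform").sum())
        lines = [
            "Paralog/Isoform Classifier Results",
            "=" * 40,
            f"method:           {self.method}",
            f"seed:             {self.seed}",
            f"eligible pairs:   {len(elig)} ({n_pos} paralog / {n_neg} isoform)",
            f"excluded (TZ):    {len(self.model.data.frame) - len(elig)}",
            f"features:         {', '.join(MODEL_FEATURES)}",
        ]
        for key, val in self.trained.params.items():
            lines.append(f"{key + ':':<18}{val:.6g}" if isinstance(val, float) else f"{key + ':':<18}{val}")
        imp = self.feature_importances
        if imp is not None:
            lines.append("feature importances (Gini):")
            for name, v in imp.items():
                lines.append(f"  {name:<6}{v:8.4f}")
        return "\n".join(lines)


def roc_plot(cv_result: CVResult, path=None):
    """Per-fold ROC curves with the mean AUC in the legend; optional PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for i, ((fpr, tpr, _), auc) in enumerate(
        zip(cv_result.fold_rocs, cv_result.fold_aucs), start=1
    ):
        ax.plot(fpr, tpr, lw=1, label=f"fold {i} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_title(f"mean AUC = {cv_result.mean_auc:.3f}")
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
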