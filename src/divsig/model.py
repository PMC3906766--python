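"""Model/Results layer over the classification machinery.

`SortingSignalModel` holds a feature table and a classifier configuration;
``fit()`` trains on all rows and returns a `SortingSignalResults` carrying
the fitted classifier, training diagnostics and, for the SVM, the pairwise
decision scores used by the influence measure. ``cross_validate()`` runs
the repeated stratified evaluation and returns an
:class:`~divsig.evaluate.EvaluationResult`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, examples_to_frame, train_classifier
from .evaluate import EvaluationResult, balance_classes, cross_validate
from .io import LabeledExample
from .metrics import PairwiseScoreSet, influence_score
from .pipeline import feature_subset

__all__ = ["SortingSignalModel", "SortingSignalResults", "rank_influence"]


class SortingSignalModel:
    """A sorting-signal classifier over a labeled feature table.

    Parameters
    ----------
    data
        DataFrame indexed by protein id with feature columns and a label
        column.
    feature_set
        Named subset (``div``, ``classical20``, ``classical40``,
        ``classical``, ``combo``) or an explicit list of column names.
    config
        Classifier kind and hyperparameters.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_set: str | Sequence[str] = "combo",
        label_column: str = "label",
        config: ClassifierConfig | None = None,
    ):
        if label_column not in data.columns:
            raise ValueError(f"no '{label_column}' column in data")
        self.config = config or ClassifierConfig()
        self.label_column = label_column
        all_features = [c for c in data.columns if c != label_column]
        if isinstance(feature_set, str):
            self.feature_names = feature_subset(all_features, feature_set)
            self.feature_set = feature_set
        else:
            missing = set(feature_set) - set(all_features)
            if missing:
                raise ValueError(f"unknown feature columns: {sorted(missing)}")
            self.feature_names = list(feature_set)
            self.feature_set = "custom"
        self.data = data

    @classmethod
    def from_examples(
        cls,
        examples: Sequence[LabeledExample],
        feature_set: str | Sequence[str] = "combo",
        config: ClassifierConfig | None = None,
    ) -> "SortingSignalModel":
        X, y = examples_to_frame(examples)
        X = X.copy()
        X["label"] = y
        return cls(X, feature_set=feature_set, config=config)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def y(self) -> np.ndarray:
        return self.data[self.label_column].to_numpy(dtype=object)

    def fit(self) -> "SortingSignalResults":
        model = train_classifier(self.X, self.config, y=self.y)
        return SortingSignalResults(model=self, estimator=model)

    def cross_validate(
        self,
        folds: int = 5,
        repeats: int = 5,
        seed: int = 0,
        shuffle_labels: bool = False,
    ) -> EvaluationResult:
        return cross_validate(
            self.X,
            self.config,
            folds=folds,
            repeats=repeats,
            seed=seed,
            shuffle_labels=shuffle_labels,
            y=self.y,
        )

    def balanced(self, seed: int = 0) -> "SortingSignalModel":
        """A copy subsampled so every class has the minimum class size."""
        examples = [
            LabeledExample(id=str(i), features=row[self.feature_names].to_dict(),
                           label=row[self.label_column])
            for i, row in self.data.iterrows()
        ]
        kept_ids = {ex.id for ex in balance_classes(examples, seed=seed)}
        sub = self.data.loc[[i for i in self.data.index if str(i) in kept_ids]]
        return SortingSignalModel(
            sub, feature_set=self.feature_names, label_column=self.label_column,
            config=self.config,
        )


@dataclass
class SortingSignalResults:
    """A fitted classifier plus prediction and diagnostic accessors."""

    model: SortingSignalModel
    estimator: object

    def predict(self, newdata: pd.DataFrame | None = None) -> np.ndarray:
        X = self._features(newdata)
        return self.estimator.predict(X.to_numpy(dtype=float))

    def class_posteriors(self, newdata: pd.DataFrame | None = None) -> pd.DataFrame:
        X = self._features(newdata)
        post = self.estimator.class_posteriors(X.to_numpy(dtype=float))
        post.index = X.index
        return post

    def pairwise_scores(self, newdata: pd.DataFrame | None = None) -> list[PairwiseScoreSet]:
        if not hasattr(self.estimator, "pairwise_scores"):
            raise AttributeError("pairwise scores are only available for the SVM")
        X = self._features(newdata)
        return self.estimator.pairwise_scores(X.to_numpy(dtype=float))

    def _features(self, newdata: pd.DataFrame | None) -> pd.DataFrame:
        if newdata is None:
            return self.model.X
        return newdata[self.model.feature_names]

    @property
    def training_accuracy(self) -> float:
        return float(np.mean(self.predict() == self.model.y)) * 100.0

    def summary(self) -> str:
        classes = ", ".join(sorted(set(self.model.y)))
        lines = [
            "Sorting-signal classifier",
            f"  kind:            {self.model.config.kind}",
            f"  feature set:     {self.model.feature_set} "
            f"({len(self.model.feature_names)} features)",
            f"  examples:        {len(self.model.data)}",
            f"  classes:         {classes}",
            f"  train accuracy:  {self.training_accuracy:.2f}%",
        ]
        return "\n".join(lines)


def rank_influence(
    with_scores: Sequence[PairwiseScoreSet],
    without_scores: Sequence[PairwiseScoreSet],
    ids: Sequence[str],
) -> pd.DataFrame:
    """Per-example influence of a feature group, sorted by effect size.

    Columns: influence (total-variation distance of decoded posteriors),
    label_with, label_without, flipped.
    """
    if not (len(with_scores) == len(without_scores) == len(ids)):
        raise ValueError("score lists and ids must have equal length")
    rows = []
    for pid, sw, swo in zip(ids, with_scores, without_scores):
        infl, lw, lwo = influence_score(sw, swo)
        rows.append((pid, infl, lw, lwo, lw != lwo))
    frame = pd.DataFrame(
        rows, columns=["id", "influence", "label_with", "label_without", "flipped"]
    ).set_index("id")
    return frame.sort_values("influence", ascending=False)
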