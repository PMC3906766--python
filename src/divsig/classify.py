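"""The classifiers: majority baseline, decision tree, one-vs-one RBF SVM.

The SVM follows the one-vs-one scheme: one soft-margin RBF machine per
unordered class pair (cost C = 50, gamma = 1 / number of features),
majority voting across machines, with voting ties broken by the smallest
exponential-decoding loss. Features are z-scored on training statistics
before SVM training by default, since an RBF kernel with gamma = 1/d
presumes comparable feature scales.

Each trained model exposes ``predict`` and ``class_posteriors``; the SVM
additionally exposes the raw ``pairwise_scores`` needed by the influence
measure.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import CLASS_LABELS, LabeledExample
from .metrics import DecodedScores, PairwiseScoreSet, loss_decode

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "MajorityClassifier",
    "TreeClassifier",
    "OneVsOneSVM",
    "majority_classifier",
    "train_classifier",
    "examples_to_frame",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier kind and hyperparameters.

    ``gamma=None`` means the RBF default 1 / (number of features);
    ``standardize=None`` means on for the SVM and off otherwise.
    ``tree_confidence`` controls pruning strength of the tree baseline.
    """

    kind: str = "svm"
    C: float = 50.0
    gamma: float | None = None
    tree_confidence: float = 0.25
    standardize: bool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"majority", "tree", "svm"}:
            raise ValueError(f"unknown classifier kind '{self.kind}'")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    @property
    def do_standardize(self) -> bool:
        if self.standardize is None:
            return self.kind == "svm"
        return self.standardize


def _canonical_classes(y: Sequence[str]) -> list[str]:
    present = set(y)
    unknown = present - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    return [c for c in CLASS_LABELS if c in present]


class MajorityClassifier:
    """Predicts the modal training label for every input.

    Its accuracy equals the majority class fraction; by the metric
    conventions of this package its MCC is identically 0 and its AUC 0.5.
    """

    def fit(self, X, y: Sequence[str]) -> "MajorityClassifier":
        if len(y) == 0:
            raise ValueError("empty training set")
        self.classes_ = _canonical_classes(y)
        counts = Counter(y)
        top = max(counts.values())
        tied = [c for c in self.classes_ if counts[c] == top]
        if len(tied) > 1:
            logger.info("majority tie among %s; using fixed class order", tied)
        self.majority_ = tied[0]
        return self

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), self.majority_, dtype=object)

    def class_posteriors(self, X) -> pd.DataFrame:
        p = 1.0 / len(self.classes_)
        return pd.DataFrame(p, index=range(len(X)), columns=self.classes_)


class TreeClassifier:
    """Entropy-split decision tree baseline with cost-complexity pruning."""

    def __init__(self, config: ClassifierConfig):
        self.config = config

    def fit(self, X, y: Sequence[str]) -> "TreeClassifier":
        self.classes_ = _canonical_classes(y)
        if len(self.classes_) < 2:
            raise ValueError("training set has a single class")
        # weaker confidence -> heavier pruning, loosely mirroring C4.5's knob
        alpha = 0.005 * (1.0 - self.config.tree_confidence)
        self._tree = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=2,
            ccp_alpha=alpha,
            random_state=self.config.seed,
        )
        self._tree.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict(self, X) -> np.ndarray:
        return self._tree.predict(np.asarray(X, dtype=float))

    def class_posteriors(self, X) -> pd.DataFrame:
        proba = self._tree.predict_proba(np.asarray(X, dtype=float))
        frame = pd.DataFrame(proba, columns=list(self._tree.classes_))
        return frame[[c for c in self.classes_ if c in frame.columns]]


class OneVsOneSVM:
    """One RBF SVM per class pair, majority voting, loss-decoded posteriors."""

    def __init__(self, config: ClassifierConfig):
        self.config = config

    def fit(self, X, y: Sequence[str]) -> "OneVsOneSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = _canonical_classes(y)
        if len(self.classes_) < 2:
            raise ValueError("training set has a single class")
        self._scaler = StandardScaler() if self.config.do_standardize else None
        if self._scaler is not None:
            X = self._scaler.fit_transform(X)
        gamma = self.config.gamma
        if gamma is None:
            gamma = 1.0 / X.shape[1]
        self._machines: dict[tuple[str, str], tuple[SVC, float]] = {}
        for i, a in enumerate(self.classes_):
            for b in self.classes_[i + 1 :]:
                mask = (y == a) | (y == b)
                clf = SVC(C=self.config.C, kernel="rbf", gamma=gamma)
                clf.fit(X[mask], y[mask])
                # sign so that a positive decision value favors class `a`
                sign = 1.0 if clf.classes_[1] == a else -1.0
                self._machines[(a, b)] = (clf, sign)
        return self

    @property
    def n_machines(self) -> int:
        return len(self._machines)

    def _transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._scaler is not None:
            X = self._scaler.transform(X)
        return X

    def pairwise_scores(self, X) -> list[PairwiseScoreSet]:
        """One :class:`PairwiseScoreSet` per row of ``X``."""
        X = self._transform(X)
        per_pair = {
            pair: sign * clf.decision_function(X)
            for pair, (clf, sign) in self._machines.items()
        }
        return [
            PairwiseScoreSet({pair: float(vals[i]) for pair, vals in per_pair.items()})
            for i in range(len(X))
        ]

    def decode(self, X) -> list[DecodedScores]:
        return [loss_decode(s) for s in self.pairwise_scores(X)]

    def predict(self, X) -> np.ndarray:
        scores = self.pairwise_scores(X)
        out = []
        for s in scores:
            votes = Counter()
            for (a, b), val in s.scores.items():
                votes[a if val > 0 else b] += 1
            top = max(votes.values())
            tied = [c for c in self.classes_ if votes[c] == top]
            if len(tied) == 1:
                out.append(tied[0])
            else:  # voting tie: smallest summed decoded loss, then class order
                losses = loss_decode(s).losses
                out.append(min(tied, key=lambda c: (losses[c], CLASS_LABELS.index(c))))
        return np.array(out, dtype=object)

    def class_posteriors(self, X) -> pd.DataFrame:
        decoded = self.decode(X)
        return pd.DataFrame([d.posteriors for d in decoded], columns=self.classes_)


def examples_to_frame(
    examples: Sequence[LabeledExample],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack examples into (feature DataFrame indexed by id, label array)."""
    if not examples:
        raise ValueError("no examples")
    names = list(examples[0].features)
    X = pd.DataFrame(
        [[ex.features[n] for n in names] for ex in examples],
        index=[ex.id for ex in examples],
        columns=names,
    )
    y = np.array([ex.label for ex in examples], dtype=object)
    return X, y


def majority_classifier(train: Sequence[LabeledExample]) -> MajorityClassifier:
    X, y = examples_to_frame(train)
    return MajorityClassifier().fit(X, y)


def train_classifier(train, config: ClassifierConfig, y=None):
    """Train the configured classifier.

    ``train`` is either a list of :class:`LabeledExample` or a feature
    matrix, in which case ``y`` supplies the labels.
    """
    if y is None:
        X, y = examples_to_frame(train)
    else:
        X = train
    if config.kind == "majority":
        return MajorityClassifier().fit(X, y)
    if config.kind == "tree":
        return TreeClassifier(config).fit(X, y)
    return OneVsOneSVM(config).fit(X, y)
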