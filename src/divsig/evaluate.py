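"""Cross-validated evaluation: accuracy, per-class AUC and MCC, confusion.

Evaluation is stratified k-fold cross-validation repeated with reshuffled
fold assignments; reported numbers are means and standard deviations over
the folds x repeats. Per-class AUC is one-vs-rest on held-out examples
using the class's decoded pseudo-posterior (or predicted probability) as
the score; per-class MCC is one-vs-rest on the held-out hard predictions.
A label-shuffled control (class labels permuted once before evaluation)
estimates the no-signal baseline: AUC near 0.5 and MCC near 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierConfig, examples_to_frame, train_classifier
from .io import CLASS_LABELS, LabeledExample
from .metrics import auc, mcc

__all__ = ["EvaluationResult", "cross_validate", "balance_classes"]


@dataclass
class EvaluationResult:
    """Cross-validation summary.

    ``accuracy`` is in percent; ``per_class`` holds AUC/MCC means and SDs
    per class; ``confusion`` (rows = true, columns = predicted) is averaged
    over repeats so its entries sum to the dataset size.
    """

    accuracy: float
    accuracy_sd: float
    per_class: pd.DataFrame
    confusion: pd.DataFrame
    folds: int
    repeats: int
    seed: int
    n_examples: int

    def summary(self) -> str:
        lines = [
            f"Stratified {self.folds}-fold CV x {self.repeats} repeats "
            f"(n = {self.n_examples}, seed = {self.seed})",
            f"Accuracy: {self.accuracy:.2f}% +/- {self.accuracy_sd:.2f}",
            "",
            "Per-class (one-vs-rest):",
            self.per_class.to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            "Confusion matrix (rows = true, columns = predicted):",
            self.confusion.to_string(float_format=lambda v: f"{v:.1f}"),
        ]
        return "\n".join(lines)


def _fold_scores(model, X_test: pd.DataFrame, classes: list[str]) -> pd.DataFrame:
    post = model.class_posteriors(X_test)
    missing = [c for c in classes if c not in post.columns]
    for c in missing:
        post[c] = 0.0
    return post[classes].reset_index(drop=True)


def cross_validate(
    examples,
    config: ClassifierConfig,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    shuffle_labels: bool = False,
    y=None,
) -> EvaluationResult:
    """Repeated stratified k-fold evaluation of the configured classifier.

    ``examples`` is a list of :class:`LabeledExample` or a feature matrix
    with labels in ``y``. With ``shuffle_labels`` the labels are permuted
    once (seeded) before evaluation, giving the randomized control.
    """
    if y is None:
        X, y = examples_to_frame(examples)
    else:
        X = pd.DataFrame(examples) if not isinstance(examples, pd.DataFrame) else examples
        y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    if shuffle_labels:
        y = y[rng.permutation(len(y))]
    classes = [c for c in CLASS_LABELS if c in set(y)]
    counts = pd.Series(y).value_counts()
    too_small = counts[counts < folds]
    if len(too_small):
        raise ValueError(
            f"classes {list(too_small.index)} have fewer members than folds={folds}; "
            "reduce the fold count"
        )

    acc: list[float] = []
    auc_per_class: dict[str, list[float]] = {c: [] for c in classes}
    mcc_per_class: dict[str, list[float]] = {c: [] for c in classes}
    confusion = np.zeros((len(classes), len(classes)))
    cls_index = {c: i for i, c in enumerate(classes)}
    Xv = X.to_numpy(dtype=float)

    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for train_idx, test_idx in skf.split(Xv, y):
            model = train_classifier(Xv[train_idx], config, y=y[train_idx])
            y_test = y[test_idx]
            pred = model.predict(Xv[test_idx])
            acc.append(float(np.mean(pred == y_test)) * 100.0)
            scores = _fold_scores(model, X.iloc[test_idx], classes)
            for c in classes:
                is_c = y_test == c
                auc_per_class[c].append(auc(scores[c].to_numpy(), is_c))
                pred_c = pred == c
                tp = int(np.sum(pred_c & is_c))
                fp = int(np.sum(pred_c & ~is_c))
                fn = int(np.sum(~pred_c & is_c))
                tn = int(np.sum(~pred_c & ~is_c))
                mcc_per_class[c].append(mcc(tp, fp, tn, fn))
            for t, p in zip(y_test, pred):
                confusion[cls_index[t], cls_index[p]] += 1

    per_class = pd.DataFrame(
        {
            "auc": [np.mean(auc_per_class[c]) for c in classes],
            "auc_sd": [np.std(auc_per_class[c], ddof=1) for c in classes],
            "mcc": [np.mean(mcc_per_class[c]) for c in classes],
            "mcc_sd": [np.std(mcc_per_class[c], ddof=1) for c in classes],
        },
        index=classes,
    )
    conf = pd.DataFrame(confusion / repeats, index=classes, columns=classes)
    return EvaluationResult(
        accuracy=float(np.mean(acc)),
        accuracy_sd=float(np.std(acc, ddof=1)),
        per_class=per_class,
        confusion=conf,
        folds=folds,
        repeats=repeats,
        seed=seed,
        n_examples=len(y),
    )


def balance_classes(
    examples: Sequence[LabeledExample], seed: int = 0
) -> list[LabeledExample]:
    """Subsample so every class has exactly the minimum class size.

    Uniform random sampling without replacement, deterministic given the
    seed; the surviving examples keep their original order.
    """
    labels = [ex.label for ex in examples]
    if any(lab is None for lab in labels):
        raise ValueError("all examples must be labeled")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes to balance")
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for cls in counts.index:
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        chosen = rng.choice(len(idx), size=target, replace=False)
        keep.update(idx[i] for i in chosen)
    return [ex for i, ex in enumerate(examples) if i in keep]
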