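"""Evaluation metrics and one-vs-one score decoding.

MCC follows the convention that a zero factor in the denominator yields 0,
so a constant (majority-class) predictor scores exactly 0. AUC is the
rank-based Mann-Whitney statistic with ties counted one half, so a constant
score yields exactly 0.5. Pairwise SVM scores are combined into per-class
losses by exponential loss-based decoding over the one-vs-one coding
matrix; the influence of a feature group on one example is the total
variation distance between the pseudo-posteriors decoded with and without
that group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import CLASS_LABELS

__all__ = [
    "mcc",
    "auc",
    "PairwiseScoreSet",
    "DecodedScores",
    "loss_decode",
    "influence_score",
]


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Returns 0 whenever any denominator factor is zero (e.g. a constant
    predictor), matching the Pearson-correlation reading of the statistic.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion table")
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based AUC: P(score of a positive > score of a negative), ties 1/2.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _ordered_pair(a: str, b: str) -> tuple[str, str]:
    """Order a class pair by the canonical class order."""
    return (a, b) if CLASS_LABELS.index(a) < CLASS_LABELS.index(b) else (b, a)


@dataclass(frozen=True)
class PairwiseScoreSet:
    """One-vs-one decision scores for a single example.

    Keys are class pairs ordered canonically (MTS < SP < CTP < none); a
    positive score favors the first class of the pair.
    """

    scores: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        classes = self.classes
        expected = len(classes) * (len(classes) - 1) // 2
        if len(self.scores) != expected:
            raise ValueError(
                f"expected {expected} pairwise scores for {len(classes)} classes, "
                f"got {len(self.scores)}"
            )
        for a, b in self.scores:
            if _ordered_pair(a, b) != (a, b):
                raise ValueError(f"pair ({a}, {b}) is not in canonical order")

    @property
    def classes(self) -> tuple[str, ...]:
        seen = {c for pair in self.scores for c in pair}
        return tuple(c for c in CLASS_LABELS if c in seen)

    def negated(self) -> "PairwiseScoreSet":
        return PairwiseScoreSet({pair: -s for pair, s in self.scores.items()})


@dataclass(frozen=True)
class DecodedScores:
    """Per-class exponential losses and the normalized pseudo-posterior."""

    losses: Mapping[str, float]
    posteriors: Mapping[str, float]

    @property
    def label(self) -> str:
        """Arg-min-loss class; ties broken by canonical class order."""
        best = min(self.losses.values())
        return next(c for c in CLASS_LABELS if self.losses.get(c) == best)


def loss_decode(scores: PairwiseScoreSet) -> DecodedScores:
    """Exponential loss-based decoding of one-vs-one scores.

    With the one-vs-one coding matrix M (M[c, (a, b)] = +1 if c == a, -1 if
    c == b, 0 otherwise), the loss of class c is
    ``sum over its machines of exp(-M[c, pair] * score(pair))``; a lower
    loss means a more favored class. Pseudo-posteriors are proportional to
    the reciprocal losses.
    """
    classes = scores.classes
    losses: dict[str, float] = {}
    for c in classes:
        total = 0.0
        for (a, b), s in scores.scores.items():
            if c == a:
                total += math.exp(-s)
            elif c == b:
                total += math.exp(s)
        losses[c] = total
    inv = {c: 1.0 / losses[c] for c in classes}
    z = sum(inv.values())
    posteriors = {c: inv[c] / z for c in classes}
    return DecodedScores(losses=losses, posteriors=posteriors)


def influence_score(
    scores_with: PairwiseScoreSet, scores_without: PairwiseScoreSet
) -> tuple[float, str, str]:
    """How much a feature group moved one example's decoded prediction.

    Returns the total variation distance between the pseudo-posteriors
    decoded from the two score sets, together with the decoded labels
    (with, without). Ranking examples by this score lists prediction flips
    by effect size.
    """
    if scores_with.classes != scores_without.classes:
        raise ValueError("score sets must cover the same classes")
    dw = loss_decode(scores_with)
    dwo = loss_decode(scores_without)
    tv = 0.5 * sum(
        abs(dw.posteriors[c] - dwo.posteriors[c]) for c in scores_with.classes
    )
    return float(tv), dw.label, dwo.label
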