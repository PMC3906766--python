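"""Single-feature importance: MDL discretization plus information gain.

A continuous feature F is first binned by the Fayyad-Irani minimum
description length (MDL) procedure: recursively place the binary cut that
minimizes the class-label entropy of the two halves, accepting a cut at
threshold T on a set S of N examples only when

    Gain(S, T) > log2(N - 1) / N + Delta(S, T) / N,
    Delta(S, T) = log2(3^k - 2) - [k*Ent(S) - k1*Ent(S1) - k2*Ent(S2)],

with k, k1, k2 the numbers of classes present in S and its halves.
Candidate thresholds are midpoints between adjacent distinct values whose
class memberships differ (boundary points), which provably contains the
optimal cut. The importance of the binned feature is the information gain

    I(C, F) = H(C) - H(C | F)

in bits: the reduction in class-label entropy once the bin is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import LabeledExample

__all__ = [
    "Discretization",
    "FeatureImportance",
    "mdl_discretize",
    "information_gain",
    "rank_features",
]


@dataclass(frozen=True)
class Discretization:
    """Strictly increasing cut points; an empty tuple means a single bin."""

    cuts: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut points must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.cuts) + 1

    def assign(self, values: Sequence[float]) -> np.ndarray:
        """Bin index per value (0-based); values below the first cut get 0."""
        return np.digitize(np.asarray(values, dtype=float), self.cuts)


@dataclass(frozen=True)
class FeatureImportance:
    feature: str
    gain: float
    discretization: Discretization


def _entropy_of_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def _label_entropy(codes: np.ndarray, n_classes: int) -> float:
    return _entropy_of_counts(np.bincount(codes, minlength=n_classes))


def _recurse(values: np.ndarray, codes: np.ndarray, n_classes: int, cuts: list[float]) -> None:
    """Find the best accepted cut in the (sorted) block and recurse."""
    n = len(values)
    if n < 2:
        return
    # boundary candidates: adjacent distinct values with differing class content
    cand: list[int] = []  # split before index i
    for i in range(1, n):
        if values[i] > values[i - 1]:
            left = codes[np.flatnonzero(values == values[i - 1])]
            right = codes[np.flatnonzero(values == values[i])]
            lset, rset = set(left.tolist()), set(right.tolist())
            if not (len(lset) == 1 and lset == rset):
                cand.append(i)
    if not cand:
        return
    ent_s = _label_entropy(codes, n_classes)
    best_i, best_we = -1, np.inf
    for i in cand:
        we = (i / n) * _label_entropy(codes[:i], n_classes) + (
            (n - i) / n
        ) * _label_entropy(codes[i:], n_classes)
        if we < best_we - 1e-12:
            best_we, best_i = we, i
    gain = ent_s - best_we
    k = len(set(codes.tolist()))
    left, right = codes[:best_i], codes[best_i:]
    k1, k2 = len(set(left.tolist())), len(set(right.tolist()))
    ent1 = _label_entropy(left, n_classes)
    ent2 = _label_entropy(right, n_classes)
    delta = np.log2(3.0**k - 2.0) - (k * ent_s - k1 * ent1 - k2 * ent2)
    threshold = (np.log2(n - 1) + delta) / n
    if gain <= threshold:
        return
    cuts.append(float((values[best_i - 1] + values[best_i]) / 2.0))
    _recurse(values[:best_i], codes[:best_i], n_classes, cuts)
    _recurse(values[best_i:], codes[best_i:], n_classes, cuts)


def mdl_discretize(values: Sequence[float], labels: Sequence[str]) -> Discretization:
    """Fayyad-Irani MDL binning of a continuous feature against class labels.

    Examples with equal feature values are never split apart. A feature
    with a single distinct value (or no accepted cut) yields an empty
    discretization, i.e. one bin.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must have the same length")
    if len(values) == 0:
        raise ValueError("need at least one example")
    order = np.argsort(values, kind="stable")
    _, codes = np.unique(labels, return_inverse=True)
    cuts: list[float] = []
    _recurse(values[order], codes[order], len(set(codes.tolist())), cuts)
    return Discretization(cuts=tuple(sorted(cuts)))


def information_gain(
    values: Sequence[float], labels: Sequence[str], discretization: Discretization
) -> float:
    """I(C, F) = H(C) - H(C|F) in bits, on the discretized feature."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    n_classes = int(codes.max()) + 1 if len(codes) else 0
    n = len(values)
    h_c = _label_entropy(codes, n_classes)
    bins = discretization.assign(values)
    h_c_given_f = 0.0
    for b in np.unique(bins):
        mask = bins == b
        h_c_given_f += (mask.sum() / n) * _label_entropy(codes[mask], n_classes)
    return float(h_c - h_c_given_f)


def rank_features(examples: Sequence[LabeledExample]) -> list[FeatureImportance]:
    """Discretize-then-gain for every feature, sorted by descending gain.

    Ties are broken by feature name so the ranking is deterministic.
    """
    labels = [ex.label for ex in examples]
    if any(lab is None for lab in labels):
        raise ValueError("all examples must be labeled")
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes to rank features")
    names = list(examples[0].features)
    out: list[FeatureImportance] = []
    for name in names:
        vals = [ex.features[name] for ex in examples]
        disc = mdl_discretize(vals, labels)
        out.append(FeatureImportance(name, information_gain(vals, labels, disc), disc))
    return sorted(out, key=lambda fi: (-fi.gain, fi.feature))
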