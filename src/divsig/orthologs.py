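"""Reciprocal-best-hit ortholog sets under global alignment similarity.

Orthologs of a reference protein are defined operationally: protein P of
species S and P' of species S' are reciprocal best hits (RBHs) if each is
the other's strictly highest-scoring match under global (end-to-end)
alignment. Global rather than local alignment is used deliberately: an
"ortholog" that differs at the N- or C-terminus may carry a different
sorting signal, and that difference should depress its score.

The ortholog set of a reference protein is the protein plus all of its
RBHs, one per other species; sets with fewer than four sequences are
discarded by default because the divergence score only stabilizes with
four or more rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment scoring: substitution matrix plus affine gap costs.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps
    are penalized like internal ones (true global alignment).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    max_length: int = 20_000

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


@dataclass
class OrthologSet:
    """A reference protein and its RBHs across species."""

    reference: SequenceRecord
    members: list[tuple[str, SequenceRecord]]

    @property
    def size(self) -> int:
        return 1 + len(self.members)

    def records(self) -> list[SequenceRecord]:
        return [self.reference] + [rec for _, rec in self.members]


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align_score(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams = AlignParams()
) -> float:
    """Optimal global alignment score of two proteins; symmetric in a, b."""
    for rec in (a, b):
        if len(rec) > params.max_length:
            raise ValueError(
                f"sequence '{rec.id}' exceeds the maximum length {params.max_length}"
            )
    aligner = _make_aligner(params)
    return float(aligner.score(a.residues, b.residues))


def _score_matrix(
    proteome_a: Sequence[SequenceRecord],
    proteome_b: Sequence[SequenceRecord],
    params: AlignParams,
) -> np.ndarray:
    aligner = _make_aligner(params)
    for rec in list(proteome_a) + list(proteome_b):
        if len(rec) > params.max_length:
            raise ValueError(
                f"sequence '{rec.id}' exceeds the maximum length {params.max_length}"
            )
    scores = np.empty((len(proteome_a), len(proteome_b)))
    for i, ra in enumerate(proteome_a):
        for j, rb in enumerate(proteome_b):
            scores[i, j] = aligner.score(ra.residues, rb.residues)
    return scores


def _unique_argmax(row: np.ndarray) -> int | None:
    """Index of the strict maximum, or None on a tie."""
    best = np.max(row)
    hits = np.flatnonzero(row == best)
    return int(hits[0]) if len(hits) == 1 else None


def reciprocal_best_hits(
    proteome_a: Sequence[SequenceRecord],
    proteome_b: Sequence[SequenceRecord],
    params: AlignParams = AlignParams(),
) -> list[tuple[str, str]]:
    """RBH pairs (idA, idB) between two proteomes.

    A pair is reported only when each protein is the *unique* best hit of
    the other; score ties yield no pair. Every protein appears in at most
    one pair, so the result is a one-to-one partial matching. All-vs-all
    scoring: quadratic in proteome sizes, intended for modest inputs.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    for side in (proteome_a, proteome_b):
        ids = [r.id for r in side]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids within a proteome")
    scores = _score_matrix(proteome_a, proteome_b, params)
    pairs: list[tuple[str, str]] = []
    for i, ra in enumerate(proteome_a):
        j = _unique_argmax(scores[i, :])
        if j is None:
            logger.info("tie for best hit of '%s'; no RBH emitted", ra.id)
            continue
        if _unique_argmax(scores[:, j]) == i:
            pairs.append((ra.id, proteome_b[j].id))
    return pairs


def build_ortholog_sets(
    reference_proteome: Sequence[SequenceRecord],
    other_proteomes: Mapping[str, Sequence[SequenceRecord]],
    params: AlignParams = AlignParams(),
    min_size: int = 4,
) -> list[OrthologSet]:
    """Assemble one candidate ortholog set per reference protein.

    RBHs are computed independently between the reference proteome and each
    other species (no transitive clustering). Sets smaller than ``min_size``
    sequences are discarded and the discarded count logged.
    """
    members: dict[str, list[tuple[str, SequenceRecord]]] = {
        rec.id: [] for rec in reference_proteome
    }
    for species, proteome in other_proteomes.items():
        by_id = {rec.id: rec for rec in proteome}
        for ref_id, other_id in reciprocal_best_hits(reference_proteome, proteome, params):
            members[ref_id].append((species, by_id[other_id]))
    retained: list[OrthologSet] = []
    discarded = 0
    for rec in reference_proteome:
        oset = OrthologSet(reference=rec, members=members[rec.id])
        if oset.size >= min_size:
            retained.append(oset)
        else:
            discarded += 1
    logger.info(
        "retained %d ortholog sets, discarded %d with fewer than %d sequences",
        len(retained), discarded, min_size,
    )
    return retained
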