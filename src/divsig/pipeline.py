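"""Feature extraction over ortholog MSAs and feature-set bookkeeping."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

from .divergence import DIVERGENCE_FEATURE_NAMES, divergence_features, entropy_profile
from .io import Alignment, LabelTable, LabeledExample, read_fasta
from .seqfeatures import composition_features, physchem_features

logger = logging.getLogger(__name__)

__all__ = ["family_features", "build_examples", "examples_from_dir", "feature_subset"]

FEATURE_GROUPS = ("div", "phys", "comp")


def family_features(
    alignment: Alignment,
    include: Sequence[str] = FEATURE_GROUPS,
    ld_positions: tuple[int, ...] = (),
) -> dict[str, float] | None:
    """Feature dict for one orthoMSA, or None if the reference is too short.

    Divergence features are read off the gap-aware entropy profile in
    reference coordinates; classical features use the ungapped reference.
    """
    feats: dict[str, float] = {}
    if "div" in include:
        profile = entropy_profile(alignment)
        vec = divergence_features(profile, ld_positions=ld_positions)
        if vec.flagged_short:
            logger.info(
                "reference '%s' shorter than 80 residues; excluded", alignment.reference_id
            )
            return None
        feats.update(vec.as_dict())
    ref = alignment.reference
    unaligned = type(ref)(id=ref.id, residues=ref.ungapped, species=ref.species)
    if "phys" in include:
        feats.update(physchem_features(unaligned))
    if "comp" in include:
        feats.update(composition_features(unaligned))
    return feats


def build_examples(
    alignments: Iterable[Alignment],
    labels: LabelTable | None = None,
    include: Sequence[str] = FEATURE_GROUPS,
    ld_positions: tuple[int, ...] = (),
) -> list[LabeledExample]:
    """Extract one labeled example per alignment; short references skipped."""
    out: list[LabeledExample] = []
    for aln in alignments:
        feats = family_features(aln, include=include, ld_positions=ld_positions)
        if feats is None:
            continue
        pid = aln.reference_id
        label = labels[pid] if labels is not None and pid in labels else None
        out.append(LabeledExample(id=pid, features=feats, label=label))
    return out


def examples_from_dir(
    msa_dir: str | Path,
    labels: LabelTable | None = None,
    include: Sequence[str] = FEATURE_GROUPS,
    ld_positions: tuple[int, ...] = (),
) -> list[LabeledExample]:
    """Read every ``*.fasta`` in a directory as an orthoMSA and featurize it.

    The first record of each file is taken as the reference sequence.
    """
    paths = sorted(Path(msa_dir).glob("*.fasta"))
    if not paths:
        raise ValueError(f"no .fasta files in {msa_dir}")
    alignments = (read_fasta(p, aligned=True) for p in paths)
    return build_examples(alignments, labels=labels, include=include, ld_positions=ld_positions)


def feature_subset(names: Sequence[str], which: str) -> list[str]:
    """Select the feature columns of a named feature set.

    ``div`` — the divergence vector (plus any LD features);
    ``classical20``/``classical40`` — charge, hydropathy and composition of
    the corresponding N-terminal window; ``classical`` — every
    non-divergence feature; ``combo`` — everything.
    """
    div = set(DIVERGENCE_FEATURE_NAMES)

    def is_div(n: str) -> bool:
        return n in div or n.startswith("LD")

    if which == "div":
        picked = [n for n in names if is_div(n)]
    elif which == "classical20":
        picked = [n for n in names if n.endswith("20") or n.startswith("comp20_")]
        picked = [n for n in picked if not is_div(n)]
    elif which == "classical40":
        picked = [n for n in names if n.endswith("40") or n.startswith("comp40_")]
        picked = [n for n in picked if not is_div(n)]
    elif which == "classical":
        picked = [n for n in names if not is_div(n)]
    elif which == "combo":
        picked = list(names)
    else:
        raise ValueError(f"unknown feature set '{which}'")
    if not picked:
        raise ValueError(f"feature set '{which}' selects no columns")
    return picked
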