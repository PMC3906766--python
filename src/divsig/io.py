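"""Sequence and table I/O for the sorting-signal divergence pipeline.

Reads aligned and unaligned FASTA, class-label tables and feature tables,
and validates ortholog multiple sequence alignments (orthoMSAs): every row
the same length, a designated reference sequence present, no all-gap rows.
Violations raise; nothing is silently truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: 'X' (unknown residue) is accepted everywhere; physico-chemical code skips it.
VALID_RESIDUES = frozenset(AA20 + "X")
GAP = "-"
#: Canonical class vocabulary and tie-break order.
CLASS_LABELS = ("MTS", "SP", "CTP", "none")

_SPECIES_BRACKET = re.compile(r"\[([^\]]+)\]\s*$")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence, optionally tagged with its species of origin."""

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence '{self.id}' is empty")
        if not self.species:
            object.__setattr__(self, "species", self.id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """An ortholog MSA with a designated reference sequence.

    Invariants enforced at construction: >=2 rows, all rows the same length,
    exactly one row whose id equals ``reference_id``, no all-gap row.
    """

    rows: list[SequenceRecord]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        width = len(self.rows[0])
        for rec in self.rows:
            if len(rec) != width:
                raise ValueError(
                    f"unequal row lengths: record '{rec.id}' has length "
                    f"{len(rec)}, expected {width}"
                )
            if set(rec.residues) <= {GAP}:
                raise ValueError(f"record '{rec.id}' is all gaps")
        hits = [r for r in self.rows if r.id == self.reference_id]
        if len(hits) != 1:
            raise ValueError(
                f"reference id '{self.reference_id}' matches {len(hits)} rows, "
                "expected exactly 1"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def reference(self) -> SequenceRecord:
        return next(r for r in self.rows if r.id == self.reference_id)

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range 1..{self.n_cols}")
        return "".join(r.residues[col - 1] for r in self.rows)

    def reference_columns(self) -> list[int]:
        """1-based MSA columns holding the reference's non-gap residues.

        Entry ``i`` (0-based) is the column of reference residue ``i + 1``.
        """
        ref = self.reference.residues
        return [c + 1 for c, ch in enumerate(ref) if ch != GAP]


@dataclass(frozen=True)
class LabelTable:
    """Mapping from reference protein id to sorting-signal class."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        for pid, lab in self.labels.items():
            if lab not in CLASS_LABELS:
                raise ValueError(
                    f"unknown class '{lab}' for '{pid}'; "
                    f"allowed labels: {', '.join(CLASS_LABELS)}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pid: str) -> str:
        return self.labels[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.labels

    def items(self):
        return self.labels.items()


@dataclass
class LabeledExample:
    """A named feature vector with an optional class label."""

    id: str
    features: dict[str, float]
    label: str | None = None


def _parse_species(rec_id: str, description: str) -> tuple[str, str]:
    """Split a FASTA id into (protein id, species tag).

    Supports ``id|species`` and a trailing bracketed ``[species]`` in the
    description; otherwise the species defaults to the id itself.
    """
    if "|" in rec_id:
        pid, species = rec_id.split("|", 1)
        if pid and species:
            return pid, species
    m = _SPECIES_BRACKET.search(description)
    if m:
        return rec_id, m.group(1)
    return rec_id, rec_id


def _validate_residues(pid: str, seq: str, aligned: bool) -> str:
    seq = seq.upper()
    if seq.endswith("*"):  # trailing stop only; internal '*' is an error
        seq = seq[:-1]
    allowed = VALID_RESIDUES | ({GAP} if aligned else set())
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(
                f"illegal residue character '{ch}' at position {pos} "
                f"of record '{pid}'"
            )
    if not aligned and GAP in seq:
        raise ValueError(f"gap character in unaligned record '{pid}'")
    return seq


def read_fasta(
    path: str | Path,
    aligned: bool = False,
    reference_id: str | None = None,
) -> list[SequenceRecord] | Alignment:
    """Read a FASTA file of protein sequences.

    Parameters
    ----------
    path
        FASTA file; '>' headers, wrapped lines allowed, ';' comments rejected.
    aligned
        If true, validate the records as an MSA and return an :class:`Alignment`.
    reference_id
        Reference row of the alignment; defaults to the first record.
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(";"):
            raise ValueError(f"';' comment lines are not supported (line {lineno})")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            pid, species = _parse_species(rec.id, rec.description)
            seq = _validate_residues(pid, str(rec.seq), aligned)
            if pid in seen:
                raise ValueError(f"duplicate sequence id '{pid}' in {path}")
            seen.add(pid)
            records.append(SequenceRecord(id=pid, residues=seq, species=species))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    if not aligned:
        return records
    ref = reference_id if reference_id is not None else records[0].id
    return Alignment(rows=records, reference_id=ref)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.species == rec.id else f"{rec.id}|{rec.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_labels(path: str | Path) -> LabelTable:
    """Read a two-column TSV of (protein id, class label); header optional."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"expected 2 tab-separated columns at line {lineno}")
            pid, lab = (p.strip() for p in parts)
            if lineno == 1 and lab.lower() in {"label", "class"}:
                continue
            if lab not in CLASS_LABELS:
                raise ValueError(
                    f"unknown class '{lab}' at line {lineno}; "
                    f"allowed labels: {', '.join(CLASS_LABELS)}"
                )
            if pid in labels:
                raise ValueError(f"duplicate id '{pid}' at line {lineno}")
            labels[pid] = lab
    return LabelTable(labels=labels)


def write_labels(table: LabelTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for pid, lab in table.items():
            fh.write(f"{pid}\t{lab}\n")


_NO_LABEL = "NA"


def write_feature_table(examples: Sequence[LabeledExample], path: str | Path) -> None:
    """Write examples as a TSV: header ``id  label  <feature names>``.

    Feature order is taken from the first example and must be shared by all;
    floats are written with enough digits to round-trip through
    :func:`read_feature_table` to 1e-9.
    """
    if not examples:
        with open(path, "w") as fh:
            fh.write("id\tlabel\n")
        return
    names = list(examples[0].features)
    nameset = set(names)
    for ex in examples:
        if set(ex.features) != nameset:
            raise ValueError(
                f"example '{ex.id}' has a different feature set than '{examples[0].id}'"
            )
    with open(path, "w") as fh:
        fh.write("id\tlabel\t" + "\t".join(names) + "\n")
        for ex in examples:
            vals = "\t".join(format(ex.features[n], ".12g") for n in names)
            fh.write(f"{ex.id}\t{ex.label or _NO_LABEL}\t{vals}\n")


def read_feature_table(path: str | Path) -> list[LabeledExample]:
    """Inverse of :func:`write_feature_table`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "label"]:
            raise ValueError("feature table must start with 'id' and 'label' columns")
        names = header[2:]
        out: list[LabeledExample] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            pid, lab = parts[0], parts[1]
            feats = {n: float(v) for n, v in zip(names, parts[2:], strict=True)}
            out.append(
                LabeledExample(id=pid, features=feats, label=None if lab == _NO_LABEL else lab)
            )
    return out
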