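"""Synthetic ortholog families with N-terminal signal-like divergence.

The generator emulates the statistical structure the divergence score
exploits: proteins carrying an N-terminal sorting signal evolve faster in
the signal region than in the protein body, with class-dependent
composition. An ancestral sequence is drawn from class-conditional,
position-specific residue frequencies and each ortholog evolves
independently down a star phylogeny: every site mutates with probability
``background_rate``, multiplied by ``rho`` inside the signal region, by
redrawing from the position's frequency profile. Signal-region indels are
realized as gap characters in non-reference rows, so the reference stays
ungapped and reference-coordinate mapping is exercised by hand-made
fixtures instead.

Class anatomy (region = positions 1..20 for MTS and SP, 1..50 for CTP):

* MTS — arginine/lysine-rich, acidic residues depleted;
* SP — weakly basic n-region (1-5), strongly hydrophobic h-region (6-15),
  small-residue c-region (16-20);
* CTP — serine-rich over a longer region;
* none — background frequencies and background rate everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .io import AA20, CLASS_LABELS, Alignment, LabelTable, SequenceRecord, write_fasta, write_labels

__all__ = ["SimulationParams", "SyntheticFamily", "simulate_family", "simulate_dataset"]

#: Average proteome amino-acid frequencies (Swiss-Prot-like), AA20 order.
BACKGROUND_FREQS = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0674, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0582, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}

# per-class composition biases: multiplicative tilts applied to the
# background, per signal sub-region (half-open 0-based position ranges)
_CLASS_TILTS: dict[str, list[tuple[int, int, dict[str, float]]]] = {
    "MTS": [
        (0, 20, {"R": 4.0, "K": 2.5, "S": 2.0, "L": 1.5, "A": 1.5, "D": 0.1, "E": 0.1}),
    ],
    "SP": [
        (0, 5, {"K": 2.0, "R": 1.5}),
        (5, 15, {"L": 3.0, "I": 2.5, "V": 2.5, "F": 2.0, "A": 1.5,
                 "D": 0.05, "E": 0.05, "K": 0.05, "R": 0.05}),
        (15, 20, {"A": 2.5, "G": 1.5, "S": 1.5, "D": 0.3, "E": 0.3, "K": 0.3, "R": 0.3}),
    ],
    "CTP": [
        (0, 50, {"S": 3.0, "T": 1.5, "A": 1.5, "R": 1.3, "K": 1.3, "D": 0.2, "E": 0.2}),
    ],
    "none": [],
}

_DEFAULT_SIGNAL_LENGTHS = MappingProxyType({"MTS": 20, "SP": 20, "CTP": 50, "none": 0})


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the generator.

    ``n_species`` counts the reference plus its orthologs (an 11-species
    panel by default). ``rho`` multiplies the per-site substitution
    probability inside the signal region; ``indel_rate`` is the per-cell
    probability of a gap at a signal-region position of a non-reference row.
    """

    n_species: int = 11
    length_range: tuple[int, int] = (150, 500)
    signal_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_SIGNAL_LENGTHS)
    )
    rho: float = 4.0
    background_rate: float = 0.15
    indel_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.rho < 1.0:
            raise ValueError("rho must be >= 1")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be a probability")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be a probability")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        if max(self.signal_lengths.values()) >= self.length_range[0]:
            raise ValueError("signal length must be shorter than every protein")

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "length_range": list(self.length_range),
            "signal_lengths": dict(self.signal_lengths),
            "rho": self.rho,
            "background_rate": self.background_rate,
            "indel_rate": self.indel_rate,
        }


@dataclass
class SyntheticFamily:
    """One labeled ortholog family: a gap-free reference plus orthologs."""

    label: str
    alignment: Alignment
    params: SimulationParams
    seed: int

    @property
    def reference(self) -> SequenceRecord:
        return self.alignment.reference


def _position_frequencies(label: str, length: int, signal_len: int) -> np.ndarray:
    """(length, 20) per-position residue probabilities for one class."""
    base = np.array([BACKGROUND_FREQS[aa] for aa in AA20])
    base = base / base.sum()
    probs = np.tile(base, (length, 1))
    for lo, hi, tilt in _CLASS_TILTS[label]:
        hi = min(hi, signal_len, length)
        if lo >= hi:
            continue
        row = base.copy()
        for aa, mult in tilt.items():
            row[AA20.index(aa)] *= mult
        probs[lo:hi] = row / row.sum()
    return probs


def simulate_family(
    label: str,
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
    family_id: str | None = None,
) -> SyntheticFamily:
    """Draw one ortholog family of the given class; deterministic in seed."""
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown class '{label}'")
    rng = np.random.default_rng(seed)
    lo, hi = params.length_range
    length = int(rng.integers(lo, hi + 1))
    signal_len = int(params.signal_lengths.get(label, 0))
    probs = _position_frequencies(label, length, signal_len)
    aa_idx = np.arange(20)

    def _draw(p: np.ndarray) -> np.ndarray:
        # vectorized categorical draw, one per row of p
        cum = np.cumsum(p, axis=1)
        u = rng.random((len(p), 1))
        return (u > cum).sum(axis=1)

    ancestral = _draw(probs)
    sub_p = np.full(length, params.background_rate)
    if signal_len:
        sub_p[:signal_len] = np.minimum(params.background_rate * params.rho, 0.95)

    fid = family_id or f"{label}-fam{seed}"
    aa = np.array(list(AA20))
    rows = [SequenceRecord(id=fid, residues="".join(aa[ancestral]), species="ref")]
    for k in range(1, params.n_species):
        seq = ancestral.copy()
        mutate = rng.random(length) < sub_p
        if mutate.any():
            seq[mutate] = _draw(probs[mutate])
        chars = aa[seq]
        if signal_len and params.indel_rate > 0:
            gaps = rng.random(signal_len) < params.indel_rate
            chars[:signal_len][gaps] = "-"
        residues = "".join(chars)
        if set(residues) == {"-"}:  # vanishingly unlikely; keep row valid
            residues = "".join(aa[seq])
        rows.append(SequenceRecord(id=f"{fid}_s{k}", residues=residues, species=f"sp{k}"))
    alignment = Alignment(rows=rows, reference_id=fid)
    return SyntheticFamily(label=label, alignment=alignment, params=params, seed=seed)


def simulate_dataset(
    class_counts: Mapping[str, int],
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticFamily], LabelTable]:
    """Independent families with exact class counts and distinct ids.

    With ``out_dir`` the dataset is also written to disk: one aligned FASTA
    per family under ``msa/``, a ``labels.tsv`` and a ``params.json``.
    """
    for label, n in class_counts.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class '{label}'")
        if n < 0:
            raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    families: list[SyntheticFamily] = []
    labels: dict[str, str] = {}
    for label in CLASS_LABELS:
        for i in range(class_counts.get(label, 0)):
            fam_seed = int(rng.integers(2**31))
            fid = f"{label}{i + 1:04d}"
            fam = simulate_family(label, params, seed=fam_seed, family_id=fid)
            families.append(fam)
            labels[fid] = label
    table = LabelTable(labels=labels)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "msa").mkdir(parents=True, exist_ok=True)
        for fam in families:
            write_fasta(fam.alignment.rows, out / "msa" / f"{fam.label}_{fam.reference.id}.fasta")
        write_labels(table, out / "labels.tsv")
        with open(out / "params.json", "w") as fh:
            json.dump({"seed": seed, "params": params.to_dict()}, fh, indent=2)
    return families, table
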