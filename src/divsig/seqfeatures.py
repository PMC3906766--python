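"""Classical sequence features: charge counts, hydropathy, composition.

All features are computed on the unaligned reference protein over one of
three windows: the first 20 residues, the first 40 residues, or the whole
sequence. Charged residues are R/K (positive) and D/E (negative) at
physiological pH — histidine is excluded. Hydrophobicity is the mean
Kyte-Doolittle hydropathy index over the window.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import AA20, SequenceRecord

#: Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

POSITIVE_RESIDUES = frozenset("RK")
NEGATIVE_RESIDUES = frozenset("DE")

WINDOWS = ("first20", "first40", "full")
_WINDOW_LEN = {"first20": 20, "first40": 40, "full": None}


def _window_residues(seq: SequenceRecord, window: str) -> str:
    if window not in WINDOWS:
        raise ValueError(f"unknown window '{window}'; expected one of {WINDOWS}")
    n = _WINDOW_LEN[window]
    s = seq.residues
    if "-" in s:
        raise ValueError(f"sequence '{seq.id}' is aligned; features need unaligned input")
    out = s if n is None else s[:n]
    if not out:
        raise ValueError(f"empty window for sequence '{seq.id}'")
    return out


def count_charged(seq: SequenceRecord, window: str, polarity: str) -> int:
    """Number of charged residues of the given polarity in the window."""
    if polarity == "positive":
        charged = POSITIVE_RESIDUES
    elif polarity == "negative":
        charged = NEGATIVE_RESIDUES
    else:
        raise ValueError("polarity must be 'positive' or 'negative'")
    if window == "full":
        raise ValueError("charge counts are defined on first20/first40 windows")
    return sum(1 for ch in _window_residues(seq, window) if ch in charged)


def mean_hydrophobicity(seq: SequenceRecord, window: str) -> float:
    """Mean Kyte-Doolittle hydropathy over the window; 'X' residues skipped."""
    if window == "full":
        raise ValueError("hydrophobicity is defined on first20/first40 windows")
    vals = [KYTE_DOOLITTLE[ch] for ch in _window_residues(seq, window) if ch != "X"]
    if not vals:
        raise ValueError(f"window of '{seq.id}' contains only unknown residues")
    return sum(vals) / len(vals)


@dataclass(frozen=True)
class CompositionVector:
    """Frequencies of the 20 standard amino acids over a window."""

    frequencies: dict[str, float]
    window: str

    def __getitem__(self, aa: str) -> float:
        return self.frequencies[aa]


def aa_composition(seq: SequenceRecord, window: str) -> CompositionVector:
    """Amino-acid frequencies in the window, over counted (non-X) residues."""
    residues = [ch for ch in _window_residues(seq, window) if ch != "X"]
    if not residues:
        raise ValueError(f"window of '{seq.id}' contains only unknown residues")
    n = len(residues)
    freqs = {aa: 0.0 for aa in AA20}
    for ch in residues:
        freqs[ch] += 1.0
    return CompositionVector({aa: c / n for aa, c in freqs.items()}, window=window)


_WINDOW_SUFFIX = {"first20": "20", "first40": "40", "full": "f"}


def physchem_features(seq: SequenceRecord) -> dict[str, float]:
    """Charge and hydropathy features over the first-20 and first-40 windows."""
    out: dict[str, float] = {}
    for window in ("first20", "first40"):
        s = _WINDOW_SUFFIX[window]
        out[f"pos{s}"] = float(count_charged(seq, window, "positive"))
        out[f"neg{s}"] = float(count_charged(seq, window, "negative"))
        out[f"hphob{s}"] = mean_hydrophobicity(seq, window)
    return out


def composition_features(seq: SequenceRecord) -> dict[str, float]:
    """Composition over first20/first40/full, named ``comp20_A .. compf_Y``."""
    out: dict[str, float] = {}
    for window in WINDOWS:
        s = _WINDOW_SUFFIX[window]
        comp = aa_composition(seq, window)
        for aa in AA20:
            out[f"comp{s}_{aa}"] = comp[aa]
    return out
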