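"""Gap-aware column entropy and the divergence feature set.

The divergence score of an MSA column is its Shannon entropy in bits,

    H(i) = -sum_j F(i,j) * log2 F(i,j),

where F(i,j) is the frequency of character j in column i, with the twist
that every gap occurrence is treated as a *unique* character: a column
{L, L, I, -, -} over five sequences has frequencies L:0.4, I:0.2 and two
distinct gap tokens of 0.2 each, so heavily gapped columns score as highly
divergent. H(i) ranges over [0, log2 n] for n rows.

Per-protein features are means of the entropy profile over N-terminal
windows of the reference protein (first 20, first 40, residues 80-99),
z-scores of those means against all same-length windows of the protein,
and the N/C contrast NCdiff = N_raw_20 - N_raw_80_99.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GAP, Alignment

__all__ = [
    "CharFrequencyMap",
    "ColumnEntropyProfile",
    "DivergenceFeatureVector",
    "column_frequencies",
    "column_entropy",
    "entropy_profile",
    "smoothed_entropy",
    "local_divergence",
    "divergence_features",
    "DIVERGENCE_FEATURE_NAMES",
]

#: Serialized feature order (Table-style divergence vector).
DIVERGENCE_FEATURE_NAMES = (
    "Nraw20",
    "Nraw40",
    "Nraw80_99",
    "mu20",
    "sigma20",
    "mu40",
    "sigma40",
    "NCdiff",
    "N20",
    "N40",
    "N80_99",
)


@dataclass(frozen=True)
class CharFrequencyMap:
    """Per-character frequencies of one MSA column.

    Gap occurrences appear as distinct ``gap#k`` tokens of frequency 1/n;
    amino-acid characters are pooled by identity.
    """

    tokens: tuple[tuple[str, float], ...]

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(f for _, f in self.tokens)

    def frequency(self, char: str) -> float:
        """Frequency of a pooled (non-gap) character; 0.0 if absent."""
        for tok, f in self.tokens:
            if tok == char:
                return f
        return 0.0


def column_frequencies(
    alignment: Alignment, col: int, unique_gaps: bool = True
) -> CharFrequencyMap:
    """Character frequencies of 1-based column ``col``.

    With ``unique_gaps`` (the default, and the scoring rule of this package)
    each gap is its own token; ``unique_gaps=False`` pools gaps like an
    ordinary character ("straight" entropy, kept for comparison only).
    """
    chars = alignment.column(col)
    n = len(chars)
    counts: dict[str, int] = {}
    gap_tokens: list[tuple[str, float]] = []
    for ch in chars:
        if ch == GAP and unique_gaps:
            gap_tokens.append((f"gap#{len(gap_tokens) + 1}", 1.0 / n))
        else:
            counts[ch] = counts.get(ch, 0) + 1
    pooled = [(c, k / n) for c, k in sorted(counts.items())]
    return CharFrequencyMap(tokens=tuple(pooled + gap_tokens))


def column_entropy(alignment: Alignment, col: int, unique_gaps: bool = True) -> float:
    """Shannon entropy of a column in bits (0*log 0 := 0)."""
    freqs = np.array(column_frequencies(alignment, col, unique_gaps).frequencies)
    freqs = freqs[freqs > 0]
    return float(-np.sum(freqs * np.log2(freqs)))


@dataclass
class ColumnEntropyProfile:
    """Entropy per reference residue position.

    ``values[i-1]`` is the entropy of the MSA column holding the reference's
    i-th non-gap residue (1-based); columns where the reference is gapped are
    dropped, so features read off this profile live in reference-protein
    coordinates.
    """

    values: np.ndarray
    n_rows: int
    columns: list[int] = field(default_factory=list)  # 1-based MSA columns

    def __len__(self) -> int:
        return len(self.values)

    @property
    def length(self) -> int:
        return len(self.values)

    def value(self, i: int) -> float:
        """Entropy at 1-based reference position ``i``."""
        if not 1 <= i <= len(self.values):
            raise IndexError(f"position {i} out of range 1..{len(self.values)}")
        return float(self.values[i - 1])


def entropy_profile(alignment: Alignment, unique_gaps: bool = True) -> ColumnEntropyProfile:
    """Column entropies mapped to reference residue coordinates."""
    cols = alignment.reference_columns()
    vals = np.array([column_entropy(alignment, c, unique_gaps) for c in cols])
    return ColumnEntropyProfile(values=vals, n_rows=alignment.n_rows, columns=cols)


def smoothed_entropy(profile: ColumnEntropyProfile, i: int, j: int) -> float:
    """Mean entropy over the inclusive interval [i, j], clipped to [1, L]."""
    if i > j:
        raise ValueError(f"empty interval [{i}, {j}]")
    L = len(profile)
    lo, hi = max(i, 1), min(j, L)
    if lo > hi:
        raise ValueError(f"interval [{i}, {j}] lies outside positions 1..{L}")
    return float(np.mean(profile.values[lo - 1 : hi]))


def local_divergence(profile: ColumnEntropyProfile, k: int) -> float:
    """Local divergence LD(k): mean entropy over [k-10, k+10], end-clipped."""
    if not 1 <= k <= len(profile):
        raise IndexError(f"position {k} out of range 1..{len(profile)}")
    return smoothed_entropy(profile, k - 10, k + 10)


@dataclass
class DivergenceFeatureVector:
    """The per-protein divergence feature set.

    Window means are in bits; N20/N40/N80_99 are unitless z-scores.
    ``flagged_short`` marks proteins too short (< 80 residues) for the
    C-terminal-side normalization window; such proteins are excluded from
    training by default.
    """

    Nraw20: float
    Nraw40: float
    Nraw80_99: float
    mu20: float
    sigma20: float
    mu40: float
    sigma40: float
    NCdiff: float
    N20: float
    N40: float
    N80_99: float
    LD: dict[int, float] = field(default_factory=dict)
    flagged_short: bool = False

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in DIVERGENCE_FEATURE_NAMES}
        for k, v in self.LD.items():
            d[f"LD{k}"] = v
        return d


def _window_mean_stats(values: np.ndarray, w: int) -> tuple[float, float]:
    """Mean and population SD of the sliding-window means of length ``w``.

    Windows span the full profile; if the profile is shorter than ``w`` the
    single clipped window is used (SD 0).
    """
    L = len(values)
    if L < w:
        return float(np.mean(values)), 0.0
    csum = np.concatenate(([0.0], np.cumsum(values)))
    means = (csum[w:] - csum[:-w]) / w
    return float(np.mean(means)), float(np.std(means))


def divergence_features(
    profile: ColumnEntropyProfile, ld_positions: tuple[int, ...] = ()
) -> DivergenceFeatureVector:
    """Compute the full divergence feature vector from an entropy profile."""
    L = len(profile)
    nraw20 = smoothed_entropy(profile, 1, 20)
    nraw40 = smoothed_entropy(profile, 1, 40)
    flagged = L < 80
    if flagged:
        nraw80_99 = float("nan")
    else:
        nraw80_99 = smoothed_entropy(profile, 80, 99)
    mu20, sigma20 = _window_mean_stats(profile.values, 20)
    mu40, sigma40 = _window_mean_stats(profile.values, 40)
    ncdiff = nraw20 - nraw80_99

    def _z(x: float, mu: float, sigma: float) -> float:
        if sigma > 0:
            return (x - mu) / sigma
        warnings.warn("zero window-SD; z-score set to 0", stacklevel=3)
        return 0.0

    n20 = _z(nraw20, mu20, sigma20)
    n40 = _z(nraw40, mu40, sigma40)
    # the C-side window is normalized against the length-20 window statistics
    n80_99 = _z(nraw80_99, mu20, sigma20) if not flagged else float("nan")
    ld = {k: local_divergence(profile, k) for k in ld_positions}
    return DivergenceFeatureVector(
        Nraw20=nraw20,
        Nraw40=nraw40,
        Nraw80_99=nraw80_99,
        mu20=mu20,
        sigma20=sigma20,
        mu40=mu40,
        sigma40=sigma40,
        NCdiff=ncdiff,
        N20=n20,
        N40=n40,
        N80_99=n80_99,
        LD=ld,
        flagged_short=flagged,
    )
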