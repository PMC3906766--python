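import numpy as np
import pytest

from divsig.io import Alignment, SequenceRecord
from divsig.synthetic import simulate_dataset
from divsig.pipeline import build_examples

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def toy_alignment():
    """Five-row alignment whose first column is {L, L, I, -, -}."""
    rows = [
        SequenceRecord(id="r1", residues="LLIAA"),
        SequenceRecord(id="r2", residues="LLKAA"),
        SequenceRecord(id="r3", residues="ILIAA"),
        SequenceRecord(id="r4", residues="-LIAA"),
        SequenceRecord(id="r5", residues="-LIAA"),
    ]
    return Alignment(rows=rows, reference_id="r1")


def random_alignment(rng, n_rows=None, n_cols=None, gap_frac=0.2):
    """A random valid alignment with an ungapped first (reference) row."""
    n_rows = n_rows or int(rng.integers(2, 9))
    n_cols = n_cols or int(rng.integers(3, 30))
    letters = np.array(list(AA20))
    rows = []
    for r in range(n_rows):
        chars = letters[rng.integers(0, 20, size=n_cols)].copy()
        if r > 0:
            gaps = rng.random(n_cols) < gap_frac
            if gaps.all():
                gaps[0] = False
            chars[gaps] = "-"
        rows.append(SequenceRecord(id=f"r{r}", residues="".join(chars)))
    return Alignment(rows=rows, reference_id="r0")


@pytest.fixture(scope="session")
def balanced_synthetic():
    """Balanced 3-class synthetic dataset at default generator parameters."""
    families, labels = simulate_dataset({"MTS": 100, "SP": 100, "none": 100}, seed=20240)
    examples = build_examples((f.alignment for f in families), labels=labels)
    return families, labels, examples
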