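# Methods

## The divergence score and its conventions

The column score is the Shannon entropy of the column's character
frequencies, in bits, with each gap occurrence treated as a unique
character. The gap rule makes heavily gapped columns maximally divergent —
an all-gap column of *n* rows scores exactly log2 *n* — which reflects the
intuition that an insertion/deletion-riddled region is evolving freely.
The plain ("pooled-gap") entropy is available via
`column_frequencies(..., unique_gaps=False)` but is not used by default.
'X' (unknown residue) is treated as an ordinary 21st character by the
entropy and excluded from charge, hydropathy and composition counts.

**Coordinates.** Divergence features describe the *reference protein*, so
the entropy profile is indexed by reference residue positions: MSA columns
where the reference is gapped are dropped. This is a modelling choice —
the alternative (raw MSA-column indexing) would let upstream indels in
other species shift a protein's own N-terminal window.

**Windows.** `H̄(i,j)` is the arithmetic mean of the profile over the
inclusive interval, clipped at the sequence ends, so `LD(k) = H̄(k−10,
k+10)` exists at every position, including the termini. The window
statistics `μ_w`, `σ_w` are the mean and *population* standard deviation
of the sliding-window means over **all** length-*w* windows of the whole
profile (not just the N-terminal region); z-scores use these, and
`N80-99` is deliberately normalized with `μ_20`/`σ_20` (the length-20
window statistics). A protein whose profile is perfectly flat has
`σ_w = 0`; its z-scores are set to 0 with a warning rather than NaN.
Proteins shorter than 80 residues have no C-side normalization window;
they are flagged and excluded from feature tables by default. For lengths
in [80, 99) the `H̄(80,99)` window is clipped to the available tail.

## Classical features

Charged residues are R/K (positive) and D/E (negative) — the
physiological-pH convention; histidine is excluded as only fractionally
protonated. Hydropathy is the mean of the Kyte–Doolittle (1982) index
over the window (I = +4.5 … R = −4.5). Composition is the frequency of
the 20 standard residues over the first 20, first 40, or all residues,
excluding 'X' from both numerator and denominator. Feature names follow
the `pos20 / neg40 / hphob20 / comp20_A … compf_Y` convention.

## Ortholog sets

Orthologs are defined operationally as reciprocal best hits (RBHs) under
*global* alignment similarity: differences at the termini — exactly where
sorting signals live — should depress the score, and strong similarity in
one shared domain should not suffice. Scoring uses BLOSUM62 with affine
gap costs (open 10, extend 1; a gap of length L costs 10 + (L−1)) and end
gaps penalized. These parameters are this package's own defaults; any
matrix/penalty combination can be supplied via `AlignParams`. Best-hit
ties are resolved conservatively: a tie means no RBH pair, since "best"
is read as strict superiority. Ortholog sets are assembled
reference-vs-each-species independently (no transitive clustering), and
sets with fewer than four sequences are discarded because the entropy
score is unstable below that depth. The aligner is exact
Needleman–Wunsch-style dynamic programming (via Biopython's
`PairwiseAligner`), all-vs-all; it is quadratic in proteome size and
intended for curated panels, not heuristic genome-scale search.

## Feature importance

Continuous features are binned by the Fayyad–Irani MDL procedure before
computing information gain `I(C,F) = H(C) − H(C|F)` (base-2 throughout).
Candidate cuts are restricted to midpoints between adjacent *distinct*
values whose class memberships differ; this preserves the optimal cut and
guarantees equal feature values are never split apart. A cut on a block
of N examples with k classes is accepted only when its gain exceeds
`[log2(N−1) + log2(3^k − 2) − (k·Ent(S) − k1·Ent(S1) − k2·Ent(S2))] / N`,
and the procedure recurses on both halves. Gain is therefore invariant
under strictly monotone transforms of the feature. Ranking ties are
broken by feature name for determinism.

## Classifiers and evaluation

* **Majority** — predicts the modal training label (ties broken in the
  fixed order MTS < SP < CTP < none). Under this package's metric
  conventions its MCC is exactly 0 (zero-denominator convention) and its
  AUC exactly 0.5 (constant scores, ties counted ½).
* **Tree** — an entropy-split decision tree with cost-complexity pruning,
  a deliberately simple baseline; no attempt is made to match any
  specific C4.5 implementation bit for bit.
* **SVM** — one Gaussian-RBF machine per unordered class pair with
  cost C = 50 and γ = 1/#features, majority voting across machines,
  voting ties broken by the smallest exponential-decoding loss. Features
  are z-scored on training statistics before SVM training (default on:
  an RBF with γ = 1/d presumes comparable scales); the scaler is fit on
  the training fold only, never on held-out data.

Pairwise scores are signed so a positive value favors the
canonically-first class of the pair. Exponential loss-based decoding
gives class c the loss `Σ exp(−M[c,m]·s_m)` over its machines (coding
matrix M ∈ {−1, 0, +1}); pseudo-posteriors are the normalized reciprocal
losses. The **influence** of the divergence features on one example is
the total-variation distance between the posteriors decoded with and
without them, reported together with both decoded labels; this is a
pragmatic effect-size ordering, not a calibrated probability difference.

Evaluation is stratified 5-fold cross-validation repeated 5 times with
reshuffled folds (all seeded; results are bit-reproducible). Accuracy is
aggregated per fold, mean ± SD over folds × repeats; per-class AUC is
one-vs-rest on held-out examples using that class's decoded
pseudo-posterior as the score, and per-class MCC is one-vs-rest on the
hard predictions. The confusion matrix is averaged over repeats so its
entries sum to the dataset size. A label-shuffled control (labels
permuted once, seeded) and minimum-class-size balanced subsampling are
built in.

## The synthetic generator

`simulate_family` emulates the single property the method exploits:
signal regions evolve faster than the protein body, with class-dependent
composition. An ancestral sequence (length uniform on 150–500) is drawn
from class-conditional position-specific residue frequencies; each of the
other 10 species in the 11-species panel evolves independently down a
star phylogeny, mutating each site with probability 0.15, multiplied by
ρ = 4 inside the signal region (MTS/SP: positions 1–20; CTP: 1–50), by
redrawing from the position's frequency profile. Signal-region indels
appear as gaps in non-reference rows with per-cell probability 0.05, so
the reference stays ungapped (reference-coordinate mapping is exercised
by hand-made gapped fixtures instead). Composition biases: MTS regions
are R/K-rich and D/E-poor; SP regions have a weakly basic n-region
(1–5), a strongly hydrophobic h-region (6–15) and a small-residue
c-region (16–20); CTP regions are serine-rich; `none` proteins are
background throughout (Swiss-Prot-like average frequencies).

A star phylogeny suffices because the entropy score itself ignores
phylogenetic structure; position-wise redrawing replaces a rate-matrix
CTMC because the pipeline only consumes column heterogeneity. What the
generator does **not** emulate: real phylogenetic correlation between
species, alignment errors, cleavage-site motifs, paralogy, or the
divergence-scale differences between clades. Passing the end-to-end
tests therefore shows the pipeline recovers the divergence signal it was
built for, not that it attains any particular accuracy on real
proteomes. By design MTS and SP share the same rate anatomy, so
divergence-only 3-way accuracy on synthetic data is capped near 2/3
(signal vs none is learned; MTS vs SP is not) — separating those two is
exactly the role of the composition features.

## Problem sizes and numerics

Default test and evaluation sizes — 100 families per class for recovery
experiments, 500 examples for the shuffled control, 200 families for
profile statistics — were chosen as the smallest sizes at which the
Monte-Carlo error of the checked statistics is comfortably below the
asserted margins. Entropy computations treat 0·log 0 as 0; feature
tables serialize floats to 12 significant digits and round-trip to
1e-9; all randomness flows through explicit integer seeds (NumPy
`default_rng`), and cross-validation with a fixed seed is
bit-reproducible.

## Known limitations

* The RBH stage has no heuristic prefilter; it is not meant for full
  proteome-vs-proteome scans beyond a few thousand comparisons.
* Per-class AUC in multiclass settings depends on the decoded
  pseudo-posterior; other score choices would give slightly different
  AUCs (hard predictions, and hence MCC/accuracy, are unaffected).
* The tree baseline is intentionally generic; its numbers should be read
  as "a small interpretable model", not as a tuned competitor.
* MSAs are inputs: the package validates but never computes multiple
  alignments.
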