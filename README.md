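# divsig

Predicting N-terminal protein sorting signals from the *evolutionary
divergence* of ortholog alignments.

Cleavable N-terminal sorting signals — mitochondrial matrix targeting
signals (MTS), secretory signal peptides (SP) and chloroplast transit
peptides (CTP) — are only loosely constrained at the sequence level, and
they evolve markedly faster than the body of the protein. `divsig` turns
that divergence into a predictive feature: it scores each column of an
ortholog multiple sequence alignment (orthoMSA) with a gap-aware Shannon
entropy, summarizes the N-terminal entropy profile into per-protein
features, combines them with classical charge / hydropathy / composition
features, and trains and evaluates SVM, decision-tree and majority-class
classifiers for the four-way problem {MTS, SP, CTP, none}. It is aimed at
computational biologists studying protein subcellular localization who
have (or can build) per-protein ortholog alignments.

## The divergence score

For column *i* of an orthoMSA with *n* rows,

    H(i) = − Σ_{j∈A} F(i,j) · log2 F(i,j)        (bits)

where *F(i,j)* is the frequency of character *j* in the column, and —
crucially — **every gap occurrence is its own unique character**: the
column `{L, L, I, -, -}` is scored as one character at frequency 0.4 and
three characters at frequency 0.2, giving H = 1.921928 bits. Heavily
gapped columns therefore count as highly divergent. H(i) ranges over
[0, log2 n].

Per-protein features are means of the profile (in reference-protein
coordinates) over N-terminal windows — `H̄(1,20)`, `H̄(1,40)`,
`H̄(80,99)` — their z-scores against all same-length windows of the
protein, the contrast `NCdiff = H̄(1,20) − H̄(80,99)`, and the local
divergence `LD(k) = H̄(k−10, k+10)`.

The surrounding pipeline covers ortholog-set construction by reciprocal
best hits under global (end-to-end, affine-gap) alignment with a
≥4-sequence filter, Fayyad–Irani MDL discretization + information gain for
single-feature importance, one-vs-one RBF SVMs (C = 50, γ = 1/#features)
with exponential loss-based decoding, MCC / AUC / accuracy evaluation
under repeated stratified cross-validation, and a per-protein *influence*
score (total-variation distance between decoded posteriors with and
without the divergence features). A synthetic generator produces labeled
ortholog families whose signal regions evolve faster than the body, so the
whole pipeline is testable without any downloads.

## Worked example

```python
import divsig

families, labels = divsig.simulate_dataset({"MTS": 100, "SP": 100, "none": 100}, seed=42)
examples = divsig.build_examples((f.alignment for f in families), labels=labels)

model = divsig.SortingSignalModel.from_examples(examples, feature_set="div")
result = model.cross_validate(folds=5, repeats=5, seed=7)
print(result.summary())
```

prints

```
Stratified 5-fold CV x 5 repeats (n = 300, seed = 7)
Accuracy: 66.60% +/- 4.40

Per-class (one-vs-rest):
       auc  auc_sd   mcc  mcc_sd
MTS  0.717   0.057 0.236   0.107
SP   0.702   0.055 0.261   0.101
none 1.000   0.000 1.000   0.000

Confusion matrix (rows = true, columns = predicted):
      MTS   SP  none
MTS  46.8 53.2   0.0
SP   47.0 53.0   0.0
none  0.0  0.0 100.0
```

Divergence alone separates signal-bearing from signal-free proteins
essentially perfectly on this data (the `none` row), doubling the 33.3%
majority-class baseline overall — but it cannot tell MTS from SP, whose
divergence anatomy is the same; that is what the classical composition
features add (`feature_set="combo"` reaches ~93% here). Feature
importances confirm the picture:

```python
for fi in divsig.rank_features(examples)[:5]:
    print(f"{fi.feature:10s} {fi.gain:.3f} bits ({fi.discretization.n_bins} bins)")
```

```
N20        0.918 bits (2 bins)
N40        0.918 bits (2 bins)
NCdiff     0.918 bits (2 bins)
Nraw20     0.918 bits (2 bins)
Nraw40     0.918 bits (2 bins)
```

Each divergence feature alone carries ~0.92 of the 1.585 bits of class
entropy — exactly the signal-vs-none bit.

The same steps are available from the shell:

```sh
divsig simulate --classes MTS=100,SP=100,none=100 --seed 42 --out data/
divsig features --msa-dir data/msa --labels data/labels.tsv --out features.tsv
divsig infogain --features features.tsv --out importance.tsv
divsig evaluate --features features.tsv --feature-set div --seed 7 --out report.json
```

plus `divsig entropy` for per-position profiles, `divsig rbh` for
reciprocal-best-hit ortholog sets, and `divsig influence` for the
divergence-influence ranking.

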