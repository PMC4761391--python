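# memopred

Membrane proteins sit in or on the lipid bilayer, mediate transport and
signalling, and are the target of roughly half of all drugs — yet deciding
from sequence alone whether a protein is membrane-associated is still a
useful, non-trivial prediction task. `memopred` implements a classical
pattern-recognition pipeline for this binary decision, built for
bioinformaticians who want an inspectable, fully reproducible baseline
rather than a black box: every stage, from the moment transforms to the
backpropagation updates, is implemented in plain NumPy and validated against
independent oracles.

## Method

**Feature extraction.** A sequence of length *k* over the 20-letter amino
acid alphabet is encoded to integer codes (A=1, …, Y=20) and embedded
row-major into an *n* × *n* matrix with *n* = ⌈√*k*⌉, zero padded. Three
moment families characterise that matrix *f*(*i*, *j*):

- raw moments  M<sub>xy</sub> = Σ<sub>i</sub> Σ<sub>j</sub> i<sup>x</sup> j<sup>y</sup> f(i, j),
- central moments μ<sub>xy</sub> about the centroid (M₁₀/M₀₀, M₀₁/M₀₀),
  which are translation invariant,
- discrete orthogonal Hahn moments H<sub>ij</sub>, projections onto the
  orthonormalised Hahn polynomial basis h̃<sub>n</sub><sup>μ,ν</sup>(r, N)
  on r = 0 … N−1 (μ = ν = 0 by default, the discrete Chebyshev special
  case).

All three families are computed up to order 3 (x + y ≤ 3, ten values each)
for both the sequence matrix and the position-relative incidence matrix
(PRIM), a *k* × 20 matrix carrying *i* + 1 in column *j* when position *i*
holds the *j*-th amino acid. Together with the 20-element amino acid
frequency vector (FM) this yields an 80-dimensional descriptor per
sequence.

**Classification.** A four-layer perceptron (80–32–16–1 by default) with
logistic sigmoid activations is trained by online backpropagation — every
pattern one at a time — minimising E = ½ Σ<sub>p</sub> (t<sub>p</sub> −
o<sub>p</sub>)² with learning rate λ = 0.01. Membrane maps to target 1.

**Evaluation.** Jackknife (leave-one-out) and seeded stratified k-fold
cross-validation, confusion matrix, overall and per-class accuracy
(Accuracy = 100 · (TP + TN)/(TP + TN + FP + FN)), and ROC/AUC by threshold
sweep with the trapezoid rule. Scalers are re-fit inside every fold to
avoid leakage.

A seeded synthetic-sequence generator provides labelled data with a
compositional class signal (hydrophobic-enriched "membrane" profile vs a
near-uniform one), so the entire pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from memopred import ProteinSequence, extract_features, generate_dataset, kfold, accuracy
from memopred.classifier import make_mlp_trainer, TrainingConfig
from memopred.features import extract_feature_table

seq = ProteinSequence("demo", "MKTLLVLAVVAFASSALA" * 4)   # k = 72
fv = extract_features(seq)
fv.block("seq_raw")[:4]   # raw moments M00, M01, M02, M03 of the 9x9 embedding
# array([  692.,  2624., 14456., 89096.])
fv.block("fm").astype(int)  # residue counts, A..Y
# array([20, 0, 0, 0, 4, 0, 0, 0, 4, 16, 4, 0, 0, 0, 0, 8, 4, 12, 0, 0])
```

M₀₀ = 692 is the total mass of the encoded matrix; the FM block shows the
20 leucines and 16 alanines typical of a signal-peptide-like repeat. A
small cross-validated benchmark on 50 synthetic sequences per class:

```python
table = extract_feature_table(generate_dataset(50, seed=7))
X = table.drop(columns=["id", "label"]).to_numpy(float)
y = table["label"].to_numpy()
trainer = make_mlp_trainer((32, 16), TrainingConfig(lam=0.01, max_epochs=150))
scores, preds, cm = kfold(X, y, 5, trainer, seed=11)
cm, accuracy(cm)
# (ConfusionMatrix(TP=49, TN=42, FP=8, FN=1), 91.0)
```

91.0% of the 100 held-out predictions are correct: 49 of the 50 membrane
sequences are recovered (98% sensitivity) at the cost of 8 false positives.

The same workflow is available from the shell:

```sh
memopred simulate --n-per-class 200 --out synth.fasta --seed 7
memopred extract synth.fasta --out features.tsv
memopred train features.tsv --out model.json
memopred evaluate features.tsv --outdir report/      # confusion.tsv, roc.csv, plots
memopred predict model.json synth.fasta --out predictions.tsv
```

Sequence sets are curated before extraction (minimum length 50; records
whose headers carry ambiguous annotations such as "fragment", "probable" or
"by similarity" are dropped, with a TSV report). Redundancy reduction by
sequence identity is out of scope — pre-cluster with an external tool
(e.g. `cd-hit -c 0.8`) when benchmarking on database-derived sets.

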