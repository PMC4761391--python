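# Methods

## Sequence embedding and encoding

A validated sequence of length *k* is mapped residue-by-residue to integer
codes and laid out row-major in an *n* × *n* matrix, *n* = ⌈√*k*⌉, with the
trailing *n*² − *k* cells set to 0. The embedding is lossless (flattening
and stripping trailing zeros recovers the code list) and the padding never
exceeds one partial row plus one row: (*n* − 1)² < *k* ≤ *n*².

The residue → code bijection is not dictated by the method itself; any
fixed bijection carries the same information. We default to alphabetical
one-letter order (A=1 … Y=20), matching the column convention of the PRIM,
and expose it as a configurable `EncodingMap`.

Three policies handle non-canonical letters (X, B, Z, U, O, J), which are
common in database sequences: `strict` (error, listing positions),
`drop_nonstandard` (default; remove and shorten), and `map_x_to_zero`
(retain the letter, encode as 0 — i.e. indistinguishable from padding in
the matrix view and absent from PRIM/FM).

Curation mirrors standard benchmark construction: sequences shorter than
50 residues are excluded, as are records whose description contains any of
"fragment", "potential", "probable", "probably", "may be", "by similarity"
(case-insensitive substring match over the FASTA header, the only
annotation channel the tool sees). Identity-based redundancy reduction
requires a clustering tool and is deliberately out of scope.

## Moment families

Raw and central moments use zero-based indices i, j ∈ {0 … n−1}, one
convention shared with the Hahn support r ∈ {0 … N−1}. Central moments are
taken about the centroid (M₁₀/M₀₀, M₀₁/M₀₀) and are checked to be
translation invariant; the (1,0) and (0,1) entries vanish identically and
serve as built-in diagnostics. "Up to order 3" is read as x + y ≤ 3 (10
values per family); a `grid` scheme switching to x, y ∈ {0..3} (16 values)
is available and changes the feature-layout fingerprint.

### Hahn basis

The discrete Hahn polynomial is implemented as

    h_n^{μ,ν}(r, N) = (−1)^n (N+ν−1)_n (N−1)_n
                      · ₃F₂(−n, n+μ+ν+1, −r; ν+1, 1−N; 1)

with the terminating hypergeometric sum accumulated by term-ratio
recurrence (each factor is O(N), so no factorial overflow for the supports
used here) and Pochhammer prefactors in log-Gamma form. The orthogonality
weight is

    ρ(r) = Γ(ν+r+1) Γ(μ+N−r) / (Γ(r+1) Γ(N−r)),

computed in log space. At μ = ν = 0 the weight is uniform and the family
reduces to the discrete Chebyshev polynomials; the (−1)^n sign aligns the
basis with the recurrence-defined Chebyshev convention (positive leading
coefficient), which an independent three-term-recurrence implementation
cross-checks in the tests.

The square norm d_n² is computed directly as Σ_r h_n(r)² ρ(r) — it *is*
the norm, and the orthonormality identity Σ_r h̃_m(r) h̃_n(r) = δ_mn is
the ground truth the normalisation exists to achieve. Construction
verifies the Gram matrix against the identity at 1e-8 and fails loudly
otherwise; non-finite intermediates raise rather than propagate. Observed
deviations are ≈ 3e-15 up to N = 64, and the full-order transform/inverse
round trip errs below 2e-11 for N ≤ 12 (tolerance 1e-6).

μ and ν default to 0. They are exposed because the Hahn family is defined
for general non-negative parameters, but nothing in the pipeline requires
a non-uniform weight, and the parameter-free Chebyshev case is standard in
the discrete-moments literature.

2-D Hahn moments are H = (A β Aᵀ)ᵀ with A the normalized table and β the
embedded matrix, i.e. H_ij pairs h̃_i with the column coordinate and h̃_j
with the row coordinate; the inverse transform is exact at full order
because A is orthogonal.

## PRIM, FM, and the feature vector

The PRIM is a *k* × 20 positional-incidence matrix: row *i* carries the
value *i* + 1 in the column of the amino acid observed at position *i* and
0 elsewhere (entry sum *k*(*k* + 1)/2). The incidence value is a design
choice — the construction is pluggable so a substitution-score variant can
be swapped in — but the positional reading uses only information present
in the sequence itself and preserves order information, which is the
point of the representation. Raw and central moments run on the rectangle
directly; the Hahn transform needs a square support, so the PRIM is
flattened row-major and re-embedded as a square matrix first, reusing the
sequence-embedding mechanism. The FM (20 residue counts) enters the
feature vector as is: a 1 × 20 count vector has trivial 2-D structure, and
keeping raw counts preserves composition losslessly.

Layout (80 features under defaults): seq_raw, seq_central, seq_hahn,
prim_raw, prim_central, prim_hahn (10 each), then fm (20). The layout and
extraction settings are hashed into a fingerprint stored with scalers and
trained models; mismatched configurations are refused rather than
silently mis-scored. For degenerate inputs with *k* ≤ 9 the sequence
matrix is smaller than the order-3 basis needs; the basis order is clamped
to N − 1 and missing entries are reported as 0 so the layout stays fixed
(curated data never hits this: length ≥ 50 implies N ≥ 8).

Features are standardised (per-feature mean/sd from training folds only;
zero-variance features pass through, with near-zero variance detected
relative to the feature's magnitude to absorb float cancellation noise).
Raw moments grow like n^{x+y+1}, so unscaled features would saturate the
sigmoid immediately.

## Network and training

Four layers by default — 80 inputs, hidden 32 and 16, one sigmoid output —
with membrane as target 1. Hidden sizes are a deliberate middle ground:
small enough that a jackknife over a few hundred instances is a desk-scale
computation, large enough for the synthetic benchmark; both are
configurable. Weights (and per-neuron biases, treated as weights from a
constant-1 activation) initialise uniformly in [−0.5, 0.5], seeded.

Updates are online (per pattern), with seeded epoch shuffling on by
default. The objective is E = ½ Σ_p (t_p − o_p)²; the trace also logs the
conventional RMSE for readability, clearly labelled — the two differ by
normalisation only. Backpropagation uses

    δ_out    = −(t − o) · σ′(s_out)
    δ_hidden = σ′(s_hidden) · Σ_i δ_i w_{hidden,i}
    Δw_{from,to} = −λ o_from δ_to,       λ = 0.01

which is the exact gradient of E, validated against central finite
differences (vector-norm relative error ≈ 1e-9, tolerance 1e-5, 20 random
4-3-3-1 networks). A `literal_output_delta` option drops the σ′(s_out)
factor, reproducing the simplified textbook delta; it is not the gradient
of E and exists for comparison only. Non-finite gradients abort training
with a diagnostic rather than corrupting the model. Stopping: 1000 epochs
(default) or epoch error below 1e-3, whichever first. Momentum, adaptive
optimisers and regularisation are intentionally absent from the core
update; the hooks for them are the config dataclass and the trainer
closure.

## Evaluation protocol

Jackknife is a literal leave-one-out loop (verified against an independent
six-iteration loop with a deterministic nearest-centroid trainer); k-fold
uses a seeded stratified partition with fold sizes differing by at most
one, reducing to the jackknife at k = n. The scaler is re-fit inside every
fold on training instances only — evaluating with a globally fit scaler
leaks test statistics. Terminology note: we follow the convention that a
false positive is a Type I error and a false negative Type II. ROC sweeps
the unique sigmoid scores (before thresholding), AUC by trapezoid; ties at
the decision threshold go to the positive class. The implementation is
cross-checked against scikit-learn's `roc_auc_score` in the tests but not
backed by it.

## Synthetic study conditions

The generator emulates compositional divergence only: the membrane profile
puts weight 0.56 on the hydrophobic set {A, F, I, L, M, V, W} (0.08 each)
and 0.44 uniformly on the other 13 residues; the nonmembrane profile is
uniform (0.05 each). Total-variation distance ≈ 0.21. Lengths are uniform
on [50, 400]; residues i.i.d. within a sequence. The default study set is
200 sequences per class at seed 7.

What this does *not* model: transmembrane-helix topology, signal peptides,
positional motifs, length–class correlation, homology structure. Passing
the 85% end-to-end bar (observed ≈ 99% with 5-fold CV, MLP 80–32–16–1,
150 epochs) therefore demonstrates that the pipeline is wired correctly
and that the features detect compositional signal — it says nothing about
accuracy on real proteome data, where the class signal is weaker and
partly positional. The 85% figure is an engineering floor chosen for the
synthetic conditions, not a literature claim; published benchmark
accuracies on curated Swiss-Prot sets depend on external data and
unstated hyperparameters and are reproduced here only at the level of
their confusion-count arithmetic.

## Problem sizes and numerical choices

Orthonormality is validated for N up to 64 (the largest PRIM embedding a
400-residue sequence needs is N = 90, built and cached per distinct size;
construction re-validates every basis). Moment-oracle equivalence uses 200
random rectangles up to 16 × 16 against literal double loops. The XOR
capacity check uses λ = 0.5 and up to 20,000 epochs (λ = 0.01 is the
pipeline default; XOR is a 4-pattern saturation test where a larger step
is the standard choice). Basis construction tolerance 1e-8, round-trip
tolerance 1e-6, centroid requires M₀₀ > 0 (all-zero matrices raise).

## Known limitations

- The PRIM incidence semantics ("score of the position's residue") admit
  several readings; the positional one is implemented and flagged as
  pluggable.
- Raw-moment magnitudes make the feature vector ill-conditioned without
  standardisation; the scaler is therefore not optional in practice.
- Online training is O(patterns × epochs) per fold; a full jackknife on
  thousands of sequences is expensive by design (that cost is intrinsic
  to leave-one-out), and k-fold is the desk-scale alternative.
- Binary task only; multi-class membrane-type discrimination is out of
  scope.
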