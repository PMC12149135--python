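# Methods

## Problem

`nmfuse` predicts whether a candidate ribonucleoside in an RNA transcript
carries a 2′-O-methyl mark (Nm; subtypes Am, Cm, Gm, Um). The unit of
analysis is a fixed-length window centered on the candidate: the site is
extended 25 nt upstream and downstream, giving 51-nt windows. Classification
is binary (modified vs. unmodified), with balanced training sets.

## Feature views

Each window is encoded three ways:

1. **Sequence** `X_seq ∈ {0,1}^{L×4}` — one-hot base identity with the
   fixed column order (A, C, G, U). `N` encodes as an all-zero row and is
   allowed anywhere except the window center.
2. **Chemistry** `X_chem ∈ {0,1}^{L×3}` — three chemical-property bits per
   nucleotide: purine vs. pyrimidine ring count (`1` for A/G), amino vs.
   keto group (`1` for A/C), weak vs. strong pairing (`1` for A/U). Hence
   A→(1,1,1), C→(0,1,0), G→(1,0,0), U→(0,0,1). The code is invertible over
   {A,C,G,U}.
3. **Structure** `X_str ∈ {0,1}^{L×L}` — symmetric base-pair matrix with
   zero diagonal, obtained by stack-matching a dot-bracket string:
   `X_str[i,j] = X_str[j,i] = 1` iff bases i and j pair. Structures come
   from a per-window dot-bracket file, from an `RNAfold --noPS` hook, or
   from the built-in maximum-pairing folder (below). Each window is folded
   in isolation; folding such short sequences is inherently error-prone,
   which bounds how informative this view can be.

### Maximum-pairing fallback folder

`fold_nussinov` implements the classic maximum base-pairing dynamic
program (AU, GC and GU wobble pairs; minimum hairpin loop of 3 unpaired
bases). It exists so that the pipeline and its tests run without a
thermodynamic folder; it is *not* a free-energy model. The traceback is
made deterministic by always pairing position i with the smallest
admissible partner consistent with the optimal count. The DP table is
numba-compiled; an independent memoized recursion serves as its test
oracle.

## Model

Three branches feed a fully connected head:

* **CNN branches** (sequence and chemistry): 1-D convolution along the
  window (64 kernels, width 3, same padding, channels = view width), ReLU,
  max-pool (width 2, stride 2), flatten, linear map to a 64-dim embedding
  (`X_seq2`, `X_chem2`).
* **GAT branch** (structure): the window becomes a graph — one node per
  position with its one-hot base identity as the node feature; edges are
  the base pairs of `X_str` plus backbone edges (i, i±1) plus self-loops,
  so no node is isolated. Two stacked multi-head graph-attention layers
  (8 heads) refine the node features: per head k,
  `e_ij = LeakyReLU(a_kᵀ [W_k h_i ‖ W_k h_j])` on the neighborhood,
  `α_ij = softmax_j(e_ij)`, output `σ((1/K) Σ_k Σ_j α_ij^k W_k h_j)` with
  σ = ELU and LeakyReLU slope 0.2 (the original-GAT defaults). Head
  outputs are averaged, not concatenated. The per-node output is
  max-pooled along the window (width 2) to `X_str2 ∈ R^{25×64}`.
* **Cross-attention fusion**: `Q = X_seq2 W_q`, `K = X_str2 W_k`,
  `V = X_str2 W_v`, `A = softmax(QKᵀ/√D_k)`, `O = AV`. Queries come from
  the sequence view only (no reverse direction). `O` is reduced to a
  vector by averaging over the query axis, concatenated with `X_chem2`,
  and passed through FC(64) + ReLU + dropout(0.2) and FC(1) + sigmoid.
  Classification threshold 0.5.

Loss is mean binary cross-entropy with probabilities clamped at 1e-7.

### Ablation wiring

View switches (`use_seq/use_chem/use_str`) reproduce the seven ablation
rows (Seq, Che, Str, Seq+Che, Seq+Str, Che+Str, All). When either the
sequence or the structure view is off, cross-attention is skipped and the
remaining deep features are concatenated directly. When the structure
branch runs without a sequence branch there are no queries to attend
with, so the pooled GAT output enters the head *flattened*
(25 × 64 features) rather than node-averaged: the class signal in a
centered hairpin is positional (an unpaired loop at the center flanked by
stem pairs), and averaging over nodes would erase it. Disabling a view
makes the forward pass exactly invariant to that view's input; the GAT
node features travel with the structure view, not the sequence view.

### Implementation

No autodiff framework is used: the network runs on a small tape-based
reverse-mode engine (`_autodiff.py`, ~15 primitives) written for this
package, with a fused graph-attention layer whose hand-derived backward
exploits the symmetry of the edge set. Attention scores are computed only
on padded neighbor lists (maximum degree ≈ 4 for pair + backbone + self
edges) and scattered into a dense row-stochastic matrix for BLAS
aggregation. Every primitive and the end-to-end loss gradient are checked
against central finite differences (1e-4 relative); the GAT layer is
additionally checked against a loop-based evaluation of the attention
equations.

## Training and evaluation protocol

* Adam, learning rate 5e-4, batch size 64, at most 100 epochs, early
  stopping on a stratified 10% validation split with patience 10; the
  best-validation parameters are restored. All randomness (init, batch
  order, splits, fold shuffles, permutations) derives from one master
  seed, so runs are bit-reproducible single-threaded.
* Metrics: confusion counts at threshold 0.5 with the standard
  definitions (TN = negatives predicted negative), ACC, precision,
  recall, F1, MCC; trapezoidal AUC over the ROC (equal to the tie-averaged
  normalized Mann–Whitney U) and step-wise AUPR, both via scikit-learn.
* Cross-validation: stratified k-fold (k = 5 or 10) preserving the joint
  label × subtype balance, optionally repeated with reshuffled folds;
  reported as mean ± sd across folds and rounds. For datasets too small to
  stratify jointly, the validation split falls back to label-only strata.
* Cross-type matrix: the data are first split into disjoint train/test
  partitions; one model per training key (each subtype, plus all) is then
  scored on each test subtype, giving 5 × 4 AUC/AUPR grids.
* Permutation importance: per fold of a stratified k-fold, a trained
  model's validation AUC is compared with the AUC after permuting one
  window position's rows of one view across the validation samples
  (structure rows/columns are permuted jointly to keep matrices
  symmetric). Reported as standard − permuted, so positive = important;
  a `within` mode instead swaps each position with a random other
  position inside the same sample. This yields one 51-dim importance
  vector per view.

## Synthetic benchmark

The generator emulates the balanced study design: equal numbers of
positive and negative 51-nt windows, positives carrying the subtype base
at the center, subtype proportions defaulting to the published catalog
composition (Am 22.1%, Cm 26.1%, Gm 20.5%, Um 31.3%). Negatives are
i.i.d. uniform sequence whose center base also matches the subtype
("hard" negatives — the center nucleotide alone carries no signal; the
real negative-sampling scheme around positive regions is not documented,
so this explicit choice replaces it). Class signal is plantable per view:

* a degenerate motif (default `GGACU` at offset 23, written with
  probability `motif_strength`, default 0.9) — the center base inside the
  motif is always overwritten by the subtype base, so four of its five
  positions are informative;
* a structural signal: with probability `struct_signal` a positive window
  receives complementary 8-nt flanks 6 nt either side of the center, so
  the maximum-pairing fold forms a hairpin enclosing the candidate site.

All windows (both classes) are folded with `fold_nussinov`; fixtures are
written as FASTA + TSV site table + dot-bracket text and round-trip the
readers losslessly.

What passing on this benchmark does **not** show: performance on real
Nm-seq data, where the motif structure is unknown, classes are determined
experimentally, and thermodynamic folds differ from maximum-pairing
folds. The benchmark verifies that each branch can consume its intended
signal and that the protocol (CV, ablation, importance) behaves
correctly — not biological accuracy.

## Problem sizes used by the tests and the acceptance script

Cross-validated signal recovery runs at the benchmark's study conditions
(motif strength 0.9, 1000 windows per class, 5-fold CV) with training
capped at 25 epochs — on this benchmark validation loss plateaus well
before the cap, so the cap only removes post-convergence epochs. The null
benchmark uses 500 windows per class; permutation importance uses 300 per
class with 3 folds and a 15-epoch cap; the view-matched ablation contrast
uses 400 per class with a held-out test set of 400 and a 40-epoch cap
(the structure-only model needs ~10 warm-up epochs before its validation
loss starts to fall, so this cap is deliberately more generous). Unit
tests use a reduced architecture (8 kernels, 8-dim embeddings, 2 heads)
where only contracts, not learning, are being checked.

## Numerical choices and edge cases

* Probabilities clamped to [1e-7, 1 − 1e-7] before the log-loss.
* MCC, precision, recall and F1 return 0 when their denominator is 0;
  AUC/AUPR are undefined (NaN) for single-class label sets.
* Masked softmax raises on an empty neighborhood; self-loops make this
  unreachable from the public API.
* Maximum pooling drops a trailing odd position (51 → 25).
* Parameters are Glorot-uniform initialized, float32 for training;
  gradient-check tests run in float64.
* Ties in predicted probabilities are handled by scikit-learn's ROC
  construction (threshold grouping), equivalent to averaging over
  threshold placements.

## Known limitations

* The structure view folds each 51-nt window in isolation with a
  maximum-pairing model unless RNAfold structures are supplied.
* The GAT sees no positional encodings; positional structure reaches the
  classifier only through the flattened/pooled head features.
* Single-CPU numpy training: fine at benchmark scale (minutes), not
  intended for genome-scale scans.
* The cross-attention direction (sequence queries over structure
  keys/values), the query-axis mean reduction of `O`, the 2-layer GAT
  depth, and the 64-unit head width are fixed design choices where the
  architecture was genuinely open; they are recorded here and exposed in
  `ModelConfig` where configurable.
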