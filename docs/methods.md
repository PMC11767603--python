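# Methods

## Problem and model

The package predicts binary drug–target interaction (DTI) from raw character
sequences: a SMILES string for the small molecule and a one-letter amino-acid
sequence for the protein. The positive class is defined pharmacologically:
dissociation constant Kd strictly below 30 nM. The model combines three
ideas:

1. **Multi-scale convolution** for local patterns. Chemical substructures in
   SMILES and short sequence motifs in proteins appear at different spans, so
   each conv stack uses three kernel widths ((4, 6, 8) for drugs, (4, 8, 12)
   for targets) with channels (32, 64, 96). ReLU sits *between* the three
   layers only; the last layer is linear so downstream modules see signed
   features.
2. **A transformer path** for global protein context, fed with byte-pair
   encoded subwords so that attention operates over a shorter sequence of
   recurring fragments rather than individual residues.
3. **Competitive fusion.** Local (L) and global (G) channels are not simply
   concatenated: a squeeze over time followed by a bottleneck and two
   expansion maps produces, per channel, a two-way softmax
   (s_L[c] + s_G[c] = 1) that decides how much of each path survives — a
   selective-kernel-style competition. A squeeze-and-excitation block then
   re-calibrates the selected channels, and a shared cross-attention +
   position-wise interaction block (BFIM) crosses drug and target streams
   before the prediction head.

## Preprocessing

* SMILES are tokenized per character (multi-character atom symbols such as
  "Cl" deliberately become two tokens; the tokenizer is alphabet-agnostic).
* Protein characters outside the 20 standard amino-acid letters, and any
  character missing from a vocabulary, map to `'?'`, which is also the pad
  token; a binary mask, not a distinct pad index, marks real positions, and
  masked positions never act as attention keys.
* Vocabularies are built from the training split only, `'?'` at index 0 and
  remaining tokens in sorted order, so they are deterministic. The BPE model
  is likewise trained on the training-fold proteins (1000 merges by default;
  ties on pair frequency break lexicographically). In cross-validation both
  are refit per fold, so held-out sequences cannot influence tokenization.
* Default maximum lengths: 100 SMILES characters, 1000 protein characters,
  545 BPE tokens — configurable; truncation keeps the prefix.

## Decisions where the design was open

* **Conv padding** is 'same' with stride 1, keeping the time axis intact for
  later alignment.
* **Two drug branches** use the same kernel triple with independent weights
  by default; `share_drug_branch_weights` ties them (the "parallel
  shared-weight" reading). Untied is the default because it is the weaker
  assumption.
* **Alignment before fusion:** L and G are linearly projected to a common
  channel width C_f (96 by default) and adaptively mean-pooled to T_f = 64
  time bins. Adaptive pooling (contiguous bins of size ⌈T/T_f⌉ or ⌊T/T_f⌋)
  makes every sequence length compatible with a fixed fusion shape.
* **BFIM internals** are not specified beyond the name; the implementation is
  the simplest biased interaction consistent with it — a position-wise affine
  map with bias over `[A_d ; A_t ; A_d ⊙ A_t]` followed by ReLU. A bilinear
  variant (`bfim_bilinear`) first mixes the drug stream through a learned
  square map. The element-wise product term is what lets the network express
  the conjunctive ("both motifs present") structure of real binding events.
* **SFM placement.** The selective fusion has two defensible placements:
  on (L, G) before interaction, or on the two channel halves of F_cross
  (drug-conditioned vs target-conditioned streams) after interaction. The
  default applies it once to F_cross; `sfm_on_target_LG` switches to the
  former. The softmax in the fusion is across the two branches per channel
  (a competition), and the multiplication with X is element-wise gating.
* **Head and loss:** global max pooling over time, FCN widths (512, 128),
  dropout 0.1, sigmoid output, binary cross-entropy, Adam at the configured
  learning rate. Max pooling (not mean) is used because motif presence is a
  peak phenomenon.
* **Metrics:** AUC is the Mann–Whitney pair statistic (ties 0.5); AUPR is
  tie-grouped average precision; threshold metrics use 0.5, with precision
  flagged when nothing is predicted positive. Headline numbers are fold
  means by default (`pooled_metrics` switches to pooled out-of-fold scores).

## Numerical core

The network runs on a compact reverse-mode autodiff engine over numpy
(float32 working precision; float64 preserved for gradient checking).
Convolution is im2col + one large GEMM; attention masking adds −10⁹ to masked
logits before a numerically stabilized softmax; BCE clips probabilities to
[1e−7, 1 − 1e−7] in the forward value while routing gradients through the
unclipped output. Gradient correctness is verified against central finite
differences in the test suite. All randomness — initialization, shuffling,
dropout, sampling — flows from a single integer seed through named
sub-streams, and two runs with the same configuration and seed agree
bitwise on one host.

## Synthetic benchmark

The generator emulates the Davis-style distribution: keyed SMILES and protein
collections and a dense Kd matrix. Interaction follows a planted conjunctive
rule — a pair is positive iff the drug contains a fixed drug motif AND the
target contains a fixed target motif — with each motif planted with
probability 0.5, so positive prevalence is ≈ 0.25. The rule is conjunctive on
purpose: detecting each motif exercises the convolutional paths, while the
AND across the two sequences can only be resolved by the interaction stage.
Kd values are drawn log-uniformly inside class ranges ((1, 29) nM positive,
(100, 10000) nM negative) that straddle the 30 nM decision boundary, so
generated bundles round-trip through the loader and binarizer exactly.
Observed labels can be flipped with probability `label_noise`.

What the fixture does **not** emulate: chemical validity of SMILES, realistic
amino-acid composition, affinity measurement noise near the threshold,
correlated targets (kinase families), or class imbalance of real screens.
Passing the synthetic end-to-end test therefore certifies that the
architecture, optimization and data plumbing can represent and learn a
local+cross-sequence interaction rule — not that real-benchmark accuracy is
reproduced; the latter requires the real data and the full protocol
(`scripts/run_davis.py`).

A character n-gram logistic baseline is part of the test suite and must reach
AUC > 0.9 on noiseless fixtures before the deep model is blamed for any
failure: it certifies the planted signal exists.

## Problem sizes used in the shipped experiments

The shipped end-to-end experiments use a small preset (`ModelConfig.small()`:
embedding 32, conv channels (16, 32, 48), d_model 32, one transformer layer,
4 heads, FFN 64, C_f 32, T_f 32, head (128, 32); SMILES ≤ 48, protein ≤ 120
characters, ≤ 60 BPE tokens from 100 merges) on 2,000 synthetic pairs for 30
epochs, which a single CPU core completes in minutes while leaving the
learning problem non-trivial. The null-calibration experiment permutes labels
on 500 pairs; determinism checks use 80 pairs. The full-size defaults are
exercised structurally (shape and invariant tests) rather than trained in the
shipped tests.

## Known limitations

* No chemically aware tokenization or graph encoding of molecules; SMILES
  are treated as plain character strings.
* The numpy engine is single-node, CPU-only; the full 500-epoch benchmark
  protocol is impractical without porting the model to a GPU framework.
* Negative sampling treats unmeasured/weak pairs as true negatives; false
  negatives in real screens are not modeled.
* Attention maps are recorded for testing but no interpretability tooling is
  provided.
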