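# mcfdti

Sequence-based drug–target interaction (DTI) prediction: given a drug as a
SMILES string and a protein target as an amino-acid sequence, predict the
probability that the pair interacts (operationally, that the dissociation
constant Kd is below 30 nM). The package is aimed at computational chemists
and method developers who want a fully reproducible, CPU-friendly
implementation of a multi-scale convolution + transformer fusion classifier,
together with the standard kinase-benchmark construction protocol and a
synthetic benchmark generator for controlled experiments.

## The model

Both inputs are treated as character sequences.

**Drug encoder.** SMILES characters are embedded and passed through two
parallel multi-scale convolution branches, each
`Conv3(ReLU(Conv2(ReLU(Conv1(X)))))` with output channels (32, 64, 96) and
kernel widths (4, 6, 8); branch outputs are concatenated channel-wise into
`F_drug`.

**Target encoder.** Two parallel paths over the same protein: a convolution
path on amino-acid characters (kernels (4, 8, 12)) capturing local motifs
(`L`), and a transformer path on byte-pair-encoded subwords — embedding,
sinusoidal positional encoding, and stacked self-attention blocks using
`Attention(Q,K,V) = softmax(QKᵀ/√d_k)V` with padded positions masked —
capturing global context (`G`). Both are projected to a common width and
pooled to a common length, then concatenated into `F_target`.

**Fusion.** A shared cross-attention block (one set of Q/K/V projections used
in both directions) exchanges information between the drug and target maps.
The biased feature interaction module (BFIM) crosses them position-wise:
`F_cross = ReLU(W·[A_d ; A_t ; A_d ⊙ A_t] + b)`. The selective fusion module
(SFM) then lets the two halves compete per channel: with `X = [L̃ ; G̃]`,
`I = mean_T(X)`, `X̂ = ReLU(W_f I)`, `X₁ = W_u1 X̂`, `X₂ = W_u2 X̂`, a two-way
softmax over `(X₁[c], X₂[c])` yields gates `s_L[c] + s_G[c] = 1` that weight
the corresponding channels, and a squeeze-and-excitation block re-calibrates
the result. A fully connected head over max-pooled drug and selected features
emits `y = σ(FCN([F_drug ; F_select]))`, trained with binary cross-entropy
and Adam (learning rate 0.001, batch 64) under stratified 5-fold
cross-validation, reporting AUC, AUPR, precision, recall and accuracy.

Ablation variants (conv-only target, transformer-only target, one or two drug
branches, fusion off) are available through `ModelConfig.variant`.

The network runs on a small reverse-mode autodiff engine over numpy that is
part of the package (`mcfdti.autograd`), so there is no deep-learning
framework dependency.

## Worked example

Generate a synthetic benchmark with a planted interaction rule (a pair
interacts iff the drug contains one specific substring motif and the target
another), train, and evaluate:

```bash
mcfdti make-synthetic --n-drugs 10 --n-targets 10 --seed 3 --out-dir fixture
mcfdti evaluate --pairs fixture/pairs.tsv --set epochs=2 --set folds=2 \
    --set embed_dim=8 --set d_model=8 --set num_heads=2 --set num_layers=1 \
    --set ffn_dim=16 --set fusion_channels=8 --set fusion_time_bins=8 \
    --set smiles_max_len=24 --set protein_max_len=40 --set bpe_max_tokens=24 \
    --set bpe_num_merges=20 --set drug_conv_channels=4,6,8 \
    --set target_conv_channels=4,6,8 --set head_widths=16,8 \
    --seed 1 --out-dir run
```

The first command prints the bundle summary:

```
{"n_drugs": 10, "n_targets": 10, "n_records": 100, "n_positive": 30, "n_negative": 70}
```

meaning the dense 10 × 10 affinity grid produced 100 labeled pairs of which
30 satisfy the planted rule (Kd drawn below 30 nM). The second command prints
a per-fold metric table:

```
fold        auc       aupr  precision     recall   accuracy
   0     0.4952     0.3212     0.0000     0.0000     0.7000
   1     0.6971     0.4581     0.3000     1.0000     0.3000
mean     0.5962     0.3896     0.1500     0.5000     0.5000
```

— after two epochs on 50 training pairs this deliberately tiny configuration
is barely above chance; it demonstrates the plumbing, not the model. The
full-size experiment in the reproduction section (2,000 pairs, 30 epochs)
drives held-out AUC above 0.95. `run/eval_report.json` holds the same numbers
machine-readably, and `run/config.json` records the fully resolved
configuration and its hash so the run can be replayed exactly.

A Python-level version of the same workflow:

```python
from mcfdti import (SyntheticSpec, generate_pairs, ModelConfig, TrainConfig,
                    crossval_evaluate)
records, rule = generate_pairs(SyntheticSpec(seed=0), 2000)
report = crossval_evaluate(records, ModelConfig.small(),
                           TrainConfig(epochs=30, folds=5, seed=0))
print(report.table())
```

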