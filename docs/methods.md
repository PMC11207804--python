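# Methods

## Model

`admetgnn` predicts a scalar molecular property from a SMILES string with a
graph neural network that reads the molecule bottom-up: substructures
first, then the whole molecule, then a molecule-level prediction head.

**Graph representation.** Molecules are parsed with RDKit (default
aromaticity perception; the perception model is part of run metadata).
Hydrogens stay implicit: nodes are heavy atoms only. Each atom is encoded
as six concatenated one-hot blocks — atomic number (1–101), formal charge
(−3…+3 with an "extreme" bucket for |q| > 3), hybridization (S, SP, SP2,
SP3, SP3D, SP3D2, other), ring membership, aromaticity, and chirality tag
(unspecified, clockwise, counter-clockwise, other) — for a feature width of
124. Atomic numbers above 101 are a hard error rather than a silent bucket:
the element list has no catch-all, and bucketing transuranic elements would
corrupt the one-hot semantics. Connectivity is captured by five binary
N×N matrices per molecule: `A_full` (all bonds, self-loops on every real
atom) and one matrix per bond class — single, double, triple, aromatic.

**Substructure self-loops.** In a bond-class matrix, atom *i* carries a
self-loop only when it is incident to at least one bond of that class. This
is load-bearing: the masked-sum fusion multiplies branch features by the
diagonal entries, so an unconditional diagonal would make the mask vacuous
and every atom would receive every branch's features. With the
participation rule, an sp³ carbon in an otherwise aromatic molecule
contributes only through the single-bond branch.

**Attention layers.** A head projects node features (Z = HW), scores each
adjacency edge with a LeakyReLU(slope 0.2) of the concatenated pair dotted
with a learned 2F-vector, softmax-normalizes scores over each atom's
neighborhood, aggregates, and applies another LeakyReLU. Non-edges are
excluded from the softmax by masking to −∞ (implemented as a large negative
fill followed by an explicit zero mask, so excluded weights are exactly
zero). Atoms with empty neighborhoods — padding, or atoms outside a
substructure — produce exactly-zero rows. K heads run independently and are
combined by concatenation (width K·F) or averaging (width F). The K heads
are evaluated as stacked (B, K, N, ·) tensor operations; this is
arithmetically identical to evaluating them separately and is verified
against the per-head path in the tests.

**Architecture.** The complete variant: per bond class, MHAL(concat) →
MHAL(average) over that class's adjacency; masked sum over the four
branches; MHAL(concat) over `A_full`; gated attention pooling
(X = Σ_j σ(h_j W₁+b₁) ⊙ (h_j W₂+b₂), summed over real atoms only); batch
normalization; MLP; one output unit with a sigmoid for classification and
identity for regression. The whole-molecule ablation feeds the raw features
straight into the whole-molecule stage; the convolutional ablation replaces
that stage's attention with a symmetric-normalized graph convolution
(D̃^{-1/2} A D̃^{-1/2} H W) of equal output width, which has strictly fewer
parameters (D·KF vs K·(D·F + 2F)).

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| heads K | 4 | matches the whole-molecule attention stage's head count; keeps head width × count equal across stages |
| head width F | 32 | pooled width Q = K·F = 128 balances capacity against single-CPU training cost |
| pooled width P | 64 | halving step between pooling and MLP |
| MLP hidden | (64, 32) | two LeakyReLU layers; smallest stack that trains the synthetic tasks to well above baseline |
| LeakyReLU slope | 0.2 | used for every nonlinearity g and φ in the graph layers |
| optimizer | Adam, lr 1e-3, batch 32 | standard for networks of this size; all overridable in `TrainConfig` |
| epochs | 100 (protocol runs here use 30) | checkpoint selection makes extra epochs harmless, only slower |
| α (density weighting) | 0.55 | the densest target keeps weight 0.45, the rarest weight 1 |
| probability clipping ε | 1e-7 | two-sided, before logarithms |

Weight initialization is fan-average (Glorot) uniform, seeded from
`ModelConfig.seed`; per-fold models and validation draws are re-seeded as
`seed + fold_id`, so a run is reproducible end to end from two integers.

## Losses

Density-weighted RMSE: p(y) is a Gaussian KDE of the *training* targets
with Silverman's rule-of-thumb bandwidth, min–max normalized to p′ ∈ [0,1];
w_i = 1 − α·p′(y_i). Weights are computed once per fold before training —
they depend only on targets — and never see validation or test labels.
Constant target vectors degrade gracefully to unit weights. The weighted
RMSE is √(Σ w_i (y_i−ŷ_i)²/N), so α = 0 recovers plain RMSE exactly.

Class-weighted BCE: w_c = ln(N_majority/N_c + 1), natural log, so the
majority class always weighs ln 2 and minority classes more. The class
weight multiplies the entire per-sample cross-entropy term. A per-sample
diagnostics table (id, y, p′, w) is exposed for audit.

## Evaluation protocol

Five test folds partition the data (stratified for classification); within
each fold, 20% of the remainder is a validation set (stratified for
classification, plain random for regression) and the rest trains the model.
After every epoch the model is scored on validation — RMSE minimized for
regression, AUPRC maximized for classification — and the best epoch's
weights (and batch-norm statistics) are restored at the end; there is no
patience-based early stopping. Test metrics are aggregated as median and
standard deviation over the five folds. AUPRC is computed as average
precision (step-wise sum, no linear interpolation): under this estimator a
constant-score classifier scores exactly the positive prevalence, which is
the baseline all classification results are read against. Point precision
and recall are reported at threshold 0.5. The padding size n_max is the
dataset-wide maximum heavy-atom count — computed over all splits and
recorded in the run config, the one deliberate (and documented) use of
test-set information, which leaks only a matrix dimension.

## Numerical engine

The layers run on a reverse-mode autodiff engine over NumPy written for
this package (`admetgnn.autodiff`): a Tensor wrapper, broadcasting-aware
gradients, and the primitive set the layers need (stacked matmul,
LeakyReLU, sigmoid, exp/log/sqrt, reductions, reshape/transpose/concat,
masked softmax, straight-through clipping). Every primitive and the
composite layers are validated against central finite differences; batch
normalization backpropagates through the batch statistics. The engine is
eager and single-threaded; large matrix products go through BLAS.

## Synthetic data generator

The generator emulates the structure of public ADMET benchmarks without any
download: molecules are assembled from a fragment grammar (alkane chains,
one alkene, one alkyne, benzene rings, ether/amine heteroatoms), so all
four bond classes occur in every corpus and molecules stay under ~21 heavy
atoms. The regression label is 0.5·(aromatic atoms) + 1.0·(double bonds) +
1.5·(triple bonds) − 0.1·(heavy atoms) + N(0, 0.25²), which yields a skewed
marginal like the public LogD/LogS sets; the classification label is 1 iff
the molecule has a triple bond or ≥ 2 aromatic rings, generated at a
default prevalence of 0.20 (the most imbalanced CYP set's level) with 5% of
labels flipped. Labels are exact functions of structure (plus declared
noise), so every pipeline stage can be tested against ground truth.

What the generator does *not* emulate: realistic pharmacophore diversity,
large macrocycles or fused ring systems, charge states, stereochemistry
beyond the parser's tags, and any genuine structure–activity relationship.
Passing the learning-sanity criterion therefore shows the pipeline can
extract an easily learnable structural signal under class imbalance — not
that it reaches benchmark-level accuracy on real assays, which requires the
public datasets and longer training.

## Problem sizes used in the shipped checks

The end-to-end check trains the default classifier on a synthetic corpus of
n = 2000 molecules (prevalence 0.20) for 30 epochs per fold under the full
five-fold protocol — sizes chosen so the whole suite completes on one CPU
in minutes while still leaving the no-skill baseline far behind. Layer
oracles use 20 random graphs of up to 6 nodes at tolerance 1e-6; invariance
checks compare predictions across atom reindexings and padding inflation at
1e-5 (float32 forward passes).

## Known limitations

- No edge features, multi-task heads, pretraining, or uncertainty
  estimates.
- Benchmark loading needs the optional PyTDC client and network access;
  offline use goes through CSV exports.
- Training is CPU-bound NumPy; it is sized for datasets of thousands, not
  millions, of molecules.
- Published benchmark statistics can drift as the hosting platform revises
  datasets; the loaders report statistics for comparison rather than
  enforcing them.
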