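# Methods

## Problem setting

Binary classification of short peptides (2–50 residues, 20-letter standard
alphabet) into antioxidant (AOP, label 1) and non-antioxidant (label 0).
Public AOP corpora pair experimentally validated positives with randomly
generated decoy sequences; that construction makes composition a strong
signal and motivates the synthetic benchmark used throughout the tests
(see below). The model combines two views: the residue sequence and the
molecule's 2D covalent structure.

## Sequence encoder

Tokenization maps residues alphabetically (A=0 … Y=19); the padding symbol
takes index 20 and owns a 21st embedding row. The printed token alphabet
{0,…,19} says nothing about the padding representation, so the extra row
is a design choice — padding positions are excluded from pooling, so the
choice cannot leak into the embedding (verified by the padding-invariance
tests). Sequences are right-padded to n = 50; the encoder only unrolls to
the longest true length in a batch, which is mathematically identical
because the recurrences are causal and pooling is masked.

The stack is mLSTM → sLSTM → mLSTM, each block pre-normalized (LayerNorm)
with a residual connection, model width 128, average-pooled over unmasked
positions (over time, not features: pooling over features would destroy
the per-dimension semantics the fusion head consumes).

### sLSTM

Exponential input/forget gates with the log-domain stabilizer
`m_t = max(f̃_t + m_{t−1}, ĩ_t)`; the applied gates are
`exp(f̃_t + m_{t−1} − m_t)` and `exp(ĩ_t − m_t)`, both ≤ 1 by
construction. The cell tracks a normalizer `n_t` alongside the memory
`c_t`; since `|c_t| ≤ n_t` (the memory is a positively weighted sum of
tanh candidates), the output `h_t = o_t ⊙ c_t / max(n_t, 1e−6)` is
bounded. The 1e−6 floor only guards exact zeros.

Two invariances characterize stabilizer correctness and are asserted in
the tests: (i) a single update from a fixed state is exactly invariant to
adding a common constant to both exponential-gate pre-activations, and
(ii) the whole multi-step output sequence is invariant to an arbitrary
offset of the initial stabilizer state. Note that adding a common constant
to both gates *at every step of a multi-step run* is **not** an invariance
of exponential gating (the constant compounds through the forget product
and re-weights older versus newer injections); only the per-step and
stabilizer-offset forms hold.

### mLSTM

Matrix memory per head, covariance update `C_t = f_t C_{t−1} + i_t v_t k_tᵀ`
(input gate exponential, forget gate sigmoid passed through log into the
same stabilizer), keys scaled by 1/√d_h, readout
`h_t = C_t q_t / max(|n_tᵀ q_t|, 1)`. The divisor floor is 1, not a tiny
epsilon: with a tiny floor the readout is unbounded whenever the
normalizer–query dot-product is small, and desk-scale training showed
exactly that failure mode (loss spikes an order of magnitude above the
plateau). Flooring at 1 bounds the readout by a Cauchy–Schwarz-style
argument and removed the instability.

Because the mLSTM's gates depend only on the current input, the stabilized
recurrence has a closed parallel form (an attention-like weighting
`D_{ts} = exp(log i_s + Σ_{r=s+1..t} log f_r − m_t)` applied to query–key
scores). The encoder uses this form for speed; the recurrent step function
remains the reference implementation and a test asserts the two paths
agree to 1e−10.

### Widths and the parameter budget

The binding constraints are the published per-component budgets: the
sequence encoder prints as 0.70 M parameters and the MPNN as 75 k. The
internal widths are otherwise free and are pinned as: mLSTM inner width
128 (projection factor 1, 4 heads of dimension 32), sLSTM hidden width
291. This yields 696,896 sequence-encoder parameters (prints 0.70 M) and,
with the 74,962-parameter MPNN and the 26,881-parameter fusion head, a
fused total of 798,739. The printed total of 0.75 M for the full model is
arithmetically inconsistent with its own per-component budgets
(0.70 M + 75 k alone exceed it); this package treats the per-component
counts as binding and guarantees total < 0.8 M.

## Molecular graphs

Each residue is emitted from one of 20 hand-written SMILES fragments of
the form `N…C(=O)`, so string concatenation N→C forms the peptide bonds
and a trailing `O` closes the C-terminal acid. No stereochemistry is
written — the featurization is purely 2D-topological and the graph
encoder has no chirality features. Disulfide bridges and post-translational
modifications are out of scope; peptides are strictly linear chains. The
construction is validated residue-by-residue against RDKit's own
peptide-from-sequence builder in the tests.

Node features (13 dims): element one-hot {C, N, O, S, other}, degree
one-hot 1–4 (4 is the maximum heavy-atom degree in standard residues),
formal charge, aromaticity, implicit-hydrogen count, ring membership.
Edge features (5 dims): bond-order one-hot {single, double, aromatic},
conjugation, ring membership. The published description names node and
edge features without enumerating them, so this layout is a
reconstruction; it is versioned (`aopfusion-feat-1`) and stamped into
graph caches and checkpoints, and a version mismatch is a hard error.

## Graph encoder

Messages concatenate the neighbor state with the edge feature and sum over
neighbors; updates apply one learned bias-free matrix per step and vertex
degree (degree clamped at 4), followed by the logistic function — the
update is exactly `σ(H m)`, nothing more. The readout projects each final
node state to 128 dimensions and averages over nodes, which keeps the
embedding invariant to vertex relabeling and insensitive to molecule size.
Hidden width 71 places the encoder at 74,962 parameters (prints 75 k).
Batches are disjoint unions of graphs; this is algebraically identical to
encoding one graph at a time (asserted to 1e−6).

## Fusion and classification

Three strategies are implemented; hierarchical is the default and the one
the tuned configuration uses:

- **hierarchical** — per-view linear map to 64 + ReLU, then concatenation;
- **concatenation** — raw 128+128 concatenation;
- **cross_attention** — single-head scaled dot-product attention of each
  view over the other, the views being length-1 token sets. With a single
  key the softmax weight is identically 1, so each view receives the
  other's value projection; the query/key maps are retained for
  faithfulness to the strategy's definition but receive no gradient. This
  degeneracy is inherent to attending over one token.

The head is three fully connected layers (64 → 32 → 1): two hidden blocks
each followed by dropout (rate 0.2), then a logistic output. Single-view
ablation models reuse the identical components with one view absent. The
decision threshold is 0.5 with ties going to the positive class.

## Training

Adam with decoupled weight decay (3e-3) on the mean binary cross-entropy,
batch size 64, gradients clipped at global norm 5. Minibatches group
records of similar length (bucket membership and batch order reshuffled
every epoch from the seeded generator) so the recurrent unroll per batch is
short; this is a throughput choice with no effect on the model class.
Early stopping monitors validation loss (default: a stratified 10% carve-out
from the training data, so cross-validation test folds are never touched)
and restores the best-validation checkpoint.

Two optimization profiles exist:

- **full-scale defaults** (estimator defaults): learning rate 1e-5, up to
  300 epochs, patience 30 — sized for the real benchmark corpora;
- **`DESK_TRAINING`**: learning rate 1e-3, up to 20 epochs, patience 4 —
  sized for the 800-peptide synthetic benchmark, where the stronger
  learning rate converges in minutes on one CPU.

Every random draw (parameter init, bucket shuffling, dropout masks,
validation carve-out) flows from one integer seed through stable
per-component derived seeds, so the full train → predict path is
bit-reproducible (asserted in the tests).

All tensors run in float64 by default; the estimators train in float32 for
speed. The autodiff engine is eager, single-threaded NumPy; determinism on
a given machine is part of its contract.

## Synthetic data: what it does and does not show

Positives draw residues i.i.d. from
`p = (1−s)·uniform + s·uniform-over-{H,W,Y,C}`; negatives are i.i.d.
uniform; lengths are uniform on [2, 50] (a `length_weights` hook accepts
arbitrary distributions). The bias residues mirror the compositional
enrichment reported for experimentally validated radical scavengers; the
single parameter `s` makes every class statistic closed-form, so the
Bayes-optimal likelihood-ratio classifier is computable exactly and serves
as the ceiling against which trained models are judged. The fixed
benchmark uses s = 0.6 with 400+400 training and 100+100 disjoint test
peptides.

What passing these tests shows: the encoders extract composition-scale
signal, the fusion does not destroy it, optimization converges, and the
evaluation pipeline is correct end-to-end. What they do not show: real
AOP activity depends on residue order, position and structure in ways an
i.i.d. composition model cannot emulate, and real negatives are not
uniform random strings. Synthetic accuracy therefore says nothing
quantitative about accuracy on laboratory data.

## Evaluation conventions

- MCC with a zero denominator is reported as 0, flagged; precision with no
  predicted positives, and sensitivity/specificity with an absent class,
  likewise report 0 with a flag — degenerate folds aggregate cleanly.
- Paired t-tests operate on fold-wise metric differences (df = k−1).
  Zero-variance differences: p = 1 when the mean difference is also ~0,
  otherwise ±∞ with p = 0, flagged as a fully systematic offset.
- The length ablation splits at 15 residues (short < 15 ≤ long), the
  approximate minimum for stable secondary structure.
- Dataset merging defaults to plain concatenation; deduplication (first
  occurrence wins) and conflict dropping are explicit options, and label
  conflicts always produce a warning listing the sequences. The published
  merged-corpus total cannot be reproduced from the public per-dataset
  counts under either rule, so no claim is made to match it.
- Sequence identity uses global alignment with match 1, mismatch 0, gap −1,
  identity counted over alignment columns — the simplest reproducible
  convention, since no method is named in the source material.

## Known limitations

- The SMILES templates cover the 20 standard residues only; B/J/O/U/X/Z
  are rejected at validation rather than guessed at.
- Graphs ignore stereochemistry, conformation and non-covalent structure;
  for long peptides 2D topology is known to under-describe activity.
- The grid-search helper runs each candidate at a reduced epoch budget;
  winners should be retrained at full budget.
- The NumPy engine is single-threaded apart from BLAS; it is sized for
  datasets of thousands of peptides, not millions.
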