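# Methods

## Data model and padding

Input is the standard trio of a longitudinal 16S study: a sample-by-taxon
relative-abundance matrix (rows sum to 1; deviations beyond 1e-3 warn
rather than fail, since published tables are pre-normalized and sometimes
truncated), a metadata table mapping each sample to (subject, time point,
outcome), and optionally a taxonomy map. Outcomes are subject-level
properties, so conflicting labels within a subject are an error, not
last-wins. The canonical time grid (e.g. weeks 0/4/12/52, or monthly
indices) is user configuration rather than inferred from the data, which
makes slot alignment deterministic across runs and studies.

Missing visits are zero-padded under two strategies exposed behind
`strategy_tag`:

* **pad_in_sequence** — observations stay at their canonical slots;
  missing slots are zero vectors. Training treats the sequence as fully
  dense (no loss-level masking): the recurrent gates see the zero rows, and
  gradient descent is free to learn what "all-zero at week 4" means.
* **pad_at_end** — observations are compacted to the leading slots in time
  order with a zero suffix and a prefix observation mask. Here the trainer
  *does* use the mask: state updates at masked slots are skipped (the
  hidden and cell states carry through unchanged) and the "last output" is
  the hidden state at each subject's final observed slot. A masked run on a
  padded subject is therefore identical to an unmasked run on that
  subject's compacted sequence — an invariant asserted in the tests.

Both batch forms carry the mask; the padding carries no imputation model —
the recurrent network itself is expected to refine the zero placeholders.

Optional PCA reduces the taxon dimension to 300 components (the default).
Time slots are treated as independent rows for fitting, the fit uses only
the training fold's observed rows (never validation rows, never padded
zeros), and padded slots are re-zeroed after projection. Fitting inside
each CV fold costs a few refits but removes a leakage path.

## Networks

All modules run on the in-package reverse-mode autodiff engine
(`autodiff.py`), a deliberately small tape machine over numpy arrays.
Every backward rule is verified against central finite differences in the
test suite, and the fused fast paths (concatenated LSTM gate matmuls, the
einsum-based 1-D convolution) are verified against their naive per-gate /
sliding-window counterparts.

* **LSTM** — single layer, hidden size 128 by default. The hidden state is
  h_t = o_t ∘ tanh(c_t). A `state_squash="sigmoid"` switch replaces the
  tanh with a sigmoid, because one published description of this
  architecture prints the hidden-state equation that way; the tanh default
  follows the same source's own prose (the cell-state nonlinearity
  "squashes values between −1 and 1") and canonical LSTM practice.
* **CNN-LSTM** — a stack of 1-D valid cross-correlations over the taxon
  axis within each time point, kernel weights shared across time; defaults
  2 layers × 32 channels, kernel 5, stride 2 (no architecture constants are
  published for this model family; all are config-exposed). tanh sits
  *between* conv layers and none after the last: the recurrent gates supply
  the nonlinearity on the way in. An earlier ReLU variant could die
  wholesale on unlucky initializations (all-zero features with zero
  gradient, collapsing training to constant predictions); tanh cannot, and
  the choice also makes the k=1 identity-conv reduction to the plain LSTM
  exact — a test invariant.
* **Head** — one hidden layer (width 64, tanh) then softmax for mutually
  exclusive classes or per-label sigmoid in multi-label mode.
* **RNN baseline** — h_t = tanh(W_x x_t + W_h h_{t−1} + b), same head.
* **Sparse autoencoder baseline** — symmetric ReLU autoencoder whose
  *latent* layer is sigmoid so that the Bernoulli-KL sparsity penalty
  β·Σₙ KL(p ‖ p′ₙ) is well defined (p′ₙ is the batch-average activation of
  latent unit n; values at the boundary are clamped to [1e-7, 1−1e-7] with
  a warning). The full loss is reconstruction MSE + λ·Σ‖W‖² + the KL term.
  In the two-stage baseline the encoder is fit per training fold on
  observed rows, frozen, and its codes feed a plain LSTM classifier.

Weights are initialized uniform ±1/√fan_in from a per-model seed; forward
passes are deterministic and bitwise-stable.

## Distillation training

The trainer (`distill.train`) runs mini-batch Adam (lr 1e-3, batch 64,
100 epochs by default — batch and epochs follow the study protocol, the
optimizer is a package default) under three schemes:

* `none` — hard-label cross-entropy (Bernoulli per label in multi-label
  mode). Optional inverse-frequency class weighting is off by default.
* `fd` — adds, per branch, w_ce·CE(branch) + w_kl·KL(branch ‖ detached
  main) + w_feat·L2(W_main_penult, W_branch_penult), summed across
  branches with default weights (1, 1, 1). Branch penultimate layers are
  sized to match the main head's so the weight-matching penalty is
  well-posed; each branch reaches that shape through a small adapter
  layer. Two branches by default on the CNN-LSTM (after the conv stack,
  after the LSTM), one on the plain LSTM. The KL teacher is
  gradient-detached: distillation shapes the branches, not the teacher.
  The KL is implemented in its standard non-negative form
  Σ p log(p/q); probabilities are clamped to [1e-7, 1−1e-7] and
  renormalized.
* `sd` — progressive self-distillation. A per-sample teacher cache holds
  the previous epoch's predictions (epoch granularity; populated by an
  initial forward pass before epoch 1, refreshed at each epoch boundary,
  always gradient-detached). The ramp αₜ = α_T·t/T with α_T = 0.8 by
  default. `fd` and `sd` cannot be combined.

Two reduction identities pin the schemes to the baseline trainer and are
asserted to 1e-6 per epoch under a shared seed: `fd` with zero auxiliary
weights, and `sd` with α_T = 0, both retrace the plain trainer's loss
trajectory exactly.

## Transfer

Two studies' feature spaces are aligned by aggregating OTUs to a shared
taxonomic rank (phylum by default) — group abundance is the sum of member
abundances, preserving row sums — and intersecting the rank-level name
sets. The harmonized column order is the sorted intersection (recorded in
a JSON report). Fine-tuning then loads the source body, reinitializes the
head for the target label dimension, switches to a concat-pool head
(mean ‖ max ‖ last hidden over observed steps), and trains under gradual
unfreezing (the last block on epoch 1, one more block per epoch) with
discriminative learning rates lr_k = base/decay^(distance from last),
decay 2.6. "Layers" are counted at block granularity (conv stack, recurrent
core, head). Frozen blocks are skipped by the optimizer entirely, so their
parameters stay bitwise unchanged.

## Evaluation

Cross-validation is at subject level, stratified on the outcome by default
(falling back with a warning when a class is smaller than k), 10 folds in
the standard protocol; the held-out fold is the validation set — there is
no separate test partition. Multi-class ROC-AUC is macro one-vs-rest and
multi-class F1 is macro (the averaging convention is not fixed by the
protocol this package follows; the choice is recorded in every report).
Multi-label runs average per-label AUC/F1. Degenerate single-class inputs
yield NaN (reported missing), never a silent 0.5. F1 is computed as
tp/(tp + (fp+fn)/2), identical to the precision/recall harmonic mean.

Last-time-point evaluation supports two protocols: `padded_last_slot`
(subjects unobserved at the final canonical slot are dropped; prediction
read at that slot) and `last_available` (all subjects; prediction at each
subject's last observed slot). The sensitivity analysis truncates every
subject to its first h observed time points, re-pads, and reruns the full
CV per horizon.

One outcome-label quirk worth flagging: the colitis study's severity
outcome is described as "three labels" but four names (inactive, mild,
moderate, severe); this package treats severity as four mutually exclusive
classes.

## Synthetic cohorts

The generator draws each subject's baseline composition from a symmetric
Dirichlet (concentration 0.8 — sparse, microbiome-like marginals) and
assigns a class from configurable weights. A fixed random 20% of taxa are
"signal" taxa; at grid position t a subject in class c has its signal taxa
multiplied by exp(effect_size · t · d_c) before renormalization, with class
directions d_c spread evenly over [−1, 1]. The drift accumulates over time,
so a model must integrate the trajectory rather than read any single
sample — the regime recurrent classifiers target, and one a purely
per-time-point CNN cannot solve alone. Missingness is missing-at-random
over non-initial time points (the baseline visit is never dropped);
multi-label mode gives each label its own signal-taxon block. A paired-
study fixture emits two cohorts whose taxonomies share an exact number of
phylum names, for transfer tests. All randomness flows from one seed;
outputs are byte-identical across runs.

What the generator does *not* emulate: phylogenetic correlation between
taxa, informative (outcome-dependent) missingness, overdispersed count
noise, or real studies' marginal abundance distributions. Passing tests
therefore demonstrate that the pipeline recovers a known low-dimensional
temporal signal under compositional constraints and realistic missingness
— not that it matches any particular study's published scores.

## Problem sizes and numerical choices

Training tests and the recoverability checks run scaled-down
configurations chosen as a package default: hidden 32, conv 16+16
channels, 60 epochs at lr 2e-3, 5-fold CV on 200-subject cohorts. Loss
probabilities are clamped at 1e-7 (a perfectly confident correct
prediction scores ≤ 1.2e-7, not 0). Ties in rank-based AUC count one half.
Non-finite losses abort training with the offending epoch. Checkpoints
store parameter arrays plus architecture metadata so partial (body-only)
loads for transfer are shape-checked.

## Known limitations

* With the default strong synthetic signal (effect 0.5 per time step) the
  baseline CNN-LSTM reaches ceiling CV AUC (≈ 1.0) at n = 200, so the
  distillation schemes can only tie, not strictly improve — the measurable
  benefit of self-distillation requires a regime where the baseline is not
  already saturated. The branch-distillation arm stays within 0.003 AUC of
  the baseline there.
* The autodiff engine is single-threaded numpy; it is sized for
  hundreds-of-subjects cohorts, not thousands.
* No GRU or attention variants; no calibration metrics; imputation beyond
  zero-padding is out of scope by design.
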