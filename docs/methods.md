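# Methods

## Problem and pipeline

Secondary-structure prediction assigns one of three states — helix (H),
strand (E), coil (C) — to every residue of a protein chain. The
discriminative signal comes from evolutionary profiles: a PSI-BLAST
position-specific scoring matrix (PSSM) gives 20 log-odds scores per
residue. The pipeline has five stages, each usable on its own:

1. **Encoding** — centered sliding windows over the 20-channel profile,
   zero-padded at chain ends; one sample per residue.
2. **Window CNN** — a depth-parameterized convolutional classifier over
   a single window.
3. **Bayesian optimization** — Gaussian-process / Expected-Improvement
   search over the CNN's training hyperparameters.
4. **BiLSTM** — a two-layer bidirectional LSTM over each protein's
   ordered sequence of CNN fully-connected features.
5. **Metrics** — Q3 and per-class recalls Q_H/Q_E/Q_C from a 3×3
   confusion table.

## Encoding

Windows are 0-based and inclusive, `[i−p, i+p]` with `p = (w−1)/2`;
the indexing convention is ours (nothing forces one). Out-of-chain
positions are all-zero 20-vectors, distinguishable from real columns
because log-odds columns are practically never exactly zero everywhere.
Profile values are used raw by default; per-channel standardization
(mean/sd fitted on training data only) is available behind a flag
because PSI-BLAST log-odds already arrive roughly centered and sharing
units across channels. Residues outside the 20-letter alphabet are
mapped to `X` and keep whatever profile column they came with; no
imputation. DSSP letters outside the canonical eight (e.g. `C`, `-`)
fall into the coil catch-all, which is also where unknown letters land
(with a warning) — the reduction is total by construction.

## CNN family

`ArchitectureSpec(part_depth=d)` builds four parts of `d` conv layers
(ReLU after each), pooling after each part, one FC layer (default width
50 — this is also the BiLSTM input dimension), and a 3-unit softmax.
Filter counts follow `round(filter_base/√d)` with `filter_base = 256`,
keeping the parameter budget roughly flat across depths (measured
spread across d = 1…7 at fixed kernels: < 1.5×). Desk-scale configs
lower `filter_base` (default 32 in the pipeline config) purely to fit
CPU training; the rule, not the absolute count, is the design invariant.
Kernel sizes default to the full window for the first two parts and 8
for the last two, generalizing the reported window-19 optimum; a
`published_optimal_architecture()` preset reproduces that printed network
verbatim (kernels 19/19/8/8, filters 94/94/128/128, pooling after every
four conv layers) — note its filter counts do **not** follow the
256/√d rule; we expose both rather than silently reconciling them.

Numerical choices:

* **Pooling is ceil-mode** along the window axis (a trailing partial
  window is pooled as-is; averages divide by the actual member count).
  Floor-mode pooling would collapse a window of 13 to width 0 after the
  fourth part (13→6→3→1→0), making the default configuration
  unbuildable; ceil-mode (13→7→4→2→1) keeps every depth/window
  combination valid. A width-below-1 check remains and names the
  offending part.
* Pooling acts along the window axis only — the 20 amino-acid channels
  are not spatial, so a square 2×2 pool over a (window × channel)
  layout was rejected.
* The softmax head is zero-initialized: an untrained model predicts
  exactly (⅓, ⅓, ⅓), and the first optimizer step unblocks it.
  Ties in argmax resolve to the lower class index in (H, E, C) order.
* Optimizer: SGD with classical momentum; L2 decay applies to weights,
  not biases. Defaults 20 epochs, batch 128 (desk-scale pipeline: 4
  epochs). Training is deterministic given the seed (single numpy RNG,
  no threading nondeterminism in practice).
* FC features for the BiLSTM are taken **post**-ReLU by default
  (`fc_post_activation=False` switches to pre-activation); the choice
  is not forced by anything upstream.
* Class imbalance is not reweighted by default; inverse-frequency
  weights sit behind a config flag.
* Layer counting: `conv_layer_count = 4d`; `total_layer_count` counts
  input, conv, ReLU, pool, FC and softmax layers; `table_layer_count =
  4d + 6` reproduces the 10/14/18/22 convention used in published trial
  tables (which does not include ReLU layers despite claiming to — we
  report all three counts instead of guessing intent).

All layers carry hand-written backward passes; a numerical-vs-analytic
gradient check (central differences, relative tolerance 1e-4) guards
the conv/pool/FC stack and the full BiLSTM BPTT in the test suite.

## Bayesian optimization

The objective is the CNN's final validation cross-entropy as a function
of (learning rate, momentum, L2, part depth). Observations are modeled
as a GP with squared-exponential kernel on the unit-normalized search
box; bounds envelope the published trial values: lr log-uniform
[1e-3, 1e-2], momentum [0.6, 0.99], L2 log-uniform [1e-10, 1e-3], depth
integer [1, 7].

* Prior mean = empirical mean of observed losses; signal variance =
  var(y); noise variance σ_n² = 1e-4·var(y), recomputed each fit.
* Length scale fixed at 0.3 in normalized coordinates; optional
  marginal-likelihood selection over a log grid behind
  `optimize_hypers=True`. A fixed scale keeps small-budget fits stable.
* Cholesky with a jitter ladder 0 → 1e-10 → … → 1e-6; failure past the
  ladder raises with a condition estimate.
* EI is the closed form for **minimization** (improvement below the
  best observed loss), degenerating to max(0, f_best − μ) at σ = 0;
  negative posterior variances beyond −1e-10 are clipped to 0 with a
  warning.
* Acquisition is maximized over 2048 scrambled Sobol' candidates with
  the integer dimension snapped to its grid before evaluation; ties go
  to the first maximizer in draw order.
* Trials returning NaN (diverged training) are recorded as failed and
  excluded from the surrogate.

## BiLSTM

Each gate has separate recurrent and input weight blocks (a single
shared matrix per gate would require equal hidden and input dimensions
and contradicts the standard cell). Two stacked bidirectional layers;
forward and backward parameter sets are independent; per-position
merge is concatenation (summation behind a flag). Desk-scale defaults
are 64/64 hidden units (32/32 in the pipeline config); a preset exposes
the published best cell sizes 1000/800. Initial states are zero;
forget-gate biases start at 1. Sequences are batched with tail padding;
padded positions are excluded from the loss (and, because padding is
always at the tail after per-sequence reversal, they cannot leak into
valid positions). Training uses Adam (lr 0.01) with global gradient-norm
clipping at 5 — plain SGD is noticeably less stable through two
recurrent layers. The BiLSTM consumes whole-protein feature sequences,
not windows: its entire purpose is context beyond the window.

## Synthetic data

The generator emulates exactly the features downstream stages rely on:

* **Segmental labels**: a first-order Markov chain over {H, E, C} with
  stay probability 0.9 (mean segment length 10, geometric); on a
  switch, the next state is drawn from the other two in proportion to
  the prior (0.35, 0.25, 0.40) — close to helix/strand/coil marginals
  of globular chains. A Markov chain rather than i.i.d. labels gives
  the BiLSTM genuine long-range context to exploit.
* **State-dependent composition**: each state's 20-letter residue
  distribution is drawn once per run from a symmetric Dirichlet with
  concentration 1/emission_sharpness (default sharpness 2).
* **PSSM-like profiles**: column i = profile_signal × log-odds of the
  emitting state's composition + N(0, profile_noise_sd²) noise,
  i.i.d. per entry. Defaults signal 0.5, noise 5.0 were calibrated once
  so the desk-scale window CNN lands at ~80% Q3 — the regime real
  profile-based predictors occupy — rather than saturating near 100%,
  where the CNN-vs-BiLSTM comparison would be vacuous. With signal 0
  the profiles are exchangeable noise and nothing is learnable.

What it does **not** emulate: the marginal distribution and integer
quantization of real PSI-BLAST scores, position-dependent profile
quality, sequence-profile correlation beyond the state, amphipathic
periodicity inside helices, or non-geometric segment-length
distributions. Passing tests therefore demonstrate that the machinery
learns a planted segmental profile signal — not that it attains any
particular accuracy on real proteins.

Corpus defaults: 200 chains of 30–80 residues (~11k residues), split
0.6/0.2/0.2 at protein level. One seeded RNG per generate call;
sub-streams (compositions, chains, profiles) derive from fixed offsets.

## Pipeline and problem sizes

`run_pipeline` performs protein-level k-fold cross-validation (default
3 folds × 1 repeat; repeats with re-seeded partitions are available and
pool by summing confusion tables). Within each training fold, an inner
80/20 protein split provides the optimizer's validation set; the test
fold is never visible to encoding statistics, optimization or training
(protein-id bookkeeping, asserted). Desk-scale defaults — 200 proteins,
window 13, depth search [1, 3], 6+6 optimizer trials at 2 epochs each,
4 final CNN epochs, 8 BiLSTM epochs — are chosen so a full run fits
comfortably on one CPU; all are config fields. The acceptance script
uses a single split with 3 training seeds for the same reason.

## Known limitations

* Eight-state prediction is out of scope; labels are consumed as
  letter strings, not parsed from raw DSSP output.
* The GP surrogate is single-fidelity and proposes one point at a time;
  no input warping or non-Gaussian likelihoods.
* NumPy training is single-threaded-CPU scale; the published
  full-data accuracies require NR-database profiles and GPU budgets and
  are not reproduced here.
* `X` residues keep their profile columns; chains consisting mostly of
  `X` will carry little signal.
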