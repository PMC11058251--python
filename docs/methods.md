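# Methods

## The model

somnoscore scores sleep stages (W, N1, N2, N3, REM) from single-channel raw
EEG, one label per 30-s epoch (3000 samples at 100 Hz). It has two parts,
trained in **separate phases** ("separating training"):

1. **Feature extraction** — fifteen small CNNs, one per pair of
   *(epoch-shift view, target stage)*. The three views pair a signal with the
   *current* epoch's label: the current epoch itself (set A), the previous
   epoch (set B, right-shift with the first epoch duplicated), or the next
   epoch (set C, left-shift with the last epoch duplicated). Each CNN is

       conv(10 filters, 1×55) → ReLU → BN → maxpool(1×16)
       → conv(5, 1×25) → ReLU → BN → maxpool(1×16)
       → flatten(55) → FC(10) → ReLU → FC(5) → softmax

   (2,460 trainable parameters under this counting convention: kernels,
   biases, BN scale/offset, FC weights; BN running statistics excluded).

2. **Sequence classification** — a single BiLSTM (128 hidden units per
   direction) over each record's sequence of concatenated CNN softmax
   outputs (15 models × 5 probabilities = 75 features per epoch), followed
   by a 5-way FC head and a per-epoch argmax (ties break toward the lower
   stage index in the order W, N1, N2, N3, REM). 210,181 parameters;
   247,081 for the full ensemble.

### Class-weighted loss

Overnight hypnograms are strongly imbalanced (N2 dominant, N1 rare). Each
CNN targeting stage *c* minimizes a weighted cross-entropy

    loss = −(1/N) Σ_n Σ_i w_i Y_ni ln Ŷ_ni,   w_i = 0.5 / p_i,

with p_c = N_c/N and p_{i≠c} = (N−N_c)/N, so the target stage and its
complement carry equal total importance; algebraically w_i·p_i = 0.5 for
every stage. Probabilities are clipped at 1e−12 inside the log. The BiLSTM
uses plain (unweighted) cross-entropy.

### Training protocol

* CNNs: Adam (lr 0.001), batches of 64 epoch/label pairs drawn from the
  pooled, epoch-wise-shuffled 70/30 train/validation split; validation on the
  full held-out split every 150 iterations; stop after 10 consecutive
  non-improving validations (strict improvement, min-delta 0) or a pass cap
  (1,000 by default); the best-validation checkpoint is returned
  (configurable to last-iteration).
* BiLSTM: Adam (lr 0.01), batches of 4 whole-record sequences (padded,
  padding masked out of the loss), record-wise 90/10 split, validation every
  10 iterations, patience 10, same checkpointing. MOVEMENT/"?" epochs are
  relabeled W so sequences stay contiguous, and are masked out of evaluation.
* Per-component seeds derive from the master seed by hashing (set, class), so
  any single model can be retrained reproducibly.

Epoch pairs whose shifted *signal* comes from a MOVEMENT/"?" epoch but whose
*target* is scoreable are kept by default (exclusion is governed by the
scored target only); `drop_artifact_signals=True` provides the stricter
alternative, since the original convention for sets B/C is ambiguous.

The end-to-end baseline couples one unweighted CNN to the BiLSTM through its
5-way softmax and optimizes everything jointly. A 64-epoch batch is not
meaningful for joint sequence training, so it uses sequence batches of 4
records with the CNN learning rate (0.001); everything else follows the CNN
protocol.

## Numerical engine

The networks run on a small numpy engine with hand-written reverse-mode
gradients (`somnoscore.nn`). Convolutions are evaluated in the Fourier
domain (correlation, full-convolution input gradient, and kernel gradient
via `scipy.fft`), which is exact to rounding and fast on a single core.
Parameters default to float32; float64 is available and used by the
finite-difference gradient tests (relative agreement ~1e−7). Batch
normalization uses eps 1e−5 and momentum 0.1; initialization is seeded
Glorot-uniform; the forget-gate bias starts at 1. All randomness flows
through explicit `numpy.random.Generator` streams, so training is
bit-reproducible given a seed on a fixed BLAS configuration.

## Evaluation

Predictions are produced many-to-many over whole records; epochs originally
scored MOVEMENT/"?" are excluded from scoring via the evaluation mask.
Cross-validation is subject-wise (all of a subject's recordings share a
fold; k equal to the subject count gives leave-one-subject-out). Fold
results are aggregated by **pooling confusion counts** across folds
(per-fold reports are also emitted, since single overall numbers can be
defined either way).

From the pooled 5×5 confusion matrix: per-class precision/recall/F1 (0/0
conventions resolve to 0 with a warning; macro averages always run over all
five classes), ACC, macro-F1 (MF1), average precision (APR) and average
recall (ARC). Agreement statistics: Cohen's kappa with the
Fleiss–Cohen–Everitt asymptotic variance (95% CI) and a two-tailed z-test
under H0 κ=0; Fleiss' kappa (1971) for ≥3 raters with its large-sample SE
(used for both CI and z — the common simplification). McHugh bands are
applied at the printed decimals with half-open intervals: ≤0.20 None
(negatives included), <0.40 Minimal, <0.60 Weak, <0.80 Moderate, ≤0.90
Strong, else Almost Perfect.

## Synthetic cohorts

Real overnight PSG requires large downloads and hours of training, so the
package ships a generator whose defaults emulate the statistical structure
the method relies on:

* **Hypnograms**: first-order Markov chains over the five stages, diagonal
  ≈0.88 (stage continuity) with N2-favouring off-diagonal mass; stationary
  prevalences ≈ W .18, N1 .06, N2 .44, N3 .14, REM .18 — the imbalance the
  class weighting targets. Records start in W. A 2% artifact rate relabels
  epochs MOVEMENT/"?" independently.
* **EEG epochs**: mixtures of band-limited Gaussian oscillations
  (delta/theta/alpha/sigma/beta) over a 1/f background, with stage-typical
  band weights and RMS amplitudes (wake 30 µV alpha-dominant; N1 40 µV
  theta; N2 60 µV with 2–5 amplitude-modulated 0.5-s sigma spindle bursts;
  N3 110 µV delta-dominant; REM 45 µV mixed theta/beta). Per-subject
  log-normal gain jitter (σ=0.15) emulates inter-subject amplitude
  variation.

Stages are separable from band powers alone (a nearest-centroid oracle on
Welch band powers exceeds 80% accuracy), which guarantees the training tests
are well-posed. The generator does **not** emulate K-complexes, arousals,
apnea events, electrode artifacts, non-stationary drift, or realistic
inter-rater noise — so passing tests demonstrate that the pipeline's
mechanics and learning dynamics are correct, not that real-data accuracy
figures transfer.

## Problem sizes used by the test suite and acceptance script

Full-scale overnight training is hours of compute; the shipped runs use
scaled-down sizes chosen as package defaults:

* Cross-validated smoke run: 20 subjects × 1 record × 200 epochs, k=2
  subject-wise folds (the leave-one-subject-out structure is verified
  structurally), CNN passes capped at 4–5 and BiLSTM at 20–30. On one CPU
  core this achieves pooled accuracy well above the 70% sanity floor with
  every stage's F1 positive.
* Separated-vs-end-to-end comparison: 8 subjects × 120 epochs (6 train /
  2 test), five seeded repeats; the separated arm uses the single
  unweighted-CNN configuration so both arms share architecture exactly.
* Structural and formula checks run on 4-subject fixtures in seconds.

## Design choices on genuinely open points

* **Convolution padding** is "same" with stride 1; pooling is
  non-overlapping with floor semantics, giving the 3000→187→11 length
  arithmetic and the ~2.46k parameter count consistent with the nominal
  rounded figures.
* **"In-bed period"** is defined as first-to-last sleep-scored epoch, with
  the 30-minute trim margin implemented as 60 epochs on each side; records
  with no sleep epochs pass through unchanged with a warning.
* **Feature width per set** is 25 (each model's full softmax; 75 for the
  developed three-set configuration). A `condensed` mode (each model's
  target-class probability only; 5 per set) is provided because the
  single-set ablation can be read either way; the class-agnostic
  (unweighted) configuration always uses its plain 5-way softmax.
* **125 Hz inputs** (central-lead montages) are polyphase-resampled to
  100 Hz before epoching so the CNN input stays 3000 samples.
* **Checkpoint choice** defaults to best-validation (last-iteration
  available via config).

## Known limitations

* Synthetic realism is spectral only (above); absolute metric values on the
  synthetic cohorts are optimistic relative to real PSG.
* The engine is single-core numpy: full-scale (1,000-pass, 20-fold)
  training is possible but slow; the architecture is small enough that
  real-data experiments remain feasible off-line.
* Fleiss kappa CIs use the H0-based SE; bootstrap CIs are out of scope.
* Bit-reproducibility holds within a fixed BLAS/threading configuration.
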