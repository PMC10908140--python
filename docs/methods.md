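# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `capseeg`, in the order a reader meets them in the
pipeline.

## Data model and restructuring

The unit of analysis is a one-second, single-channel EEG segment of 178
samples (sampling rate 178 s⁻¹ by convention). Raw 23.5-second recordings
of 4097 samples are restructured into ⌊4097/178⌋ = 23 non-overlapping
segments; the trailing 3 samples are discarded, which is the only reading
consistent with the stated 23-segment count. Five label classes are used:
ictal seizure activity (class 1 / a), interictal recordings from the tumour
region (b) and from healthy tissue of tumour patients (c), and healthy
eyes-closed (d) / eyes-open (e) recordings. The binary task keeps class 1
as "seizure" and collapses 2–5 to "non-seizure", yielding a 1:4 imbalance
(2300 vs 9200 on a 500-recording corpus). `to_binary` refuses already-binary
input rather than silently passing it through.

## Synthetic segment generator

The generator emulates the qualitative class structure the classifiers
rely on, not the biophysics of EEG:

- **class a (seizure)**: 3 Hz spike-and-wave at amplitude 100 (≈10× the
  coloured-noise background), built from a sine plus a periodic
  von-Mises-shaped pulse whose harmonics decay quickly — chosen so the
  template's energy stays near 3 Hz instead of leaking into the alpha band —
  plus sparse heavy-tailed transients (Student-t, 3 df);
- **classes b, c**: AR(2) background (coefficients 1.2, −0.4; innovation
  sd 12) with sporadic spikes at 0.8 vs 0.3 events/s — deliberately
  confusable, mirroring the known difficulty of separating the two
  interictal tumour-related conditions;
- **class d**: strong 10 Hz oscillation (amplitude 50) over background;
- **class e**: attenuated 10 Hz (amplitude 10) over broadband noise.

Amplitudes are in the µV-scale units of the corpus dialect but unitless
internally. The defaults make the binary task easy (the seizure class is
separable on amplitude alone) and the five-class task moderately hard
(b/c overlap); passing tests on this data demonstrates that the pipeline
and optimizers work, **not** that the architectures reach corpus-level
accuracy on real EEG — real segments carry inter-patient variability,
artifacts, and non-stationarity the generator does not model.

`synth_localized_bursts` is a separate fixture-generator for saliency
evaluation: seizure segments carry one 3 Hz spike-wave burst confined to a
known 50-sample window, giving ground truth for localization scoring.

## Preprocessing conditions

Four named conditions: `any` (identity), `scaling` (per-position
standardization with population variance, ε = 1e-12), `pca` (projection
onto the top 40 principal components), `scaling_pca` (both). All parameters
are fit on the training partition only; whether the original protocol fit
them on the full data is unknown, so published accuracies may reflect a
more optimistic (leaky) protocol. PCA components have a deterministic sign
convention (largest-magnitude loading positive) so repeated fits are
bit-identical; n_components is fixed at 40 because the downstream tensor
contracts assume a 40-sample input, not because of a variance criterion.

## Class balancing

SMOTE and ADASYN are implemented from scratch (only the nearest-neighbour
search is delegated). Both emit synthetics x + u·(x_n − x) with
u ~ U(0,1) between a minority point and one of its k = 5 nearest minority
neighbours. SMOTE draws seeds round-robin from a shuffled minority
ordering; ADASYN allocates g_i = round(r̂_i G) synthetics per minority
point, where r_i is the majority fraction among its k nearest neighbours
in the full set, with the rounding residue settled one-by-one on the
highest-r̂ seeds and a uniform fallback when Σr = 0. Balancing is applied
to the training partition only, to keep test folds free of synthetic
leakage. Oversampling is defined for the binary task only.

## Architectures

The extractor follows the conv-block recurrence pool(f(norm(conv(x)))):
kernel-3 length-preserving convolution, per-channel batch normalization,
SELU (λ ≈ 1.0507, α ≈ 1.67326), and per block a size-2 floor-mode max-pool
plus dropout 0.5. Block plan: (2×32, 2×64, 3×128, 3×256, 3×512, 3×512) —
the six-layer 512 tail in two groups of three. A pool that would shrink
the map below one step is skipped (with a logged warning); this guard is
what makes the 40-sample PCA input viable and reproduces the published
(2, 512) / (1, 512) feature-map contracts for 178- and 40-sample inputs.

Heads:

- **dense**: global-max-pool over time, then 1024, 512, 256, 128, 128, 64,
  32, 16 units (batch-norm + SELU each; the duplicated 128 follows the
  prose architecture description), then a softmax output layer;
- **capsule**: the (t × channels) map regrouped into primary capsules of
  dimension 16 (`num_caps` is read as capsule *width*; the alternative
  reading — 16 primary capsules — remains reachable through the
  `num_caps` / `capsule_d_out` fields of `ArchitectureSpec`), squashed,
  transformed by W_ij, routed for
  r = 3 iterations (the convention of the original capsule formulation;
  the routing depth is otherwise unstated);
- **transformer**: post-norm encoder blocks (MHA → residual + LayerNorm →
  4×-wide SELU MLP → residual + LayerNorm); no positional encoding by
  default since the encoder sees at most two positions (sinusoidal
  encoding is available behind a flag); head counts/layers per variant:
  16/2 (`cnn_tf`), 16/1 (`cnn_tf_fully`), 8/1 (`cnn_tf_caps`).

Training: Adam(lr 0.001, β = 0.9/0.999), batch 128, 500 epochs, softmax
cross-entropy, no early stopping. `ArchitectureSpec.scaled(factor)`
divides conv channels (dense widths are cheap and stay as stated) for
desk-scale work.

### Numerical choices

- **Capsule logits.** Class-capsule lengths lie in (0, 1), so a softmax
  over raw lengths cannot express a class-probability ratio beyond e —
  it could not even represent the 4:1 binary prior. The head therefore
  scales lengths by a learnable logit temperature (initialized at 10, the
  usual cosine-softmax convention) before the softmax. A margin loss on
  the raw lengths is available via `loss="margin"`.
- **Batch-norm re-estimation.** Dropout interleaved with batch-norm causes
  a variance shift between train-mode and eval-mode activations, so the
  running statistics tracked during training describe the wrong
  distribution (we measured a 0.96 → 0.80 eval-accuracy drop from this
  alone). `train()` ends with one pass over the training inputs with
  frozen weights and dropout disabled, replacing the running statistics
  with eval-consistent estimates — the same recalibration used with
  stochastic weight averaging.
- ε guards: 1e-7 in squash and layer-norm denominators, 1e-5 in batch
  norm, 1e-12 in the scaler.
- Max-pool gradient splits ties evenly; SELU's negative branch clamps its
  argument before `expm1` so masked branches cannot overflow.
- Everything runs in float64; determinism is exact under a fixed seed on
  one machine (init, batch order, and dropout masks all derive from the
  spec seed).

## Evaluation

Metrics follow the confusion-matrix definitions — accuracy
(TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall TP/(TP+FN), F1 their
harmonic mean — computed one-vs-rest per class for multiclass, with macro
averages alongside. Degenerate ratios (zero denominators) report 0 and are
flagged. The confusion matrix is oriented predicted-rows × actual-columns
(the transpose of the common convention, kept for comparability with the
reference tables); the serialized form labels both axes. Cross-validation
is the mean ± sd of per-fold accuracy over stratified k = 10 folds.

1-D Grad-CAM differentiates the pre-softmax class score with respect to a
named conv layer's feature maps, time-averages the gradients into channel
weights, and rectifies the weighted sum; maps are linearly upsampled to
the input length and normalized to [0, 1] per map. For localization
analyses a mid-stack layer (e.g. `block3_conv3`, 22 time steps) is the
right probe: the final conv layers see only 2 time steps after pooling,
too coarse to resolve a 50-sample burst.

## Classical baselines

The eight classical algorithms (DTC, MLP, KNN, SGDC, ETC, SVM, RFC, GB)
run through scikit-learn behind a grid-search harness; the default grids
are built around the published winning values (each winner plus a
neighbouring value — the original full grids were not published). Tree
ensembles expose impurity-based feature importance for the top-30 ranking.

## Problem sizes used in the test-suite

The end-to-end checks train the scaled-down variants (conv channels ÷ 8)
on 100 synthetic segments per class, batch 32: 30 epochs for the
capsule-accuracy checks (binary ≥ 0.90, five-class ≥ 0.60 vs 0.20 chance),
10 epochs × 3 seeds for the loss-trend check on all five variants, and
100 epochs on 300 burst-labelled segments for Grad-CAM localization
(≥ 80/100 segments). These sizes were chosen as the smallest at which the
checks are stable across seeds.

## Known limitations

- Single-channel, fixed-length segments only; no EDF/BDF ingestion,
  multi-channel montages, or artifact rejection.
- The published corpus-level accuracies (99.9 % binary, ~87–88 %
  multiclass) are not reproducible from synthetic data and are out of
  scope here; the synthetic tasks verify mechanism, not clinical
  performance.
- The numpy engine is single-threaded apart from BLAS matmuls; full-size
  500-epoch training is out of its intended range.
- Routing unrolls through the autodiff graph; gradients flow through all
  r iterations (no stop-gradient variants).
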