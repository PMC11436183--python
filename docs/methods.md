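# Methods

## Problem and model

The task is binary classification of single EEG epochs: perception
(class 1) versus imagination (class 0) of a stimulus, one decision per
trial, from `C` channels × `T` samples of raw epoched EEG. The model is a
capsule network in two stages: a convolutional front-end (the
spatio-temporal capsule-generation block, STCG) that turns the epoch into
`n_caps` primary capsules of dimension `d_caps`, and a single routed
capsule layer that maps them to one output capsule per class, whose norm
is the class score.

The model assumes only that class information is present in stationary
spatio-temporal second-order structure: the temporal convolution learns
band/latency filters, the spatial depthwise convolution learns electrode
patterns, and routing learns which conjunctions of capsule-level features
vote for which class. No artifact handling, re-referencing or filtering is
performed — the model consumes raw epochs.

## Squash and routing

Capsules are squashed to norm `1 − e^{−‖s‖}`. At the origin the formula
is 0/0; the continuous extension `squash(0) = 0` is implemented with an
epsilon-guarded norm (`√(‖s‖² + 1e−12)`), which keeps gradients finite and
perturbs the norm law by less than 1e−9 for any input of norm ≥ 1e−3. For
extremely large inputs the output norm can measure one ulp above 1 purely
from final rounding.

Self-correlation routing computes predictions `Û = U W`, a per-class Gram
tensor `A = Û Ûᵀ / d_l`, coupling `C = softmax(Σ_k A)` across output
capsules (stabilized by max-subtraction, which leaves the values
unchanged), and the aggregate `S_j = Σ_i (C_ij + B_ij) Û_ij`. Design
points that were genuinely open and how they were fixed:

* **Output squashing.** The output capsules are squashed after
  aggregation (flag `squash_output`). The margin loss and the
  norm-as-probability reading both require norms in [0, 1], which the
  unsquashed sum does not guarantee.
* **Gram scaling.** The default divides by `d_l`; `corr_scale="sqrt_d"`
  switches to the `√d_l` convention used by attention mechanisms, since
  either scaling is defensible. Only the default is used in tests.
* **Initialization.** `W ~ N(0, 1/d_l)` (fan-in scaled) seeded; `B = 0`,
  i.e. no initial preference between capsule pairs.
* **Output capsule dimension** defaults to `d_out = 16`, a conventional
  class-capsule size; it is a free config field.

The dynamic-routing baseline is the classic routing-by-agreement: zero
logits, then per round softmax-coupling, weighted sum, squash, and a
logit update by the prediction–output dot product. It exists for the
ablation grid and as an independent cost reference.

## Architecture defaults

The front-end skeleton (5 conv + 2 pool) is fixed; the free parameters
default to `F1 = 16` temporal filters of length `TI = 65` samples
(≈ 63 ms at 1024 Hz), depth multiplier `D = 2`, `F2 = 64` pointwise
filters, average pooling widths 4 and 8. These are standard
depthwise-separable EEG front-end proportions and make the temporal
pipeline close exactly on both T = 3073 and T = 2049:
`T → T/4 → T/32`, and the fusion kernel spans whatever remains, so the
block always emits exactly `F2` values. The hard invariant is
`F2 = n_caps · d_caps`; the config validates it and the sweep harness
re-derives `F2` at every sweep point. Primary capsules default to
`n_caps = 8`, `d_caps = 8` — the middle of the count range that the
sensitivity sweep covers (2–12) and the top of the dimension range (1–8),
where accuracy saturates. Batch normalization + ELU follow conv layers
1, 2 and 4 (switchable, `batch_norm=False` removes them); average rather
than max pooling because pooling here reduces redundancy in a continuous
signal rather than detecting sparse events.

Training defaults: Adam, learning rate 0.02, batch size 20, 120 epochs,
margin loss with m⁺ = 0.9, m⁻ = 0.1, λ = 0.5, mean reduction over the
batch (stable learning-rate semantics across batch sizes). No schedule,
no early stopping. The "reduced" preset (16 channels, 129 samples, F1 = 8,
TI = 9, 30 epochs) is the geometry used by the test suite so the full
pipeline trains in tens of seconds on one CPU core; it changes scale
only, not structure.

## Synthetic data

The generator emulates the study geometry — two balanced classes, 124
channels at 1024 Hz, 3073 samples (visual) or 2049 (audio), the sample
count being `round(duration·sfreq) + 1`. Each class owns a fixed random
spatial mixing matrix (channels × sources) and band-limited oscillatory
sources (4–30 Hz by default) with class-specific frequencies, phases and
Welch-window amplitude envelopes; a trial is the class template plus
pink (1/f) noise given a fixed random spatial covariance, rescaled
per-trial so that `10·log10(mean template power / mean noise power)`
equals `snr_db` exactly. `snr_db = +inf` disables noise, making trials
identical to their templates — the anchor for exact tests.

What it deliberately does not model: head geometry or dipole physics,
trial-to-trial signal variability (the class template is fixed per seed),
non-stationarity across a session, and artifacts (blinks, EMG, line
noise). Passing tests therefore demonstrate that the architecture,
routing, losses and harness are correct and that the pipeline can extract
genuine spatio-temporal class structure at a given SNR — they say nothing
about accuracy on real recordings, where variability and artifacts
dominate. The default `snr_db = 10` is a clean-signal regime chosen so
the "easy" condition is unambiguous; chance-level behaviour is probed at
−30 dB.

## Complexity accounting

`count_complexity` gives closed-form per-layer counts: convolution MACs =
output elements × kernel taps × (input channels per group), 1 MAC =
2 FLOPs, exponentials/divisions counted as 1 FLOP. Because both routing
mechanisms consume the same prediction transform, the transform is its
own line item and `routing_flops` isolates the part that differs. In
closed form the routing-proper costs are ≈ `(n_l² + n_l)·n_out·d_out`
MACs for self-correlation (the Gram term dominates) versus
≈ `2r·n_l·n_out·d_out` for r rounds of dynamic routing, a ratio of about
`2r/(n_l + 1)`: at r = 3 dynamic routing costs roughly twice
self-correlation for small capsule counts (n_l = 2) and the advantage
reverses past n_l ≈ 5, where the quadratic Gram term takes over. The
complexity comparison in the acceptance suite is therefore made at the
small-capsule geometry where the near-2× relation holds; parameter
monotonicity is checked over the full 2–12 capsule sweep.

## Numerical and procedural choices

* Everything is float64 NumPy; with fixed seeds a (seed, config, data)
  triple reproduces losses and accuracies bit-for-bit on a machine.
* Softmaxes subtract the row maximum before exponentiation.
* Ties in the class argmax go to the lower class index.
* Cropping to a standard duration keeps the leading (stimulus-locked)
  window.
* Cross-validation folds are stratified with a seeded shuffle; the
  non-CV default split is a stratified 80/20 hold-out. Per-fold training
  seeds are `base_seed + fold` so folds differ but remain reproducible.
* The ablation grid trains all four front-end × routing variants on the
  identical hold-out split and seed, so rows differ only in the variant.
* The "traditional capsule" ablation front-end is two square-kernel
  convolutions (5×5, then 3×3 after a (2, 4) pooling) whose final maps are
  globally averaged into exactly `n_caps · d_caps` values — a deliberately
  generic convolutional capsule source with matched capsule geometry.

## Known limitations

* The autodiff core implements exactly the primitives this model needs
  (stride-1 convs, non-overlapping pooling, binary einsum); it is not a
  general framework and is CPU-only.
* Trial-invariant class templates make the synthetic task easier than
  real decoding; high accuracies on synthetic data are expected and are a
  pipeline check, not a performance claim.
* Complexity counts are analytic forward-pass estimates; they ignore
  memory traffic and framework overhead.
* The EDF import path takes consecutive fixed-length windows; event-based
  epoching should be done upstream with dedicated EEG tooling.
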