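# stcapsnet

A spatio-temporal capsule network with **self-correlation routing** for
binary EEG epoch classification — deciding from a single multichannel EEG
epoch whether a subject was *perceiving* a stimulus (class 1) or
*imagining* it (class 0). It is aimed at BCI / cognitive-neuroscience
researchers who want a light-weight capsule classifier for trial-wise EEG
decoding, complete with a seeded synthetic-EEG generator so the whole
pipeline can be exercised and tested without any recordings.

## Model

**Front-end (STCG block).** An epoch `X ∈ ℝ^{C×T}` (default 124 channels;
T = 3073 samples for 3 s at 1024 Hz, 2049 for 2 s) passes through five
convolutional and two pooling layers: a temporal convolution `(1, TI)`
with `F1` filters, a spatial depthwise convolution `(C, 1)` that collapses
the electrode axis, average pooling, a depthwise-separable convolution
(`(1, 16)` depthwise, then `F2` pointwise `(1, 1)` kernels), a second
pooling, and a depthwise fusion convolution spanning the residual temporal
extent. The resulting `F2 = n·d` values are reshaped into `n` primary
capsules `s ∈ ℝ^d` and squashed:

    squash(s) = (1 − e^{−‖s‖}) · s / ‖s‖

so each capsule's norm lies in [0, 1) and reads as a feature-presence
probability.

**Self-correlation routing.** With input capsules `U` (n_l × d_l) and a
learnable transform `W` (n_l × n_{l+1} × d_l × d_{l+1}):

    Û_{ij}   = U_i W_{ij}                             (predictions)
    A_{ikj}  = Û_{ij} · Û_{kj} / d_l                  (self-correlation)
    C_{ij}   = softmax_j ( Σ_k A_{ikj} )              (coupling, Σ_j C_{ij} = 1)
    S_j      = squash( Σ_i (C_{ij} + B_{ij}) Û_{ij} ) (output capsules)

with `B` a trainable log-prior matrix. The whole routing is a single
fixed computation graph — no iterations — unlike the classic
routing-by-agreement baseline (`dynamic_routing`, also included for
ablations). Output-capsule norms are the class scores; training minimizes
the margin loss

    ζ_n = T_n max(0, m⁺ − ‖u_n‖)² + λ (1 − T_n) max(0, ‖u_n‖ − m⁻)²

with defaults m⁺ = 0.9, m⁻ = 0.1, λ = 0.5, optimized with Adam
(lr 0.02, batch 20, 120 epochs by default). Accuracy is reported as
`(Tp + Tn) / (Tp + Tn + Fp + Fn) × 100%` with perception as the positive
class.

The package has no deep-learning framework dependency: it ships a small
NumPy reverse-mode autodiff core (`stcapsnet.autodiff`) sized exactly to
this architecture.

## Worked example

Simulate a synthetic two-class EEG set at a reduced geometry (16 channels,
1 s at 128 Hz, 10 dB SNR), train, and evaluate:

```bash
$ stcaps simulate --trials 50 --channels 16 --sfreq 128 --duration 1.0 \
      --snr-db 10 --seed 7 --out demo.npz
wrote 100 trials of shape (16, 129) to demo.npz

$ cat reduced.yaml
n_channels: 16
F1: 8
TI: 9
D: 2
F2: 64
pool1: 4
pool2: 8
n_caps: 8
d_caps: 8
d_out: 16

$ stcaps train --data demo.npz --out model.npz --config reduced.yaml \
      --epochs 15 --seed 0
final train accuracy: 100.00%

$ stcaps evaluate --model model.npz --data demo.npz
tp=50 tn=50 fp=0 fn=0
accuracy: 100.00%
```

The two classes differ in their spatial mixing and oscillatory dynamics;
at 10 dB SNR the network separates them perfectly (tp/tn are the correctly
classified perception/imagination trials). `stcaps inspect` prints the
layer plan — for this config:

```
$ stcaps inspect --config reduced.yaml --samples 129
layer                       kind  kernel    out shape       params
temporal_conv               conv  (1, 9)    (8, 16, 129)    80
spatial_depthwise_conv      conv  (16, 1)   (16, 1, 129)    272
avg_pool_1                  pool  (1, 4)    (16, 1, 32)     0
separable_depthwise_conv    conv  (1, 16)   (16, 1, 32)     256
separable_pointwise_conv    conv  (1, 1)    (64, 1, 32)     1088
avg_pool_2                  pool  (1, 8)    (64, 1, 4)      0
fusion_depthwise_conv       conv  (1, 4)    (64, 1, 1)      320
total trainable parameters (incl. routing): 4256
```

Other subcommands: `stcaps cv` (stratified k-fold cross-validation),
`stcaps ablate` (front-end × routing grid), `stcaps sweep`
(capsule-count/dimension sensitivity), `stcaps complexity` (analytic
MAC/FLOP and parameter counts, 1 MAC = 2 FLOPs).

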