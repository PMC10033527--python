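# Methods

## Task and model

Optic disc (OD) and optic cup (OC) are segmented jointly from an RGB
fundus image as a 3-class per-pixel problem — background (0), disc rim
(1), cup (2) — so the anatomical containment cup ⊂ disc is represented by
construction: the *disc* structure is rim ∪ cup, the *cup* structure is
the cup class alone.

The network is a U-shaped encoder–decoder (EARDS):

- **Encoder** — EfficientNet-b0: a 3x3 stem then seven MBConv stages
  (1x1 expansion by factor X ∈ {1,6}, k x k depth-wise convolution
  (k ∈ {3,5}), squeeze-and-excitation with squeeze width
  max(1, block_input/4), 1x1 projection; residual when stride 1 and
  channels match; Swish activations; no convolution biases under batch
  norm). The stem runs at **stride 1, padding 1**, so overall
  downsampling is 16x and a 512x512 input yields a 32x32 bottleneck.
  Skip features are taken after the stem (full resolution, 32 ch) and
  after the last block at each of 1/2 (24 ch), 1/4 (40 ch) and 1/8
  (112 ch); the bottleneck is the final stage output (320 ch at 1/16).
  Built unpretrained by default from a seeded initialization (He-normal
  fan-out); a state-dict file can be loaded optionally, with tensors of
  incompatible shape left at initialization.
- **Bottleneck projection ("bridge")** — two 1x1 convolutions
  (320 → 2954 → 3456, BN + Swish) at 1/16 resolution. See *Width
  calibration* below for why this wide projection exists.
- **Decoder** — five levels. At each of the four skip levels: the skip is
  attention-gated using the pre-upsampling decoder state as gating signal,
  the decoder state is bilinearly upsampled 2x, the two are concatenated,
  and an RDSC block mixes them. A fifth RDSC block refines at full
  resolution, and a 1x1 convolution with bias maps to K = 3 logits,
  normalized per pixel by softmax.
- **Attention gate** — 1x1 conv + BN on each input, the gating branch
  bilinearly resampled to skip resolution, sum, ReLU, 1x1 conv to one
  channel (bias), sigmoid; the coefficient multiplies the skip. Gradients
  flow to both inputs.
- **RDSC block** — depth-wise 3x3 → BN → ReLU → point-wise 1x1 → BN →
  ReLU; residual path is the identity when channels are preserved,
  otherwise a 1x1 channel convolution + BN; paths are summed with no
  post-sum activation. The `use_rdsc=False` variant replaces every block
  with a standard pair (3x3 conv M→N + BN + ReLU, 3x3 conv N→N + BN +
  ReLU) of the same channel plan.

## Width calibration

The published EARDS complexity profile is: 15.44M parameters (4.21G
FLOPs) for the full model, 17.14M/8.51G with standard convolutions, and
15.28M without attention gates; the plain b0 classifier has 5.3M. The
architecture diagram fixes the wiring but not the widths, so the widths
here were calibrated once, analytically, to reproduce the parameter
profile exactly:

- The b0 encoder contributes a fixed 3,595,388 parameters (the same stage
  table with stride-2 stem, 1280-channel top convolution and 1000-way
  classifier counts 5,288,548 → 5.3M, anchoring the parameter-accounting
  conventions).
- The standard-vs-RDSC difference of 1.70M pins the *swappable*
  convolution mass near 0.5M (a standard pair costs roughly 4.5x a DSC of
  the same plan), so reaching 15.44M in total forces ≈11.2M parameters
  into components shared by both variants. The only structural receptacle
  consistent with the profile is a wide 1x1 projection at the bottleneck;
  hence the 320 → 2954 → 3456 bridge.
- Frozen solution: decoder channels (64, 48, 32, 24, 16), attention
  inter-channels (44, 24, 16, 16), bridge (2954, 3456), giving
  15,442,755 / 17,137,883 / 15,280,587 parameters — each rounding to the
  published value — and an attention-gate increment of 0.16M.

**MAC counts cannot be reconciled the same way.** One MAC is counted per
multiply in convolutional/linear layers (normalization, activations and
pooling excluded) — the convention under which b0 at 224x224 measures
0.39G, matching its published figure. At 512x512 with the stride-1 stem
the *encoder alone* costs 7.60G MACs, already above the published 4.21G
total; moreover any model carrying ~11M decoder-side parameters at 1/16
resolution or finer must spend ≥11G MACs on them. The published
parameter and FLOP figures are therefore mutually inconsistent for this
architecture at 512x512, and the profiler reports its honest
measurements (23.19G for the full model, 37.55G for the standard-conv
variant) rather than the published ones. The *direction* of the claim is
reproduced: RDSC removes a large fraction of the MACs, and removing
attention changes parameters by exactly the gates' 0.16M.

## Loss

`L = L_dice + λ·L_focal`, λ = 0.3 (selected by grid search in the
original study), ε = 1e-6, natural logarithms.

- **Soft dice**: per class k, `(2Σ m_k p_k + ε)/(Σ m_k² + Σ p_k² + ε)`
  summed over all pixels of the batch; the loss is 1 minus the mean over
  the K classes. Averaging over classes is a deliberate normalization —
  the un-normalized form (1 minus the *sum*) is negative for a perfect
  multi-class prediction and is available via `normalize=False`.
- **Focal**: per pixel and class,
  `−m α (1−p)^γ log p − (1−m)(1−α) p^γ log(1−p)`, averaged over pixels;
  γ = 2; α = 0.25/0.75/0.75 for background/rim/cup. Probabilities are
  clipped to [ε, 1−ε] before logarithms, keeping gradients finite.
- Both terms are batch-size invariant; with γ=0 and α=1/2 the focal term
  is exactly half the per-class binary cross-entropy.

## Metrics and screening

DC = 2TP/(2TP+FP+FN), JAC = TP/(TP+FP+FN) (so DC = 2·JAC/(1+JAC)),
BA = (Se+Sp)/2, computed per structure after binarizing (disc = rim ∪
cup). Degenerate denominators: a structure empty in both masks scores 1
(with a warning); empty in exactly one scores 0. The vertical diameter
is the inclusive row extent of the mask; CDR = VD_cup/VD_disc, with an
empty cup giving CDR 0 (warning) and an empty disc an error. CE is the
mean absolute CDR difference over a test set. Screening calls glaucoma
when CDR > 0.5 (strict); the ROC is the threshold sweep
(scikit-learn `roc_curve`) and AUC its trapezoidal integral.

## Synthetic data

The generator draws a bright elliptical disc containing a brighter,
offset elliptical cup on a vignetted orange background with Gaussian
noise and dark quadratic-Bezier vessel strokes; the anatomical classes
cover a few percent of a whole-fundus image (background fraction > 0.9),
reproducing the class imbalance the focal loss targets. Ellipse centres
are quantized to integers and semi-axes to half-integers (m + 0.5), so a
vertical semi-axis b rasterizes to exactly 2b rows and the generator's
analytic CDR (ratio of quantized vertical semi-axes) is exact for the
drawn image; the metrics pipeline recovers it within the one-pixel
rasterization bound 1/VD_disc across seeds.

Cohorts (`make_synthetic_dataset`) draw per-eye CDR from U(0.30, 0.45)
for normal and U(0.55, 0.80) for glaucomatous eyes, with two geometry
regimes: `view="fundus"` (disc ~12% of the image height, as in a whole
fundus photograph) and `view="roi"` (disc-centred crop with the disc
filling most of the frame, as in region-of-interest pipelines).

What the generator does **not** emulate: real texture and colour
variability, pathologies, illumination artefacts, soft expert-averaged
boundaries, or the domain shift between cameras. Tests passing on it
establish pipeline correctness and desk-scale learnability, not clinical
segmentation accuracy.

## Training regime and desk-scale sizes

RMSProp (smoothing 0.99, eps 1e-8), initial learning rate 1e-4, batch
size 2, 30 epochs by default; the rate is multiplied by 0.1 when the
validation mean dice ((disc+cup)/2) fails to improve for more than
2 consecutive validated epochs. A single seed drives weight
initialization, shuffling and the synthetic data. Augmentation is the
deterministic 4 flips x 14 translations grid (offsets (0,0), ±16/±32 on
the axes, ±16 diagonals and (32,32)), a 56-fold expansion chosen to
reproduce the published 2,800 pairs from 50 inputs; the enumeration
cannot be made symmetric at exactly 14 offsets and is fixed as listed.

Desk-scale choices (the package's own): the capacity check trains the
narrow `ModelConfig.small()` preset (bridge 96→64, same topology) for
200 steps on four 128x128 ROI-view images and reaches training-set disc
dice > 0.9; the full-width model is exercised by the profiler and by
forward-pass tests at small spatial sizes. Gradient correctness is
established in float64 against central differences (the tape supports a
switchable dtype; float32 is the training default).

## Known limitations

- The wide bottleneck projection exists to satisfy the published
  parameter profile; as a piece of architecture design in isolation it is
  unusually bulky, and a practitioner optimizing for accuracy per FLOP
  would shrink it (and then depart from the published counts).
- Batch-norm inference uses running statistics; evaluation immediately
  after very short training can therefore lag the training-mode
  behaviour.
- The numpy core is single-threaded BLAS-bound; it is meant for
  desk-scale experiments, not GPU-scale training.
- Whether the original model loaded ImageNet-pretrained weights is
  unstated; both modes exist, defaulting to seeded initialization, and no
  claim is made about pretraining effects.
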