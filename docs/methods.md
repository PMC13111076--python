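# Methods

## Problem and model

The package segments hypoechoic thyroid nodules in B-mode ultrasound
frames: given a grayscale image, produce a per-pixel probability that the
pixel belongs to a nodule. The network (RTS-Net) is an encoder–decoder:

* **Encoder** — a four-stage hierarchical vision transformer of the
  PVT-v2-b2 design: overlapping patch embeddings (stride 4, then 2, 2, 2),
  stage depths (3, 4, 6, 3), channels (64, 128, 320, 512), heads
  (1, 2, 5, 8), spatial-reduction attention ratios (8, 4, 2, 1) and
  convolutional MLPs with expansion (8, 8, 4, 4). It emits a feature
  pyramid at strides (4, 8, 16, 32).
* **Decoder** — four cascaded stages, deep to shallow. Each stage runs a
  KNN-graph convolution block, then a serial dual-path attention block,
  taps a one-channel segmentation head, and upsamples with a learned
  block `Conv1x1(ReLU(BN(DWConv3x3(Up2x(·)))))`; the upsampled features
  are fused with the next-shallower skip by a 1×1 channel-matching
  convolution plus addition.
* **Deep supervision** — the four head logit maps are bilinearly
  upsampled to input resolution; the prediction is the sigmoid of their
  mean (sum merging is available by config). Training minimises the
  equal-weight mean of the four heads' Dice losses.

### Graph convolution block

Feature pixels are nodes; adjacency is rebuilt *every forward pass* from
squared Euclidean distances in feature space (k = 9 neighbours per node,
ties broken toward lower node index, rows padded by repeating the last
valid neighbour when fewer than k others exist; optional dilation keeps
every δ-th of the k·δ nearest). The default aggregation is max-relative
convolution — concatenate each node's feature with the elementwise max of
neighbour-minus-centre differences, then a linear 2d→d map — with edge
convolution, GraphSAGE and GIN variants implemented for completeness.
The block is two 1×1-conv → BN → ReLU sandwiches around
`GConv(x) = GELU(BN(DynConv(x)))`, wrapped in a residual (configurable;
residual-free mode reproduces the bare composition). The inner GConv runs
at 1.75× the stage width; this single free width was fixed so that the
assembled full-scale model counts 32.0 M trainable parameters, matching
the published 32.25 M within 2% — the printed count is treated as the
constraint resolving what the architecture description leaves open.

### Dual-path attention

Both paths project Q/K/V with their own 1×1 convolutions, run multi-head
(heads = channels/64, min 1), and sit inside residual additions with a
per-path output projection, so the block is an exact identity at zero
projection weights.

* Spatial path: softmax-factorised ("efficient") attention
  `E = ρ_q(Q) (ρ_k(K)ᵀ V)` with ρ_q a softmax over the key dimension per
  position and ρ_k a softmax over positions per key dimension. The
  dk×dv context is contracted first, so cost is linear in positions; the
  test suite verifies the linear and quadratic association orders agree
  to 1e-5 across random shapes.
* Channel path: channel-transpose attention `C = V · softmax(KᵀQ / r)`
  over the d×d channel covariance, softmax per column, with a learnable
  per-head temperature r (init 1.0). Inside the block, Q and K are
  L2-normalised along the position axis before the covariance — the
  convention of the channel-transpose-attention family — so the
  covariance is bounded and r alone controls sharpness. Without this the
  covariance softmax saturates and SGD at the stated learning rate
  produces gradient spikes of two orders of magnitude in the channel
  projections. The bare `channel_attention` operation is exactly the
  formula above; the normalisation is part of the block's projection
  conditioning.

### Initialisation

Linear layers use truncated-normal (std 0.02), convolutions kaiming
normal with fan-out, biases and norm offsets zero — the hierarchical-
transformer convention. The two deliberate exceptions: segmentation
heads use normal(0, 0.01) (fan-out kaiming is degenerate for a single
output channel and saturates every sigmoid at init), and the channel
attention temperatures start at 1. Drop-path is linearly scaled to 0.1
across encoder depth and disabled in evaluation mode.

## Training protocol

SGD with momentum 0.9 and weight decay 5e-4; initial learning rate 0.01
with per-iteration polynomial decay `lr0 · (1 − t/T)^0.9`; Dice loss
(ε = 1e-6) with equal-weight deep supervision; inputs resized to a fixed
square (224 for the full model), randomly flipped horizontally
(p = 0.5), replicated to three channels and normalised with the ImageNet
statistics (0.485, 0.456, 0.406)/(0.229, 0.224, 0.225). Batch size and
iteration count are not part of the published protocol; defaults are 8
and 20 000 for full-scale runs. One master seed fans out to separate
streams for weight init, data ordering, augmentation and drop-path, so a
run is bit-reproducible single-threaded. The checkpoint kept is the best
validation mean-per-image IoU.

## Metrics

Confusion-count metrics follow IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN), accuracy, precision, recall, and F1 as the
harmonic mean of precision and recall, with the empty-union convention
(a 0/0 metric is 1 iff both masks are empty, else 0). Predictions are
thresholded at 0.5. Two aggregations are reported side by side: the mean
of per-image values and the recomputation from dataset-pooled counts.
Dice = F1 holds exactly for any single confusion vector; reporting
mean-per-image Dice next to pooled-count F1 is the pair under which the
two columns of a benchmark table can differ.

HD95 uses 4-connected boundary pixels (the image border counts as
background), Euclidean distances to the nearest boundary pixel of the
other mask via a distance transform, the maximum of the two directions'
95th percentiles with linear interpolation between order statistics
(HD95 is sensitive to the percentile definition, hence documented). Both
masks empty gives 0; exactly one empty gives the image diagonal
√(H²+W²) as a sentinel. AUC is the rank-based (Mann–Whitney) statistic
with midranks for ties, pooled over all pixels of the evaluated set;
per-image AUC is skipped for single-class images.

## Synthetic phantoms

The generator emulates the features of thyroid B-mode images that drive
segmentation difficulty: bright parenchyma (level 0.55 with a smooth
±0.03 texture field), darker elliptical nodules (rotated ellipses, axes
drawn in [0.8 r, 1.2 r], intensity 0.35 below the surround by default),
fully-developed multiplicative speckle (gamma, mean 1, shape 10 →
relative std ≈ 0.32), and optional posterior acoustic shadowing (a wedge
below the nodule scaled by 0.5, p = 0.2; the mask is unchanged because a
shadow is not a nodule). Intensities are floats in [0, 1], written as
8-bit PNG with round-half-even; masks {0, 255}, binarised at >127 on
read. Coordinates are row-major, origin top-left, 0-based.

What the phantoms do **not** model: beamforming geometry, depth-dependent
attenuation and focus, heterogeneous parenchyma, vessels and other
hypoechoic confounders, operator variability. Passing the phantom
experiments therefore demonstrates that the architecture, losses,
optimisation and evaluation chain are correct and can learn
low-contrast speckled targets — not clinical-grade performance on real
ultrasound.

## Scaled-down experiments

CPU-sized study conditions used by the test suite: the quarter-width
("tiny", width multiplier 0.25) model on 96×96 phantoms — 200 training
and 50 validation images (validation phantoms drawn from a disjoint seed
stream offset by 10 000), 15 epochs of batch 8 (375 iterations), master
seed 0. Success criteria: validation mean-per-image IoU ≥ 0.60 and
above the all-foreground baseline. A single-batch overfit run (4
phantoms, 200 iterations, flips off so the batch is truly fixed) must
drive the fused-prediction Dice loss under 0.1; the deep-supervision
objective itself is floored around 0.12–0.15 at this input size because
the stride-32 head emits only 3×3 logits, so the fused prediction is the
quantity checked. The acceptance script runs a further reduced version
(100/25 images, 12 epochs) to keep its own runtime small; the suite runs
the full conditions.

## Numerical choices

* Softmaxes subtract the running maximum before exponentiation.
* Dice smoothing ε = 1e-6 in the loss; count metrics use exact integers.
* Batch norm: momentum 0.1, ε = 1e-5, biased variance for normalisation,
  unbiased for running stats; node features are normalised per channel
  over (batch, node).
* KNN ties: stable argsort ⇒ lower node index wins, exactly matching the
  brute-force oracle.
* Bilinear resampling uses the half-pixel-centre convention with
  row-stochastic interpolation matrices (so constants are preserved
  exactly), identically in upsampling blocks and head upsampling.
* The compute core is a small reverse-mode autodiff engine over NumPy
  (float32 forward, float64 in gradient checks), written for this
  package and verified against central finite differences; convolution
  backward uses cached sparse col2im scatter matrices.

## Known limitations

* CPU-only and NumPy-based: full-scale (b2) training at 224² is possible
  but slow; the architecture-level checks instantiate it, the learning
  experiments use the tiny variant.
* No pretrained encoder weights are shipped; the import hook accepts a
  name→array mapping but every test property holds at random init.
* Binary segmentation only; no test-time augmentation; no multi-GPU.
* The loss-curve criterion is a median comparison (last vs first 20
  iterations), not monotonicity — SGD noise at these batch sizes makes
  per-iteration monotonicity a meaningless assertion.
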