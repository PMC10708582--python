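# Methods

## Problem and data model

The package classifies short clips of a singly-housed mouse into eight
behavior classes. The atomic sample is a spatiotemporal cuboid: `T` frames of
`H x W x C` pixels, normalized to `[0, 1]`. Under the default preprocessing,
frames are bilinearly resized to 128x128 and center-cropped along the
vertical axis to 96 rows (the cage's redundant margins are symmetric, so 16
rows are removed from the top and 16 from the bottom), the frame sequence is
downsampled at 5-frame intervals, and consecutive non-overlapping 8-frame
windows become cuboids; a window then spans roughly 1.33 s of 30 fps video.
Windows start at frame 0 and the trailing remainder is discarded. The
per-clip label is the majority vote over the per-frame annotations, with
ties broken by the temporally central frame.

Two input streams are derived per cuboid. The **image stream** is the
(optionally *nightified* or grayscale) RGB block. The **flow stream** is
dense optical flow between consecutive frames, estimated with the iterative
Lucas–Kanade solver (`skimage.registration.optical_flow_ilk`, window radius
7 at full resolution, 3 at desk scale) and rendered as an angle/magnitude
HSV color wheel so that both streams share one `T x H x W x 3` geometry (the
last flow field is repeated once to preserve `T`). A raw 2-channel `(dx, dy)`
encoding is available behind a flag. Flow is computed after resize/crop and
appearance normalization, on the downsampled sequence, which keeps the two
streams temporally aligned per cuboid.

**Nightification.** Most recordings are daytime video; a minority are
infrared night recordings. Day frames are normalized to night-like
appearance by `out_c = round(in_c * ref_c / 255)`, where `ref` is the
per-channel arithmetic mean of all night-video pixels. The formula is the
direct reading of "weighting the [0–1]-normalized data and expanding back to
[0–255]"; it is monotone per channel and the identity at `ref = (255, 255,
255)`. Night videos are identified by a manifest flag, not by automatic
detection.

## Architectures

All five models are dual-stream networks over `(rgb, flow)` cuboids ending
in an 8-way softmax. The *feature sharing* variants jointly process the two
streams at every stacked module; the *standalone* variants replicate the
joint blocks inside each stream and merge only before the common
fully-connected (FC) stack (by addition — "late fusion"; the final-merge
operator is not dictated by the design, and addition keeps the FC geometry
identical across variants).

* **baseline** — four primary modules per stream; each is two stacked 3D
  convolutions (`n` then `1.5 n` filters, kernels 5, 3, 5, 5, uniform within
  a block) with batch normalization after each convolution and 20% dropout.
  After each module pair the streams are summed and processed by a
  channel-wise dense layer projecting `1.5 n -> n` channels (+ BN +
  dropout); the joint output feeds both streams' next module. Head: flatten
  (1x3x4x128 = 1536) -> FC 512 -> 64 -> 8.
* **civ3d_mha / civ3d_bilstm** — the same trunk with rising/falling kernels
  (7/5, 5/3, 5/3, 3/1) and the joint dense block replaced by a 3D
  Inception-v3 "block D": branches 1x1x1->3x3x3, 1x1x1->3x3x3->3x3x3 and
  max-pool->1x1x1, concatenated to the input channel count. The MHA model
  adds a residual self-attention block to each stream after the last primary
  module: the 12 end-feature positions are the tokens (d_model = 192),
  batch normalization replaces layer normalization, a learned 1D positional
  embedding is added, and 4 heads of width d_k = 514 are concatenated
  through W_O. The BiLSTM model instead replaces the flatten with a
  bidirectional LSTM (hidden 370 per direction) over the 12 positions and
  removes the primary modules' dropout.
* **srs** (Singly Reinforced Stream) — six 3D Inception-v1 blocks (branches
  1x1x1->3x3x3, 1x1x1->5x5x5, pool->1x1x1; no lone 1x1x1 branch; three
  equal-width branches of `k*n` filters each). Module 1 processes both
  streams at full resolution and concatenates them into a single running
  stream; at each later bottleneck a strided Inception computation of the
  *original* (temporally cropped) flow sequence is concatenated to the
  running features. The flow crop removes the first and last 2 frames once,
  after module 1 (the center 4 of 8 frames carry the most representative
  motion); at T = 4 and T = 16 the crop is 1+1 and 4+4 respectively, which
  leaves the architecture's parameter count unchanged.
* **crs** (Cross Reinforced Streams) — five Inception-v1 modules per stream
  with `k = 1`; each stream's next block consumes the concatenation of the
  jointly-concatenated previous module output and the *other* stream's past
  features, so reinforcement alternates between streams. The final
  1x6x8x1152 tensor is spatially average-pooled to the common 1x3x4 grid
  before the FC stack — the only head arrangement compatible with the
  published parameter total.

**Downsampling schedule.** Inferred from the published per-module output
sizes: baseline/CIv3D module 1 reduces T by 2 and H, W by 4 (strides on the
two convolutions), modules 2–3 reduce all axes by 2, module 4 reduces only
space; SRS/CRS module 1 keeps full resolution and later modules stride by 2,
with temporal striding applied only while T > 1. This schedule also
reproduces two published side facts: baseline complexity grows slightly at
T = 16 (the final temporal extent becomes 2) while SRS complexity is
T-invariant.

**Accounting.** `count_parameters` sums all trainable scalars: convolution
and dense weights and biases, and the scale/shift pair of every batch norm
(running statistics are buffers, not parameters). `count_flops` returns
twice the parameter count — the convention under which the published
complexity figures for the non-recurrent models are reproduced exactly
(e.g. 2 x 11,315,848 = 22.63e6); it is not a per-inference dense-FLOP count,
and the published BiLSTM figure follows a different, unstated convention.
`layer_output_shapes` reports the combined-stream tensor at each stacked
module (the addition/concatenation point), which is the quantity the
published shape table lists; the same shapes are also recorded from real
forward passes (`traced_module_shapes`) and the two agree.

**Width calibration.** The stacked-module table fixes filter counts,
multipliers, kernels and module output sizes, but not the Inception branch
reduction widths, the attention dimensions or the LSTM width. Those free
widths were calibrated once, jointly, so that every published
trainable-parameter total (all five models, sharing and standalone) is
reproduced exactly, and ship as package defaults (`DEFAULT_WIDTHS` plus
`attention_dk = 514`, `lstm_hidden = 370`). Two consequences are worth
stating plainly: some reduction widths exceed their input channel count
(e.g. 1738 at 192 input channels in the last CIv3D joint), and in the
standalone variants the replicated joint convolutions carry no bias — for
the baseline this bias-free reading is what reproduces both published
totals, and it is applied uniformly. The calibration pins total counts, not
the authors' internal layer-by-layer allocation, which is not published.

**Attention scaling.** The attention equation is implemented with the
conventional `1/sqrt(d_k)` score scaling; a `scale="dk"` switch reproduces
the plain `1/d_k` form.

## Training protocol

Class-weighted categorical cross-entropy (`w_k = N / (K n_k)`,
inverse-frequency with mean-one normalization; weights enter the loss, not
the sampler), SGD with momentum 0.9, batch size 8, up to 85 epochs at the
per-model base learning rate (0.0005 baseline, 0.001 others). The learning
rate is halved when validation loss fails to improve by more than 1e-4 for
5 consecutive epochs; training stops after 12 such epochs and the best
checkpoint (parameters plus batch-norm running statistics) is restored.
Four seeds {0, 1, 2, 3} are run and metric means/population-SDs reported.
Patience values and momentum are configuration, not protocol constants, as
the source protocol leaves them unquantified. Training is bitwise
reproducible given (config, seed).

## Metrics and ensembling

`evaluate` computes accuracy (argmax decisions; ties resolve to the lowest
class index), micro-averaged AP over pooled one-vs-rest decisions, macro
precision/recall/F1, micro and macro one-vs-rest AUC (trapezoidal), and the
K x K confusion matrix, all via scikit-learn. "Recall" is macro recall,
consistent with the macro reading of precision. Ensembles average predicted
distributions at inference; seed aggregation reports per-metric mean and
population standard deviation. `loocv_plan` emits the n-fold
leave-one-video-out split plan (fold execution at full scale is a GPU-scale
experiment and out of scope here).

## Synthetic study conditions

The generator renders a textured ellipsoidal "mouse" on a cage-like
backdrop (intensity gradient, vertical bars, bedding speckle — static
high-contrast structure keeps dense flow well posed) and animates one of
eight kinematic programs: drinking and eating are small oscillations at
fixed cage landmarks (left spout / right hopper), grooming is a localized
periodic deformation with a slight body-size oscillation, hanging sits at
the cage lid with a small swing, rearing elongates vertically, walking
translates at 1.5 px/frame, micromovement jitters the body center by 0.5 px
SD, and resting is an immobile pose in the bedding corner. Behaviors thus
differ in both coarse location and motion statistics, as they do in a real
cage. Defaults: 8 classes x 10 clips of 8 x 16 x 16 x 3 at noise SD 0.01,
split 70/15/15 stratified per class; everything is deterministic given the
spec seed.

The CPU-scale ("desk") model configurations quarter the filter widths, use
a 128-32-8 FC stack and per-model base learning rates (0.02, with 0.01 /
0.015 for the attention / BiLSTM models, whose heads condition the
optimization differently), chosen so that every variant memorizes the
80-clip set within 30 epochs on one CPU. What passing these runs shows is
that the implementations train end-to-end — gradients flow through every
block type and the optimization loop, schedule and checkpointing behave as
specified. It does not show real-data performance: the synthetic scenes
lack occlusion, posture ambiguity, annotation noise, day/night appearance
shifts and class imbalance at realistic ratios, and the published full-scale
accuracies require the external video corpus and GPU-scale training.

## Numerical choices

The bundled autograd engine computes in float32; cuboids are float32 in
`[0, 1]`. Convolutions and pooling use SAME (ceil) padding; batch norm uses
eps 1e-3 and running-stat momentum 0.9; dropout masks are drawn from the
model's own seeded generator. Weights initialize He-normal (convolutions)
and Glorot-uniform (dense/recurrent/attention); initialization never enters
the accounting checks, which are shape arithmetic. Loss evaluation uses the
log-sum-exp form on logits. Degenerate inputs are rejected with explicit
errors (empty frames, fewer than two frames for flow, a temporal crop that
would consume the whole flow sequence, non-normalized probability rows,
zero class counts).

## Known limitations

* Video decoding is provided for frame-stack arrays and image sequences;
  container demuxing depends on what imageio can open in the host
  environment and is not exercised by the tests.
* The published standalone parameter totals are reproduced via the
  bias-free replicated-joint reading described above; the authors' exact
  internal widths are unpublished, so per-layer allocations here are one
  consistent solution, not a unique reconstruction.
* The FLOPS figure is an accounting convention (2 x parameters), not a
  measured throughput; the BiLSTM model's published figure is not derivable
  from it.
* Full-scale training (23k+ cuboids, 85 epochs) is far outside one-CPU
  numpy throughput; the package trains real models only at desk scale.
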