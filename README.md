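# cagenet

Dual-stream spatiotemporal neural networks with **feature sharing** for
classifying the behavior of singly-housed mice in their home cage.

Automated behavioral phenotyping from home-cage video is a standard tool in
welfare monitoring and disease-model research: a camera watches one mouse and
every short clip is assigned to one of eight ethogram classes (drink, eat,
groom, hang, micromovement, rear, rest, walk). `cagenet` implements a family
of two-stream 3D convolutional classifiers for this task — one stream sees
the appearance-normalized RGB cuboid, the other a dense-optical-flow
rendering of the same clip — together with the full preprocessing pipeline,
training protocol, evaluation metrics and ensembling. It is aimed at
researchers who want to study the *feature sharing* design itself: instead of
fusing the two streams once at the end ("late fusion"), the streams are
jointly processed at regular intervals throughout the network and the joint
representation is fed back to both streams.

## The models

Each input sample is a spatiotemporal cuboid `T x H x W x C` (default
`8 x 96 x 128 x 3`): frames are resized to 128x128, center-cropped to 96 rows,
temporally downsampled at 5-frame intervals and cut into consecutive 8-frame
windows (~1.33 s of video). Five architectures are provided, each in a
*sharing* and a *standalone* (classical dual-stream) variant:

| model          | primary blocks                  | joint processing             | head        |
|----------------|---------------------------------|------------------------------|-------------|
| `baseline`     | 3D conv pairs (n, 1.5n filters) | add + dense/dropout block    | FC 512-64-8 |
| `civ3d_mha`    | 3D conv pairs, 7/5/5/3 kernels  | 3D Inception-v3 block D      | self-attention + FC |
| `civ3d_bilstm` | as above, no dropout            | 3D Inception-v3 block D      | BiLSTM + FC |
| `srs`          | 3D Inception-v1 blocks          | concat flow taps into one reinforced stream | FC |
| `crs`          | 3D Inception-v1 blocks          | cross-stream concatenation   | FC |

The attention head follows

```
Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V
MHA(Q, K, V)       = Concat(head_1, ..., head_h) W_O
```

with batch normalization in place of layer normalization and the stream's
end features as the token sequence.

Everything runs on a small numpy autograd engine bundled with the package
(`cagenet.nn`): 3D convolution/pooling, batch norm, LSTM and attention with
reverse-mode gradients — no GPU framework required.

## Worked example

Build the best-performing architecture (the Singly Reinforced Stream) and
audit it against the published accounting:

```
$ cagenet build --model srs --inspect
model: srs (sharing)
parameters: 9,671,872
flops: 19.34e6
module 1: 8 x 96 x 128 x 72
module 2: 4 x 48 x 64 x 144
module 3: 2 x 24 x 32 x 288
module 4: 1 x 12 x 16 x 576
module 5: 1 x 6 x 8 x 576
module 6: 1 x 3 x 4 x 384
```

`parameters` is the total trainable-scalar count (weights, biases and norm
parameters); `flops` is twice that count, the convention under which the
published complexity table is reproduced; the module lines are the
`T x H x W x C` sizes of the combined-stream tensor at each stacked module.

Train a CPU-scale variant on synthetic labeled clips and score it:

```
$ cagenet fixtures --clips-per-class 10 --seed 7 --out synth.h5
wrote synth.h5: train=56 val=8 test=16 train_class_counts=[7, 7, 7, 7, 7, 7, 7, 7]
$ cagenet train --model srs --store synth.h5 --epochs 30 --seed 1 --out runs/
final train acc 0.982
$ cagenet evaluate --checkpoint runs/checkpoint_srs_sharing_s1.npz \
      --store synth.h5 --out report.json
accuracy 1.000 -> report.json
```

The report JSON carries accuracy, micro-averaged AP, macro precision /
recall / F1, micro and macro one-vs-rest AUC and the 8x8 confusion matrix.
`cagenet ablate --axis variant|input_kind|temporal_length` runs the matched
sweeps (sharing vs standalone; grayscale / raw / nightified input; T = 4, 8,
16 with the SRS temporal crop scaled accordingly) under identical seeds.

## Layout

- `cagenet.video_io` — decoding, resize/crop, temporal downsampling, cuboid
  assembly, HDF5 cuboid stores
- `cagenet.preprocess` — nightification, grayscale, dense optical flow
- `cagenet.blocks` / `cagenet.architectures` — network blocks and the five
  dual-stream builders with parameter/FLOPS/shape accounting
- `cagenet.training` — class-weighted cross-entropy, SGD, LR-on-plateau,
  early stopping, multi-seed runs
- `cagenet.evaluation` — metrics, ensembling, seed aggregation, n-fold
  leave-one-video-out planning
- `cagenet.synthetic` — the labeled synthetic clip generator
- `cagenet.cli` / `cagenet.ablation` — the `cagenet` command and sweep driver
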