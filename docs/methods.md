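# Methods

## Data model

A sample is a sequence of 3D poses, `coords ∈ ℝ^{T×20×3}`, with T ≥ 3 (the
acceleration stream is a second difference). Joints are numbered 1..20 and
grouped into five parts, each a center plus three members:

| part | center | members |
|------|--------|---------|
| left arm (LA) | 7 | 8, 19, 9 |
| right arm (RA) | 4 | 5, 17, 6 |
| left leg (LL) | 13 | 14, 20, 15 |
| right leg (RL) | 10 | 11, 18, 12 |
| trunk | 1 | 2, 3, 16 |

Only this index arithmetic is normative; the semantic joint names used in
the code (shoulder, elbow, hand, …) are labels of convenience. The hand
joints default to 9 (left) and 6 (right) — the terminal member of each arm
chain — and are configurable on `JointIndexMap`.

Sequences are stored either as CSV (T rows × 60 columns, header
`j01_x … j20_z`) or as an `.npz` container with keys `coords` and
optionally `label`; datasets are described by a JSON manifest
(`n_classes`, `class_names`, `entries` with per-sample path/label/id).

## Feature streams

* **body**: raw coordinates, optionally root-centered at joint 1. By
  default no centering or scale normalization is applied — the network's
  input batch-norm layer absorbs global offset and scale.
* **part** (45/frame): member-minus-center difference vectors in the fixed
  order LA, RA, LL, RL, trunk; translation invariant by construction.
* **joint** (160/frame): distances from all 20 joints to each hand (left
  block then right block), then the unit vectors from each joint to each
  hand. A joint coinciding with a hand gets orientation (0,0,0) (guarded
  division). The hand-pair scope (40 distances) is the default because the
  stream exists to expose hand-versus-body geometry; an all-pairs variant
  (190 distances) is available separately.
* **velocity / acceleration**: first/second finite differences (lengths
  T−1 and T−2), linearly interpolated back to the common length.

All streams are resampled to one configurable length (default 64) before
batching: coordinates are linearly resampled first and spatial features
computed on the resampled frames; motion features are differenced on the
original frames and then resampled. Linear interpolation on a uniform grid
is used throughout — it is exact at the endpoints, idempotent at a fixed
length, and never overshoots per-column bounds.

## Network

**Graph convolution.** One layer per spatial stream:
`f_out = σ(D^{−1/2}(A+I)D^{−1/2} f_in W)`, applied per frame. The body
graph is a 19-edge natural-connectivity spanning tree (part centers to
members, limb centers and trunk members to the trunk center); the part
graph is a 5-node star with the limbs attached to the trunk. Both ship as
JSON package data and are replaceable. Each stream has its own GCN
(16 output channels by default, ReLU); the joint stream bypasses graph
convolution since its features are already relational.

**Temporal streams.** Input batch-norm → kernel-1 projection → four blocks
with channels (32, 64, 128, 256) joined by kernel-1 temporal convolutions →
global average pool → 256-dim embedding. Each block runs two parallel
branches with kernels 3 and 5; branch outputs are summed after per-branch
batch-norm (summation preserves the per-branch weight accounting), with an
identity shortcut (kernel-1 projection when channels change), ReLU and
dropout. Branches are *basic* (plain kernel-k convolutions) or
*bottleneck* (kernel-1 compress to `in/r` → kernel-k at reduced width →
kernel-1 expand). Padding is symmetric ("same"), stride 1, so length is
preserved until the pool; a causal mode is available by flag.

**Parameter accounting.** `count_block_parameters` counts convolution
weights only — no biases, no batch-norm affine terms — matching how such
tables are conventionally computed. For a depth-1 32→32 block with kernels
(3,5): basic 8192; bottleneck 4096 (r=2; branches 1792 + 2304), 1536 (r=4;
704 + 832), 640 (r=8; 304 + 336); ratios 0.5, 0.1875, 0.078125.
`verify_parameter_count` enumerates the arrays of an instantiated block and
must agree exactly. The inter-block kernel-1 convolutions are not part of
the per-block accounting. The stacked-conv receptive field is
`1 + depth·dilation·(kernel−1)`: 7 and 13 frames for a depth-3 stack of
kernels 3 and 5, which is why the stream default is three temporal
convolutions per kernel path (the accounting default is depth 1, the
structure the printed counts describe).

**Attention and fusion.** An attention block maps each stream embedding
through a shared FC (weights shared across streams, as a single W implies)
+ batch-norm + ReLU, stacks the S results, and takes a softmax across the
stream axis per channel; the output concatenates `f_s ⊙ a_s + f_s`. The
weights are non-negative and sum to 1 across streams at every channel, and
the residual keeps gradient flowing to suppressed streams. The channel-wise
max across streams is computed and exposed for inspection; a strict mode
uses the softmax of max-pooled per-stream scalars instead. Two-step fusion
applies the block over the three spatial embeddings and the two temporal
embeddings (early stage; each result is FC-projected to a common width,
default 256 — the projection exists to give the late block same-length
inputs), then over the two branch vectors (late stage, output 512).
`naive_concat` is the single-stage baseline. The classifier head is
dropout → FC → softmax; ties in arg-max resolve to the lowest class index.

## Training

Defaults follow the reference protocol: Adam, learning rate 1e-5, weight
decay 5e-4 (applied to convolution/FC weights only), batch 256, dropout
0.5, 60/10/30 train/val/test split, early stopping on validation accuracy
(patience 20) with best-weight restoration; cross-entropy loss (the
standard choice for a softmax classifier). One integer seed drives split
shuffling, initialization and dropout; with single-threaded BLAS a run is
bit-reproducible.

Desk-scale runs (`desk_train_config` / `desk_model_config`) are the
package's own choice for minute-scale CPU experiments on the synthetic
fixtures: sequence length 32, stream channels (16, 32, 64, 64), bottleneck
r=2, depth-1 branches, dropout 0.1, learning rate 1e-3, batch 32, ≤ 40
epochs. Three measures matter at this scale and are on by default:

* tiny trailing mini-batches are dropped (their batch statistics are noise);
* because a short run performs too few updates for the exponential
  running averages of batch-norm to converge, the statistics are
  recalibrated by a cumulative-average pass over the training features
  before each validation evaluation;
* early-stopping ties on the small validation set break toward lower
  validation loss, so equally accurate but better-calibrated later epochs
  win.

The classifier weights are initialized small (×0.05) so the untrained model
predicts near-uniform probabilities and the starting loss sits at
`ln(n_classes)`.

## Synthetic actions

The generator emulates the *shape* of depth-sensor action corpora: fixed
20-joint skeletons, variable-length sequences (length jitter ±25% around
64 frames), multiple "subjects" via per-sample rigid transforms
(translation ±0.5 m per axis, yaw ±30°), and Gaussian coordinate noise
(default 2% of the 1.6 m template height ≈ 0.032 m). Each class is a set
of raised-cosine motion terms `a·(1−cos(2πft+φ))/2` applied along a unit
direction to one or more parts' member joints (centers follow at one
third): repeated excursions from a standing rest pose, so both the
kinematics and the mean posture carry class signal. The frozen library
covers eight classes (one-arm lift, squat, hammering, walking-in-place,
two-hand carry, overhead wave, kick, bend-over); classes must differ in at
least one (part, frequency) pair, and amplitudes were fixed once against
the separability oracle and then frozen.

`separability_oracle` — nearest-class-centroid classification on
time-averaged part features under a seeded 70/30 split — is the model-free
reference: on the frozen fixtures it reaches ≈ 0.97 (5-class, 500 samples)
and 1.0 (2-class), and a trained network is expected to land within a few
points of it.

What the generator does **not** emulate: biomechanical constraints (bone
lengths drift with noise), inter-subject anthropometric variation,
sensor-specific artifacts (occlusion, joint swaps, jitter correlated in
time), or realistic class overlap. Passing tests on this data demonstrate
that the pipeline learns class-distinct spatio-temporal structure end to
end and that the implementation is internally consistent — not that the
printed accuracies transfer to real capture data, whose benchmark accuracy
is far below saturation.

## Numerical choices and limitations

* All computation is float64 numpy; the autodiff engine covers exactly the
  ops the model needs, and every layer's gradient is tested against central
  finite differences.
* Batch-norm uses eps 1e-5, momentum 0.1; softmax and cross-entropy are
  computed with max-subtraction for stability; zero-length orientation
  vectors are mapped to zero rather than NaN.
* Degenerate inputs are rejected with validation errors: sequences shorter
  than 3 frames, self-loop edges (self-connection enters only through
  A+I), non-divisible bottleneck reductions, split fractions not summing
  to 1, identical class-motion signatures.
* Single-stream models replace the two-branch fusion by one attention
  block over the streams present (S=1 reduces to doubling the embedding).
* Training at the full reference scale (batch 256, lr 1e-5, hundreds of
  epochs, tens of thousands of samples) is supported by the same code but
  is not exercised by the test suite; the engine is single-threaded
  CPU-bound and roughly an order of magnitude slower than a GPU framework
  at equal size.
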