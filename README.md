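# mfnet — multi-stream skeleton-based action recognition

`mfnet` classifies human actions from 3D skeleton sequences (T frames ×
20 joints × xyz), the data produced by RGB-D capture of full-body motion —
for example continuous monitoring of manual work activities, where the pose
stream is far cheaper to store and far less privacy-invasive than video.

The model is a multi-feature fusion network. Each sample is expanded into
five input streams:

* **body** — raw joint coordinates, one node-feature matrix per frame;
* **part** — the skeleton split into five parts (left/right arm, left/right
  leg, trunk); per part the three member-minus-center difference vectors,
  e.g. left arm `concat(s₈−s₇, s₁₉−s₇, s₉−s₇)` (45 values/frame);
* **joint** — hand-centric geometry: Euclidean distance from every joint to
  each hand (JJED) and the unit direction vector to each hand (JJO),
  160 values/frame;
* **velocity / acceleration** — first and second finite differences
  `Vₜ = Pₜ₊₁ − Pₜ`, `Aₜ = Vₜ₊₁ − Vₜ`, linearly interpolated back to the
  common sequence length.

Spatial streams pass a graph convolution
`f_out = σ(D^{−1/2}(A+I)D^{−1/2} f_in W)` over the skeleton (body) or part
graph. Every stream then runs through its own temporal-convolution stack:
four blocks with output channels (32, 64, 128, 256), each block holding two
parallel temporal branches with kernel sizes 3 and 5 (receptive fields 7
and 13 over a depth-3 stack) in either *basic* or *bottleneck* form — the
bottleneck compresses channels by a reduction rate r with kernel-1
convolutions, cutting a 32→32 block from 8192 to 4096 (r=2), 1536 (r=4) or
640 (r=8) weights. Stream embeddings are combined by branch-wise attention
(channel-wise softmax across streams with a residual connection) in two
steps — within the spatial branch, within the temporal branch, then across
the two branches — and a dropout + FC + softmax head yields class
probabilities.

The network, including a small reverse-mode autodiff engine it trains with,
is implemented in numpy. A synthetic-action generator
(`mfnet.synthetic_actions`) produces labeled 20-joint sequences with
class-distinct kinematics so the entire pipeline trains and evaluates in
minutes on one CPU.

## Worked example

```python
import numpy as np
from mfnet import (build_mfnet, generate, separability_oracle,
                   count_block_parameters, BlockConfig, receptive_field)
from mfnet.model_training import (desk_model_config, desk_train_config,
                                  evaluate_split, train)
from mfnet.synthetic_actions import five_class_spec

print("basic 32->32 block weights:",
      count_block_parameters(BlockConfig(32, 32, structure="basic")))
print("bottleneck r=2 weights:   ",
      count_block_parameters(BlockConfig(32, 32, structure="bottleneck",
                                         reduction=2)))
print("receptive fields (depth 3):",
      receptive_field(3, 3), "and", receptive_field(3, 5), "frames")

sequences, manifest = generate(five_class_spec(seed=3))   # 500 samples
labels = manifest.labels()
print("oracle accuracy:", round(separability_oracle(sequences, labels,
                                                    seed=3), 3))

model = build_mfnet(5, desk_model_config(5), seed=3)
model, history, splits = train(model, sequences, labels,
                               desk_train_config(seed=3, max_epochs=40))
report = evaluate_split(model, sequences, labels, splits[2])
print("test accuracy:", round(report.accuracy, 3),
      " macro F1:", round(report.macro_f1, 3))
```

prints (a few minutes on one CPU):

```
basic 32->32 block weights: 8192
bottleneck r=2 weights:    4096
receptive fields (depth 3): 7 and 13 frames
oracle accuracy: 0.973
test accuracy: 1.0  macro F1: 1.0
```

The first three lines are exact architecture facts: the weight count of one
dual-kernel block before and after the bottleneck substitution, and the
temporal extent each kernel path can see. The oracle line is a model-free
nearest-centroid baseline on time-averaged part features — a lower bound
any trained model should approach. The last line is the trained five-stream
network's held-out accuracy on the 5-class synthetic fixture.

## Command line

```sh
mfnet synth   --spec spec.yaml --out data/        # generate a dataset
mfnet extract --manifest data/manifest.json --out feats/
mfnet params                                      # parameter-count table
mfnet train   --manifest data/manifest.json --config train.yaml --out run/
mfnet eval    --model run/best_model.pkl --manifest data/manifest.json
mfnet predict --model run/best_model.pkl --sequence data/c00_s0000.npz
```

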