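"""MF-Net assembly, training loop and evaluation.

The full model runs five parallel streams — body, part and joint features
through the spatial branch (body and part first pass a one-layer graph
convolution over the skeleton and part graphs; joint features are already
relational), velocity and acceleration through the temporal branch — each
into its own dual-kernel temporal-convolution stream ending in a pooled
embedding.  The embeddings are combined by the two-step attention fusion
(or the naive-concatenation baseline), and a dropout + fully connected +
softmax head yields class probabilities.

Training follows the usual protocol for this model family: Adam with weight
decay, cross-entropy loss, batch normalization, dropout 0.5, and early
stopping on validation accuracy with best-weight restoration.  One integer
seed drives the split shuffling, parameter initialization and dropout, so a
run is bit-reproducible on a fixed platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from . import nn
from .attention_fusion import StreamAttention, TwoStepFusion
from .feature_streams import (JOINT_DIM, STREAM_NAMES, ExtractConfig,
                              extract_all)
from .graph_conv import GraphConv, body_graph, part_graph
from .skeleton_core import ValidationError
from .tcn_backbone import StreamConfig, StreamNet

SPATIAL_STREAMS = ("body", "part", "joint")
TEMPORAL_STREAMS = ("velocity", "acceleration")


@dataclass
class TrainConfig:
    """Training protocol; defaults follow the reference protocol (Adam,
    lr 1e-5, weight decay 5e-4, batch 256, dropout 0.5, 60/10/30 split).

    Desk-scale runs on small synthetic sets should lower ``batch_size`` and
    raise ``learning_rate`` (see :func:`desk_train_config`).
    """

    learning_rate: float = 1e-5
    weight_decay: float = 5e-4
    batch_size: int = 256
    dropout: float = 0.5
    max_epochs: int = 500
    early_stopping_patience: int = 20
    seed: int = 0
    train_frac: float = 0.6
    val_frac: float = 0.1
    test_frac: float = 0.3

    def __post_init__(self):
        if not np.isclose(self.train_frac + self.val_frac + self.test_frac,
                          1.0):
            raise ValidationError("split fractions must sum to 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


def desk_train_config(seed: int = 0, max_epochs: int = 40) -> TrainConfig:
    """Desk-scale protocol for small synthetic datasets."""
    return TrainConfig(learning_rate=1e-3, batch_size=32,
                       max_epochs=max_epochs, early_stopping_patience=10,
                       seed=seed)


@dataclass
class ModelConfig:
    """Architecture hyper-parameters of the assembled network."""

    n_classes: int
    streams: tuple = STREAM_NAMES
    sequence_length: int = 64
    gcn_channels: int = 16
    block_channels: tuple = (32, 64, 128, 256)
    kernel_sizes: tuple = (3, 5)
    structure: str = "bottleneck"
    reduction: int = 2
    temporal_conv_depth: int = 3
    fusion: str = "two_step"            # "two_step" | "naive"
    attention_mode: str = "channel"
    dropout: float = 0.5

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        unknown = set(self.streams) - set(STREAM_NAMES)
        if unknown:
            raise ValidationError(f"unknown streams {sorted(unknown)}")
        if not self.streams:
            raise ValidationError("need at least one stream")
        if self.fusion not in ("two_step", "naive"):
            raise ValidationError(f"unknown fusion {self.fusion!r}")


def desk_model_config(n_classes: int, **overrides) -> ModelConfig:
    """Scaled-down architecture for CPU desk runs: shorter sequences,
    narrower blocks, depth-1 branches.  Same topology as the default."""
    kwargs = dict(n_classes=n_classes, sequence_length=32,
                  gcn_channels=8, block_channels=(16, 32, 64, 64),
                  temporal_conv_depth=1, dropout=0.1)
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


class MFNet(nn.Module):
    """The multi-stream fusion network."""

    def __init__(self, cfg: ModelConfig, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.cfg = cfg
        C = cfg.block_channels[-1]
        self.gcn = {}
        input_dims = {
            "body": 20 * cfg.gcn_channels,
            "part": 5 * cfg.gcn_channels,
            "joint": JOINT_DIM,
            "velocity": 60,
            "acceleration": 60,
        }
        if "body" in cfg.streams:
            self.body_gcn = GraphConv(body_graph(), 3, cfg.gcn_channels, rng)
        if "part" in cfg.streams:
            self.part_gcn = GraphConv(part_graph(), 9, cfg.gcn_channels, rng)
        self.streams = list(cfg.streams)
        self.stream_nets = [
            StreamNet(StreamConfig(
                input_dim=input_dims[name],
                block_channels=cfg.block_channels,
                kernel_sizes=cfg.kernel_sizes,
                structure=cfg.structure,
                reduction=cfg.reduction,
                temporal_conv_depth=cfg.temporal_conv_depth,
                dropout=cfg.dropout), rng)
            for name in self.streams]
        spatial = [s for s in self.streams if s in SPATIAL_STREAMS]
        temporal = [s for s in self.streams if s in TEMPORAL_STREAMS]
        self._spatial, self._temporal = spatial, temporal
        if cfg.fusion == "naive" or len(self.streams) == 1:
            fused_dim = C * len(self.streams)
            self.fuser = None
        elif spatial and temporal:
            self.fuser = TwoStepFusion(C, rng, mode=cfg.attention_mode)
            fused_dim = self.fuser.output_dim
            # the early-stage blocks expect exactly 3 + 2 streams
            self.fuser.spatial_attn.n_streams = len(spatial)
            self.fuser.temporal_attn.n_streams = len(temporal)
            self.fuser.spatial_proj = nn.Linear(len(spatial) * C, C, rng,
                                                bias=False)
            self.fuser.temporal_proj = nn.Linear(len(temporal) * C, C, rng,
                                                 bias=False)
        else:
            # single-branch model: one attention block over what is present
            self.fuser = StreamAttention(C, len(self.streams), rng,
                                         cfg.attention_mode)
            fused_dim = C * len(self.streams)
        self.fused_dim = fused_dim
        self.head_dropout = nn.Dropout(cfg.dropout, rng)
        self.classifier = nn.Linear(fused_dim, cfg.n_classes, rng, bias=True)
        # small head init: the untrained model predicts near-uniform
        # probabilities, so the starting loss sits at ln(n_classes)
        self.classifier.W.data *= 0.05

    def _stream_inputs(self, batch: dict) -> list:
        """Per-stream (B, T, D) tensors from raw stream arrays."""
        out = []
        for name in self.streams:
            x = nn.Tensor(batch[name])
            B, T = x.data.shape[:2]
            if name == "body":
                x = self.body_gcn(x)              # (B,T,20,C)
                x = x.reshape(B, T, -1)
            elif name == "part":
                x = self.part_gcn(x)
                x = x.reshape(B, T, -1)
            elif name in TEMPORAL_STREAMS:
                x = x.reshape(B, T, -1)
            out.append(x)
        return out

    def embeddings(self, batch: dict) -> list:
        return [net(x) for net, x in
                zip(self.stream_nets, self._stream_inputs(batch))]

    def logits(self, batch: dict) -> nn.Tensor:
        embs = dict(zip(self.streams, self.embeddings(batch)))
        if self.fuser is None:
            fused = nn.concat([embs[s] for s in self.streams], axis=-1)
        elif isinstance(self.fuser, TwoStepFusion):
            fused = self.fuser([embs[s] for s in self._spatial],
                               [embs[s] for s in self._temporal])
        else:
            fused = self.fuser([embs[s] for s in self.streams])
        return self.classifier(self.head_dropout(fused))

    def forward(self, batch: dict) -> np.ndarray:
        """Class probabilities, rows summing to 1."""
        return nn.softmax(self.logits(batch), axis=-1).data

    def predict(self, batch: dict) -> np.ndarray:
        """Arg-max class ids; exact ties resolve to the lowest index."""
        return np.argmax(self.forward(batch), axis=-1)


def build_mfnet(n_classes: int, model_config: ModelConfig | None = None,
                seed: int = 0) -> MFNet:
    cfg = model_config or ModelConfig(n_classes=n_classes)
    if cfg.n_classes != n_classes:
        raise ValidationError("model_config.n_classes mismatch")
    return MFNet(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# data plumbing


def prepare_features(sequences, length: int) -> dict:
    """Stack per-sample stream arrays: name -> (n_samples, T, ...)."""
    cfg = ExtractConfig(length=length)
    stacks = {name: [] for name in STREAM_NAMES}
    for seq in sequences:
        for fs in extract_all(seq, cfg):
            stacks[fs.name].append(fs.values)
    return {name: np.stack(vals) for name, vals in stacks.items()}


def split_indices(n: int, cfg: TrainConfig, labels=None):
    """Seeded shuffled train/val/test index split."""
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    n_train = int(round(cfg.train_frac * n))
    n_val = int(round(cfg.val_frac * n))
    tr = order[:n_train]
    va = order[n_train:n_train + n_val]
    te = order[n_train + n_val:]
    if min(len(tr), len(va), len(te)) == 0:
        raise ValidationError("a split is empty; dataset too small")
    return tr, va, te


def _take(features: dict, idx) -> dict:
    return {k: v[idx] for k, v in features.items()}


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    best_epoch: int = -1


def recalibrate_bn(model: MFNet, features: dict, batch_size: int = 256):
    """Recompute batch-norm running statistics over a reference set.

    Short desk-scale runs perform far too few updates for the exponential
    running averages to converge, which makes evaluation-mode inference
    unreliable; a calibration pass (cumulative average of batch statistics,
    dropout disabled, no parameter updates) fixes the estimates.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm)]
    if not bns:
        return
    drops = [m for m in model.modules() if isinstance(m, nn.Dropout)]
    saved = [d.p for d in drops]
    for d in drops:
        d.p = 0.0
    model.train()
    for bn in bns:
        bn.running_mean = np.zeros_like(bn.running_mean)
        bn.running_var = np.zeros_like(bn.running_var)
    n = next(iter(features.values())).shape[0]
    for count, lo in enumerate(range(0, n, batch_size), start=1):
        for bn in bns:
            bn.momentum = 1.0 / count
        model.logits(_take(features, slice(lo, lo + batch_size)))
    for bn in bns:
        bn.momentum = 0.1
    for d, p in zip(drops, saved):
        d.p = p


def _epoch_eval(model: MFNet, features: dict, labels: np.ndarray,
                batch_size: int = 256):
    model.eval()
    n = len(labels)
    losses, correct = [], 0
    for lo in range(0, n, batch_size):
        idx = slice(lo, lo + batch_size)
        logits = model.logits(_take(features, idx))
        loss = nn.cross_entropy(logits, labels[idx])
        losses.append(loss.data * (min(n, lo + batch_size) - lo))
        correct += int((np.argmax(logits.data, axis=1)
                        == labels[idx]).sum())
    model.train()
    return float(np.sum(losses) / n), correct / n


def train(model: MFNet, sequences, labels, cfg: TrainConfig | None = None,
          verbose: bool = False):
    """Fit the model on labeled sequences; returns (model, history, splits).

    Features are extracted once up front; the seeded split, mini-batch
    shuffling, initialization and dropout make the run reproducible.
    Early stopping watches validation accuracy and restores the best
    weights.
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, dtype=int)
    if len(sequences) == 0:
        raise ValidationError("empty dataset")
    features = prepare_features(sequences, model.cfg.sequence_length)
    tr, va, te = split_indices(len(labels), cfg, labels)
    f_tr, y_tr = _take(features, tr), labels[tr]
    f_va, y_va = _take(features, va), labels[va]

    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_acc, best_loss, best_state, patience = -1.0, np.inf, None, 0
    model.train()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(y_tr))
        ep_loss, ep_correct, ep_seen = 0.0, 0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            # drop a tiny trailing batch: its batch-norm statistics are
            # noise and would pollute the running averages
            if lo > 0 and len(idx) < max(2, cfg.batch_size // 4):
                continue
            if len(idx) < 2:
                continue
            logits = model.logits(_take(f_tr, idx))
            loss = nn.cross_entropy(logits, y_tr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.data * len(idx)
            ep_correct += int((np.argmax(logits.data, axis=1)
                               == y_tr[idx]).sum())
            ep_seen += len(idx)
        history.train_loss.append(float(ep_loss / ep_seen))
        history.train_acc.append(ep_correct / ep_seen)
        recalibrate_bn(model, f_tr)
        val_loss, val_acc = _epoch_eval(model, f_va, y_va)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        if verbose:
            print(f"epoch {epoch:3d}  train loss {history.train_loss[-1]:.4f}"
                  f"  acc {history.train_acc[-1]:.3f}"
                  f"  val loss {val_loss:.4f}  acc {val_acc:.3f}")
        # ties on the (small) validation accuracy break toward lower loss,
        # so equally accurate but more confident later epochs win
        if val_acc > best_acc or (val_acc == best_acc
                                  and val_loss < best_loss):
            best_acc, best_loss, patience = val_acc, val_loss, 0
            best_state = [a.copy() for a in model.state_arrays()]
            history.best_epoch = epoch
        else:
            patience += 1
            if patience >= cfg.early_stopping_patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, history, (tr, va, te)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    accuracy: float
    precision: list
    recall: list
    f1: list
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: list
    missing_classes: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls(**json.loads(text))


def evaluate(model: MFNet, features: dict, labels: np.ndarray) -> EvalReport:
    """Confusion-matrix metrics on a feature split; macro averages are
    unweighted class means.  Classes absent from the split score 0 and are
    listed in ``missing_classes``."""
    labels = np.asarray(labels, dtype=int)
    n_classes = model.cfg.n_classes
    preds = []
    for lo in range(0, len(labels), 256):
        preds.append(model.predict(_take(features, slice(lo, lo + 256))))
    preds = np.concatenate(preds)
    classes = np.arange(n_classes)
    prec, rec, f1, _ = precision_recall_fscore_support(
        labels, preds, labels=classes, zero_division=0)
    cm = confusion_matrix(labels, preds, labels=classes)
    missing = [int(c) for c in classes if (labels == c).sum() == 0]
    return EvalReport(
        accuracy=float((preds == labels).mean()),
        precision=prec.tolist(), recall=rec.tolist(), f1=f1.tolist(),
        macro_precision=float(prec.mean()), macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()), confusion=cm.tolist(),
        missing_classes=missing)


def evaluate_split(model: MFNet, sequences, labels, idx) -> EvalReport:
    feats = prepare_features([sequences[i] for i in idx],
                             model.cfg.sequence_length)
    return evaluate(model, feats, np.asarray(labels, dtype=int)[idx])
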