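"""Branch-wise stream attention and the two-step fusion strategy.

The attention block weighs parallel feature streams channel by channel.
Each stream embedding ``f_s`` (length C) passes through a shared FC +
batch-norm + ReLU; the S transformed vectors are stacked and a softmax
across the *stream* axis yields non-negative weights ``a_{s,c}`` with
``sum_s a_{s,c} = 1`` for every channel c.  The block output concatenates
the residually re-weighted streams::

    out = concat_s( f_s * a_s + f_s )

so every stream keeps a gradient path even when its weight collapses.
A strict mode replaces the channel-wise weights by the softmax of each
stream's max-pooled scalar response (one weight per stream).

Two-step fusion applies the block three times: once over the three spatial
streams (body, part, joint) and once over the two temporal streams
(velocity, acceleration) — the early stage, each followed by an FC
projection to a common width — then once over the two branch vectors (the
late stage).  ``naive_concat`` is the plain-concatenation baseline.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .skeleton_core import ValidationError


class StreamAttention(nn.Module):
    """Attention over ``n_streams`` embeddings of common width ``channels``.

    ``mode='channel'`` (default): softmax across streams per channel.
    ``mode='max'``: one softmax weight per stream from its max-pooled score.
    The weights of the latest forward pass are kept in ``last_weights``
    (and the channel-wise max across streams in ``last_max``) for
    diagnostics.
    """

    def __init__(self, channels: int, n_streams: int, rng, mode="channel"):
        if n_streams < 1:
            raise ValidationError("need at least one stream")
        if mode not in ("channel", "max"):
            raise ValidationError(f"unknown attention mode {mode!r}")
        self.channels = channels
        self.n_streams = n_streams
        self.mode = mode
        self.fc = nn.Linear(channels, channels, rng, bias=False)
        self.bn = nn.BatchNorm(channels)
        self.last_weights = None
        self.last_max = None

    def forward(self, features: list) -> nn.Tensor:
        if len(features) != self.n_streams:
            raise ValidationError(
                f"expected {self.n_streams} streams, got {len(features)}")
        for f in features:
            if f.data.shape[-1] != self.channels:
                raise ValidationError(
                    f"stream width {f.data.shape[-1]} != {self.channels}")
        scores = [self.bn(self.fc(f)).relu() for f in features]
        g = nn.stack(scores, axis=-2)             # (..., S, C)
        self.last_max = g.data.max(axis=-2)
        if self.mode == "channel":
            a = nn.softmax(g, axis=-2)            # weights per channel
        else:
            pooled = g.max(axis=-1, keepdims=True)   # (..., S, 1)
            a = nn.softmax(pooled, axis=-2)
        self.last_weights = a.data
        weighted = [f * _take_stream(a, s) + f
                    for s, f in enumerate(features)]
        return nn.concat(weighted, axis=-1)


def _take_stream(a: nn.Tensor, s: int) -> nn.Tensor:
    """Slice stream ``s`` from the stacked weight tensor (..., S, C)."""
    data = a.data[..., s, :]

    def back(g):
        full = np.zeros_like(a.data)
        full[..., s, :] = g
        return (full,)

    return nn.Tensor._make(data, (a,), back)


def stream_attention(features, block: StreamAttention) -> np.ndarray:
    """Functional entry point: numpy vectors in, fused numpy vector out.

    Runs the block in evaluation mode (frozen batch-norm statistics) on a
    single sample; output length is ``n_streams * channels``.
    """
    was_training = block.training
    block.eval()
    out = block([nn.Tensor(np.asarray(f, dtype=np.float64).reshape(1, -1))
                 for f in features])
    block.train(was_training)
    return out.data[0]


class TwoStepFusion(nn.Module):
    """Early attention within the spatial and temporal branches, FC
    projections to a common width, then late attention across branches.

    Default widths: 3 spatial embeddings (C each) -> 3C -> C; 2 temporal
    embeddings -> 2C -> C; late stage over the two C-wide branch vectors
    -> fused vector of width 2C.
    """

    def __init__(self, channels: int, rng, projection_dim: int | None = None,
                 mode="channel"):
        C = channels
        P = projection_dim or C
        self.spatial_attn = StreamAttention(C, 3, rng, mode)
        self.temporal_attn = StreamAttention(C, 2, rng, mode)
        self.spatial_proj = nn.Linear(3 * C, P, rng, bias=False)
        self.temporal_proj = nn.Linear(2 * C, P, rng, bias=False)
        self.late_attn = StreamAttention(P, 2, rng, mode)
        self.output_dim = 2 * P

    def forward(self, spatial: list, temporal: list) -> nn.Tensor:
        sp = self.spatial_proj(self.spatial_attn(spatial)).relu()
        tp = self.temporal_proj(self.temporal_attn(temporal)).relu()
        return self.late_attn([sp, tp])


def two_step_fuse(spatial, temporal, fusion: TwoStepFusion) -> np.ndarray:
    """Functional two-step fusion of 3 spatial + 2 temporal embeddings."""
    if len(spatial) != 3 or len(temporal) != 2:
        raise ValidationError("expects 3 spatial and 2 temporal embeddings")
    was_training = fusion.training
    fusion.eval()
    out = fusion(
        [nn.Tensor(np.asarray(f, dtype=np.float64).reshape(1, -1))
         for f in spatial],
        [nn.Tensor(np.asarray(f, dtype=np.float64).reshape(1, -1))
         for f in temporal])
    fusion.train(was_training)
    return out.data[0]


def naive_concat(features) -> np.ndarray:
    """Plain feature-level concatenation (the fusion baseline)."""
    features = [np.asarray(f, dtype=np.float64) for f in features]
    if not features:
        raise ValidationError("need at least one feature vector")
    return np.concatenate(features, axis=-1)


def attention_diagnostics(block: StreamAttention) -> dict:
    """JSON-serializable snapshot of the latest attention weights."""
    if block.last_weights is None:
        return {"weights": None, "max": None}
    return {"weights": np.asarray(block.last_weights).tolist(),
            "max": np.asarray(block.last_max).tolist()}
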