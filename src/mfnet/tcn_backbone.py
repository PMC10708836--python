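"""Dual-kernel temporal-convolution streams with a bottleneck option.

One stream is the temporal half of the network: an input batch-norm, a
kernel-1 projection, and four blocks B1..B4 with output channels
(32, 64, 128, 256) joined by kernel-1 temporal convolutions, followed by a
global average pool to a fixed-width embedding.  Each block runs two
parallel temporal branches with kernel sizes 3 and 5 (two receptive-field
scales) whose outputs are summed after per-branch batch normalization, plus
an identity (or kernel-1 projected) shortcut.

A branch is either *basic* — plain kernel-``k`` convolutions — or a
*bottleneck*: a kernel-1 compression to ``in/r`` channels, the kernel-``k``
convolution(s) at the reduced width, and a kernel-1 expansion back, cutting
the weight count by roughly the reduction rate ``r``.

``count_block_parameters`` is the analytic weight count of one block
(convolution weights only — biases and batch-norm affine terms excluded),
and ``verify_parameter_count`` is its oracle on an instantiated module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .skeleton_core import ValidationError


@dataclass
class BlockConfig:
    in_channels: int
    out_channels: int
    kernel_sizes: tuple = (3, 5)
    structure: str = "basic"           # "basic" | "bottleneck"
    reduction: int = 1                 # bottleneck channel reduction rate r
    temporal_depth: int = 1            # stacked kernel-k convs per branch
    use_bias: bool = False
    dropout: float = 0.0

    def __post_init__(self):
        if self.structure not in ("basic", "bottleneck"):
            raise ValidationError(f"unknown structure {self.structure!r}")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValidationError("kernel sizes must be odd")
        if self.structure == "bottleneck":
            if self.reduction < 1:
                raise ValidationError("reduction rate must be >= 1")
            if self.in_channels % self.reduction:
                raise ValidationError(
                    f"in_channels {self.in_channels} not divisible by "
                    f"reduction rate {self.reduction}")
        if self.temporal_depth < 1:
            raise ValidationError("temporal_depth must be >= 1")

    @property
    def mid_channels(self) -> int:
        return self.in_channels // self.reduction


@dataclass
class StreamConfig:
    """One full stream: projection, four blocks, pooled embedding."""

    input_dim: int
    block_channels: tuple = (32, 64, 128, 256)
    kernel_sizes: tuple = (3, 5)
    structure: str = "bottleneck"
    reduction: int = 2
    temporal_conv_depth: int = 3
    inter_block_kernel: int = 1
    dropout: float = 0.5
    padding: str = "same"              # "same" | "causal"

    def __post_init__(self):
        if len(self.block_channels) != 4:
            raise ValidationError("a stream has exactly four blocks")
        if any(b < a for a, b in zip(self.block_channels,
                                     self.block_channels[1:])):
            raise ValidationError("block channels must be non-decreasing")

    @property
    def embedding_dim(self) -> int:
        return self.block_channels[-1]

    def block_configs(self) -> list:
        return [BlockConfig(in_channels=c, out_channels=c,
                            kernel_sizes=self.kernel_sizes,
                            structure=self.structure,
                            reduction=self.reduction if
                            self.structure == "bottleneck" else 1,
                            temporal_depth=self.temporal_conv_depth,
                            dropout=self.dropout)
                for c in self.block_channels]


def count_block_parameters(cfg: BlockConfig) -> int:
    """Analytic learnable-weight count of one block.

    Counts convolution weights only (``use_bias`` must be off; biases and
    batch-norm affine parameters are excluded from this accounting).  For a
    depth-1 block:

    * basic:      sum over kernels k of  in * out * k
    * bottleneck: sum over kernels k of  in*(in/r)*1 + (in/r)^2*k + (in/r)*out*1

    Deeper branches repeat the kernel-k convolution ``temporal_depth`` times
    at the branch width.  A kernel-1 shortcut projection is added when the
    channel count changes.
    """
    if cfg.use_bias:
        raise ValidationError(
            "analytic accounting assumes bias-free convolutions")
    total = 0
    for k in cfg.kernel_sizes:
        if cfg.structure == "basic":
            total += cfg.in_channels * cfg.out_channels * k
            total += (cfg.temporal_depth - 1) * cfg.out_channels ** 2 * k
        else:
            mid = cfg.mid_channels
            total += cfg.in_channels * mid          # kernel-1 compression
            total += cfg.temporal_depth * mid * mid * k
            total += mid * cfg.out_channels         # kernel-1 expansion
    if cfg.in_channels != cfg.out_channels:
        total += cfg.in_channels * cfg.out_channels  # shortcut projection
    return total


def count_branch_parameters(cfg: BlockConfig, kernel: int) -> int:
    """Weight count of a single kernel-``kernel`` branch of the block."""
    sub = BlockConfig(**{**cfg.__dict__, "kernel_sizes": (kernel,)})
    n = count_block_parameters(sub)
    if cfg.in_channels != cfg.out_channels:
        n -= cfg.in_channels * cfg.out_channels
    return n


def parameter_ratio(cfg_bottleneck: BlockConfig, cfg_basic: BlockConfig
                    ) -> float:
    """Bottleneck-to-basic weight ratio for matched channels and kernels."""
    if (cfg_bottleneck.in_channels, cfg_bottleneck.out_channels,
            cfg_bottleneck.kernel_sizes) != (
            cfg_basic.in_channels, cfg_basic.out_channels,
            cfg_basic.kernel_sizes):
        raise ValidationError("configs must share channels and kernels")
    return count_block_parameters(cfg_bottleneck) / count_block_parameters(
        cfg_basic)


def receptive_field(depth: int, kernel: int, dilation: int = 1) -> int:
    """Temporal receptive field of ``depth`` stacked stride-1 convolutions:
    ``1 + depth * dilation * (kernel - 1)`` frames."""
    if depth < 1 or kernel < 1:
        raise ValidationError("depth and kernel must be >= 1")
    return 1 + depth * dilation * (kernel - 1)


def verify_parameter_count(module: nn.Module, include_bias: bool = True
                           ) -> int:
    """Total element count of a module's learnable conv/FC arrays.

    Batch-norm affine parameters are excluded so bias-free modules are
    directly comparable with :func:`count_block_parameters`.
    """
    kinds = ("weight", "bias") if include_bias else ("weight",)
    return sum(p.data.size for p in module.parameters()
               if getattr(p, "kind", "weight") in kinds)


class _Branch(nn.Module):
    """One kernel-k temporal branch (basic or bottleneck)."""

    def __init__(self, cfg: BlockConfig, kernel: int, rng, padding="same"):
        layers = []
        if cfg.structure == "basic":
            c = cfg.in_channels
            for d in range(cfg.temporal_depth):
                out = cfg.out_channels
                layers += [nn.Conv1d(c, out, kernel, rng, bias=cfg.use_bias,
                                     padding=padding),
                           nn.BatchNorm(out), nn.ReLU()]
                c = out
        else:
            mid = cfg.mid_channels
            layers += [nn.Conv1d(cfg.in_channels, mid, 1, rng,
                                 bias=cfg.use_bias), nn.BatchNorm(mid),
                       nn.ReLU()]
            for _ in range(cfg.temporal_depth):
                layers += [nn.Conv1d(mid, mid, kernel, rng,
                                     bias=cfg.use_bias, padding=padding),
                           nn.BatchNorm(mid), nn.ReLU()]
            layers += [nn.Conv1d(mid, cfg.out_channels, 1, rng,
                                 bias=cfg.use_bias),
                       nn.BatchNorm(cfg.out_channels)]
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net(x)


class TemporalBlock(nn.Module):
    """Dual-kernel residual temporal block: branch sum + shortcut, ReLU,
    dropout."""

    def __init__(self, cfg: BlockConfig, rng, padding="same"):
        self.cfg = cfg
        self.branches = [_Branch(cfg, k, rng, padding)
                         for k in cfg.kernel_sizes]
        self.shortcut = None
        if cfg.in_channels != cfg.out_channels:
            self.shortcut = nn.Conv1d(cfg.in_channels, cfg.out_channels, 1,
                                      rng, bias=False)
        self.dropout = nn.Dropout(cfg.dropout, rng) if cfg.dropout else None

    def forward(self, x):
        out = self.branches[0](x)
        for br in self.branches[1:]:
            out = out + br(x)
        res = self.shortcut(x) if self.shortcut is not None else x
        out = (out + res).relu()
        if self.dropout is not None:
            out = self.dropout(out)
        return out


class StreamNet(nn.Module):
    """Input BN -> kernel-1 projection -> B1..B4 (kernel-1 transitions) ->
    global temporal average pool -> embedding of width ``block_channels[-1]``.

    Forward maps (B, T, input_dim) -> (B, embedding_dim); temporal length is
    preserved until the final pool.
    """

    def __init__(self, cfg: StreamConfig, rng):
        self.cfg = cfg
        ch = cfg.block_channels
        self.input_bn = nn.BatchNorm(cfg.input_dim)
        self.input_proj = nn.Conv1d(cfg.input_dim, ch[0],
                                    cfg.inter_block_kernel, rng, bias=False)
        self.blocks, self.transitions = [], []
        for i, bc in enumerate(cfg.block_configs()):
            self.blocks.append(TemporalBlock(bc, rng, cfg.padding))
            if i < 3:
                self.transitions.append(
                    nn.Conv1d(ch[i], ch[i + 1], cfg.inter_block_kernel, rng,
                              bias=False))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.data.ndim == 2:                      # single sample (T, D)
            x = x.reshape(1, *x.data.shape)
        x = self.input_bn(x)
        x = self.input_proj(x)
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i < 3:
                x = self.transitions[i](x)
        return x.mean(axis=1)                     # (B, embedding_dim)


def build_stream(cfg: StreamConfig, rng=None) -> StreamNet:
    """Construct one temporal stream network from its configuration."""
    if rng is None:
        rng = np.random.default_rng(0)
    return StreamNet(cfg, rng)


@dataclass
class _TableRow:
    r: int
    branch_counts: dict
    total: int
    basic: int
    ratio: float


def reduction_table(in_channels: int = 32, kernels: tuple = (3, 5),
                    reductions: tuple = (2, 4, 8)) -> list:
    """Analytic comparison of bottleneck weight counts across reduction
    rates, against the matching basic block (the printed comparison table)."""
    basic = count_block_parameters(BlockConfig(in_channels, in_channels,
                                               kernels, "basic"))
    rows = []
    for r in reductions:
        cfg = BlockConfig(in_channels, in_channels, kernels, "bottleneck",
                          reduction=r)
        rows.append(_TableRow(
            r=r,
            branch_counts={k: count_branch_parameters(cfg, k)
                           for k in kernels},
            total=count_block_parameters(cfg),
            basic=basic,
            ratio=count_block_parameters(cfg) / basic))
    return rows
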