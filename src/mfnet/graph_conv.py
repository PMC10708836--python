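"""Skeleton graphs and the graph-convolution layer.

A skeleton frame is a graph G(V, E) over joints: the binary adjacency A has
A_ij = 1 when joints i and j are connected.  Propagation uses the
symmetrically normalized matrix

    S = D^{-1/2} (A + I) D^{-1/2}

where D is the degree matrix of A + I, and one layer computes
``f_out = sigma(S f_in W)``: each node aggregates its degree-weighted
neighborhood (including itself via the added identity) before the shared
channel mixing W.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import nn
from .skeleton_core import ValidationError


@dataclass(frozen=True)
class SkeletonGraph:
    n_nodes: int
    A: np.ndarray        # binary adjacency, zero diagonal
    A_tilde: np.ndarray  # A + I
    D: np.ndarray        # degree matrix of A_tilde (diagonal)
    S: np.ndarray        # D^{-1/2} A_tilde D^{-1/2}


def build_graph(edges, n_nodes: int) -> SkeletonGraph:
    """Build a skeleton graph from 1-based undirected joint-number pairs."""
    A = np.zeros((n_nodes, n_nodes))
    for i, j in edges:
        if not (1 <= i <= n_nodes and 1 <= j <= n_nodes):
            raise ValidationError(f"edge ({i},{j}) outside 1..{n_nodes}")
        if i == j:
            raise ValidationError(
                f"self-loop ({i},{i}): self-connection is added via I only")
        A[i - 1, j - 1] = A[j - 1, i - 1] = 1.0
    A_tilde = A + np.eye(n_nodes)
    deg = A_tilde.sum(axis=1)
    D = np.diag(deg)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    S = d_inv_sqrt[:, None] * A_tilde * d_inv_sqrt[None, :]
    return SkeletonGraph(n_nodes=n_nodes, A=A, A_tilde=A_tilde, D=D, S=S)


def _load_packaged(name: str) -> SkeletonGraph:
    raw = json.loads(resources.files("mfnet.data").joinpath(name).read_text())
    return build_graph(raw["edges"], raw["n_nodes"])


def body_graph() -> SkeletonGraph:
    """Default 20-joint skeleton graph (19-edge natural-connectivity tree)."""
    return _load_packaged("body_graph.json")


def part_graph() -> SkeletonGraph:
    """Default 5-node part graph (limbs star-connected to the trunk)."""
    return _load_packaged("part_graph.json")


_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "identity": lambda x: x,
}


@dataclass
class GcnLayerParams:
    W: np.ndarray
    activation: str = "relu"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        if not np.isfinite(self.W).all():
            raise ValidationError("W contains non-finite values")
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(
                f"activation must be one of {sorted(_ACTIVATIONS)}")


def gcn_layer(fin: np.ndarray, graph: SkeletonGraph,
              params: GcnLayerParams) -> np.ndarray:
    """One graph convolution: ``sigma(S fin W)``.

    ``fin`` may be (n_nodes, C_in) for a single frame or (..., n_nodes, C_in);
    the layer is applied identically and independently per frame.
    """
    fin = np.asarray(fin, dtype=np.float64)
    if fin.shape[-2] != graph.n_nodes:
        raise ValueError(
            f"fin has {fin.shape[-2]} nodes, graph has {graph.n_nodes}")
    if fin.shape[-1] != params.W.shape[0]:
        raise ValueError(
            f"fin channels {fin.shape[-1]} != W rows {params.W.shape[0]}")
    return _ACTIVATIONS[params.activation](graph.S @ fin @ params.W)


class GraphConv(nn.Module):
    """Trainable GCN layer over a fixed graph, for (B, T, n, C) input."""

    def __init__(self, graph: SkeletonGraph, in_channels: int,
                 out_channels: int, rng, activation="relu"):
        self.S = nn.Tensor(graph.S)
        self.W = nn.Parameter(nn._kaiming(rng, in_channels,
                                          (in_channels, out_channels)))
        self.activation = activation

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        out = self.S @ x @ self.W
        return out.relu() if self.activation == "relu" else out
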