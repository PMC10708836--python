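"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operations the action-recognition network
needs: dense and temporal (1D) convolutions, batch normalization, ReLU,
dropout, softmax/cross-entropy, concatenation and reductions.  Arrays use
the layout (batch, time, channels) throughout; a kernel-``k`` temporal
convolution is an im2col windowing followed by a matrix product.

Design notes
------------
* ``Tensor`` records a closure per parent for the backward pass; gradients
  are accumulated by a topological sweep from the loss.
* All computation is float64.  Together with single-threaded BLAS this
  makes training runs bit-reproducible for a fixed seed on a fixed platform.
* Parameters carry a ``kind`` tag (``weight`` / ``bias`` / ``norm``) so that
  parameter accounting can exclude normalization statistics, mirroring how
  the block parameter tables in the literature count only weight products.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._backward(t.grad)):
                if not parent.requires_grad or g is None:
                    continue
                g = _unbroadcast(g, parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor._make(self.data + other.data, (self, other),
                            lambda g: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor._make(self.data * other.data, (self, other),
                            lambda g: (g * other.data, g * self.data))

    __rmul__ = __mul__

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor._make(self.data - other.data, (self, other),
                            lambda g: (g, -g))

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def matmul(self, other):
        other = _as_tensor(other)

        def back(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return ga, gb

        return Tensor._make(np.matmul(self.data, other.data),
                            (self, other), back)

    __matmul__ = matmul

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def max(self, axis, keepdims=False):
        """Maximum along ``axis``; the gradient routes to the arg-max entry."""
        out = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out)
        # split ties evenly so the gradient check passes on degenerate input
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def back(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (g2 * mask,)

        return Tensor._make(out if keepdims else out.squeeze(axis),
                            (self,), back)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def concat(tensors, axis=-1):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, back)


def stack(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]

    def back(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tensors, back)


def softmax(x: Tensor, axis=-1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return ((g - dot) * s,)

    return Tensor._make(s, (x,), back)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class ids."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()

    def back(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        return (g * p / n,)

    return Tensor._make(loss, (logits,), back)


# ---------------------------------------------------------------------------
# modules


class Parameter(Tensor):
    __slots__ = ("kind",)

    def __init__(self, data, kind="weight"):
        super().__init__(data, requires_grad=True)
        self.kind = kind


class Module:
    """Base class: parameter discovery, train/eval mode, state export."""

    def parameters(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self):
        out = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    training = True

    def state_arrays(self):
        """All state needed to restore the module: parameters + BN statistics."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays):
        arrays = list(arrays)
        for p in self.parameters():
            p.data = arrays.pop(0).copy()
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.running_mean = arrays.pop(0).copy()
                m.running_var = arrays.pop(0).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng, fan_in, shape):
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        self.W = Parameter(_kaiming(rng, in_features, (in_features, out_features)))
        self.b = Parameter(np.zeros(out_features), kind="bias") if bias else None

    def forward(self, x):
        out = x @ self.W
        return out + self.b if self.b is not None else out


class Conv1d(Module):
    """Temporal convolution on (batch, time, channels) input, stride 1.

    ``padding='same'`` keeps the sequence length; ``padding='causal'`` pads
    only on the left so frame t never sees the future.
    """

    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 bias=False, padding="same"):
        if kernel_size % 2 == 0 and padding == "same":
            raise ValueError("same-padding requires an odd kernel size")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.W = Parameter(_kaiming(rng, in_channels * kernel_size,
                                    (kernel_size * in_channels, out_channels)))
        self.b = Parameter(np.zeros(out_channels), kind="bias") if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, T, C = x.data.shape
        k = self.kernel_size
        if self.padding == "same":
            left = right = (k - 1) // 2
        else:  # causal
            left, right = k - 1, 0
        xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
        # windows: (B, T, k, C) -> (B, T, k*C)
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        win = win.transpose(0, 1, 3, 2).reshape(B, T, k * C)
        out = win @ self.W.data
        if self.b is not None:
            out = out + self.b.data

        W = self.W

        def back(g):
            # g: (B, T, C_out)
            gW = np.tensordot(win, g, axes=([0, 1], [0, 1]))
            gwin = (g @ W.data.T).reshape(B, T, k, C)
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, j:j + T, :] += gwin[:, :, j, :]
            gx = gxp[:, left:left + T, :] if right == 0 else \
                gxp[:, left:gxp.shape[1] - right, :]
            gb = g.sum(axis=(0, 1)) if self.b is not None else None
            return (gx, gW) + ((gb,) if self.b is not None else ())

        parents = (x, W) + ((self.b,) if self.b is not None else ())
        return Tensor._make(out, parents, back)


class BatchNorm(Module):
    """Normalizes the trailing channel axis over all leading axes."""

    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(num_features), kind="norm")
        self.beta = Parameter(np.zeros(num_features), kind="norm")
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        if self.training:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean) * inv
        out = self.gamma.data * xhat + self.beta.data
        n = x.data.size // x.data.shape[-1]
        training = self.training
        gamma = self.gamma

        def back(g):
            ggamma = (g * xhat).sum(axis=axes)
            gbeta = g.sum(axis=axes)
            if training:
                gx = (gamma.data * inv / n) * (
                    n * g - gbeta - xhat * ggamma)
            else:
                gx = g * gamma.data * inv
            return gx, ggamma, gbeta

        return Tensor._make(out, (x, self.gamma, self.beta), back)


class Dropout(Module):
    def __init__(self, p, rng):
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with decoupled L2 weight decay on ``weight``-kind parameters."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and getattr(p, "kind", "weight") == "weight":
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
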