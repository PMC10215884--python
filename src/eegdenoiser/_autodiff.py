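"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supplies exactly the operations the 1D encoder–decoder needs: same-padded
1D convolution (im2col + BLAS tensordot), non-overlapping max-pooling,
nearest-neighbour upsampling, channel concatenation, ReLU, batch
normalization, elementwise add, and mean-squared-error reduction — each with
a hand-derived backward pass.  Gradients flow through a DAG of `Tensor`
nodes; `Tensor.backward()` runs a topological sweep from a scalar loss.

Convolution layouts follow the (batch, channels, length) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam",
           "conv1d", "relu", "add", "concat", "maxpool1d",
           "upsample_nearest", "batchnorm1d", "mse", "mean_scalars"]


class Tensor:
    """A node in the computation graph holding a NumPy array."""

    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad=False, _children=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(c.requires_grad for c in _children)
        self._children = _children
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        """Backpropagate from this (scalar) node."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                t, processed = stack.pop()
                if processed:
                    order.append(t)
                    continue
                if id(t) in seen or not t.requires_grad:
                    continue
                seen.add(id(t))
                stack.append((t, True))
                for c in t._children:
                    stack.append((c, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def conv1d(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Same-padded, stride-1 1D convolution (cross-correlation).

    x: (N, C_in, L); w: (C_out, C_in, K) with K odd; b: (C_out,).

    Implemented as one GEMM against the (C_in, C_out·K) unrolled kernel
    followed by K shifted accumulations, which keeps every large operand
    contiguous (much faster than im2col on strided views).
    """
    C_out, C_in, K = w.data.shape
    p = (K - 1) // 2
    xd = x.data
    N, _, L = xd.shape
    Lp = L + 2 * p
    if p:
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p)))
    else:
        xp = xd
    xpT = np.ascontiguousarray(xp.transpose(0, 2, 1))    # (N, Lp, C_in)
    wall = w.data.transpose(1, 0, 2).reshape(C_in, C_out * K)
    big = (xpT.reshape(-1, C_in) @ wall).reshape(N, Lp, C_out, K)
    outT = big[:, 0:L, :, 0].copy()                      # k = 0 term
    for k in range(1, K):
        outT += big[:, k:k + L, :, k]
    out = np.ascontiguousarray(outT.transpose(0, 2, 1))
    out += b.data[:, None]

    def _backward(g):
        b._accumulate(g.sum(axis=(0, 2)))
        gT = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, L, C_out)
        gbig = np.zeros((N, Lp, C_out, K), dtype=g.dtype)
        for k in range(K):
            gbig[:, k:k + L, :, k] = gT
        gflat = gbig.reshape(-1, C_out * K)
        # grad_w: (C_in, C_out*K) = xpT^T @ gbig
        gw = (xpT.reshape(-1, C_in).T @ gflat)
        w._accumulate(gw.reshape(C_in, C_out, K).transpose(1, 0, 2))
        if x.requires_grad:
            gxpT = gflat @ wall.T                        # (N*Lp, C_in)
            gxp = gxpT.reshape(N, Lp, C_in).transpose(0, 2, 1)
            x._accumulate(np.ascontiguousarray(gxp[:, :, p:p + L]))

    return Tensor(out, _children=(x, w, b), _backward=_backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def _backward(g):
        x._accumulate(g * mask)

    return Tensor(out, _children=(x,), _backward=_backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def _backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return Tensor(out, _children=(a, b), _backward=_backward)


def concat(tensors, axis=1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor(out, _children=tuple(tensors), _backward=_backward)


def maxpool1d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping max pooling; length must be divisible by ``factor``."""
    N, C, L = x.data.shape
    if L % factor:
        raise ValueError(f"length {L} not divisible by pooling factor {factor}")
    windows = x.data.reshape(N, C, L // factor, factor)
    arg = windows.argmax(axis=3)
    out = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]

    def _backward(g):
        gx = np.zeros_like(windows)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=3)
        x._accumulate(gx.reshape(N, C, L))

    return Tensor(out, _children=(x,), _backward=_backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    out = np.repeat(x.data, factor, axis=2)

    def _backward(g):
        N, C, L = g.shape
        x._accumulate(g.reshape(N, C, L // factor, factor).sum(axis=3))

    return Tensor(out, _children=(x,), _backward=_backward)


def batchnorm1d(x: Tensor, gamma: Parameter, beta: Parameter,
                running_mean, running_var, training: bool,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (batch, length).

    Mutates ``running_mean``/``running_var`` in place while training.
    """
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2))
        var = xd.var(axis=(0, 2))
        running_mean += momentum * (mean - running_mean)
        running_var += momentum * (var - running_var)
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    x_hat = (xd - mean[:, None]) * inv[:, None]
    out = gamma.data[:, None] * x_hat + beta.data[:, None]

    def _backward(g):
        gamma._accumulate((g * x_hat).sum(axis=(0, 2)))
        beta._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gi = g * gamma.data[:, None]
            if training:
                m = xd.shape[0] * xd.shape[2]
                mean_gi = gi.sum(axis=(0, 2)) / m
                mean_gix = (gi * x_hat).sum(axis=(0, 2)) / m
                gx = inv[:, None] * (gi - mean_gi[:, None]
                                     - x_hat * mean_gix[:, None])
            else:
                gx = gi * inv[:, None]
            x._accumulate(gx)

    return Tensor(out, _children=(x, gamma, beta), _backward=_backward)


def mse(pred: Tensor, target) -> Tensor:
    """Mean squared error against a constant target array."""
    target = np.asarray(target)
    diff = pred.data - target
    out = np.asarray((diff ** 2).mean())

    def _backward(g):
        pred._accumulate(g * 2.0 * diff / diff.size)

    return Tensor(out, _children=(pred,), _backward=_backward)


def mean_scalars(losses) -> Tensor:
    """Mean of scalar loss tensors (used for deep-supervision totals)."""
    out = np.asarray(np.mean([l.data for l in losses]))
    k = len(losses)

    def _backward(g):
        for l in losses:
            l._accumulate(g / k)

    return Tensor(out, _children=tuple(losses), _backward=_backward)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
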