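"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine sufficient for the convolutional classifier in this
package: broadcast-aware arithmetic, matrix multiplication, stride-1 "same"
convolution via im2col, 2x2 max pooling, global pooling reductions, the
activations used by the network, dropout, and a fused softmax cross-entropy
loss.  Tensors default to float32; float64 inputs are kept at float64 so that
finite-difference gradient checks can run at full precision.

Gradients are accumulated by topological traversal of the recorded graph.
Only the ops the architecture needs are provided; this is not a general
framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "conv2d",
    "maxpool2x2",
    "mean",
    "reduce_max",
    "reshape",
    "concat",
    "dropout",
    "softmax_cross_entropy",
]


def _as_float(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype == np.float64:
        return arr
    return arr.astype(np.float32, copy=False)


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference-only passes)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A node in the autodiff graph: an array plus an optional gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        # ``own`` marks a freshly allocated (or dead-after-backward) array
        # that may be stored without a defensive copy.
        if self.grad is None:
            if own and g.dtype == self.data.dtype:
                self.grad = g
            else:
                self.grad = g.astype(self.data.dtype)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _make(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape), own=True)
        b._accumulate(_unbroadcast(g * a.data, b.data.shape), own=True)

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T, own=True)
        b._accumulate(a.data.T @ g, own=True)

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = _wrap(x)
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x._accumulate(g * mask, own=True)

    return _make(out_data, (x,), backward)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = _wrap(x)
    s = _stable_sigmoid(x.data)

    def backward(g):
        x._accumulate(g * s * (1.0 - s), own=True)

    return _make(s, (x,), backward)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    count = x.data.size / out_data.size

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape) / count, own=True)

    return _make(out_data, (x,), backward)


def reduce_max(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    """Maximum over ``axis``; gradient is split evenly across ties."""
    x = _wrap(x)
    out_data = x.data.max(axis=axis, keepdims=True)
    mask = (x.data == out_data)
    nties = mask.sum(axis=axis, keepdims=True)
    result = out_data if keepdims else np.squeeze(out_data, axis=axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape) * mask / nties, own=True)

    return _make(result, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = _wrap(x)
    old = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(old))

    return _make(out_data, (x,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece, own=True)

    return _make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution and pooling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,C,Hp,Wp) padded input -> (N*H*W, C*kh*kw) patch matrix."""
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # windows: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw)
    n, c, h, w = windows.shape[:4]
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 'same'-padded 2-D convolution (cross-correlation).

    x: (N, C, H, W); weight: (F, C, kh, kw); bias: (F,) or None.
    """
    x, weight = _wrap(x), _wrap(weight)
    n, c, h, w = x.data.shape
    f, c2, kh, kw = weight.data.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {c2}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw)                      # (N*H*W, C*kh*kw)
    wmat = weight.data.reshape(f, -1).T             # (C*kh*kw, F)
    out = cols @ wmat
    if bias is not None:
        out = out + bias.data
    out_t = out.reshape(n, h, w, f).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, f)  # (N*H*W, F)
        weight._accumulate((cols.T @ gmat).T.reshape(weight.data.shape), own=True)
        if bias is not None:
            bias._accumulate(gmat.sum(axis=0), own=True)
        dcols = (gmat @ wmat.T).reshape(n, h, w, c, kh, kw)
        # one big transpose-copy, then contiguous per-tap adds
        dcols = np.ascontiguousarray(dcols.transpose(4, 5, 0, 3, 1, 2))  # (kh,kw,N,C,H,W)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + h, j:j + w] += dcols[i, j]
        x._accumulate(dxp[:, :, ph:ph + h, pw:pw + w], own=True)

    return _make(out_t, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    h2, w2 = h // 2, w // 2
    if h2 == 0 or w2 == 0:
        raise ValueError(f"maxpool2x2 needs spatial extent >= 2, got {h}x{w}")
    xr = x.data[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
    out_data = xr.max(axis=(3, 5))
    mask = xr == out_data[:, :, :, None, :, None]
    nties = mask.sum(axis=(3, 5), keepdims=True)

    def backward(g):
        gr = (g[:, :, :, None, :, None] * mask / nties).reshape(n, c, h2 * 2, w2 * 2)
        gx = np.zeros_like(x.data)
        gx[:, :, : h2 * 2, : w2 * 2] = gr
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# regularization / loss
# ---------------------------------------------------------------------------

def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero a fraction ``rate``, rescale survivors."""
    x = _wrap(x)
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep

    def backward(g):
        x._accumulate(g * mask, own=True)

    return _make(x.data * mask, (x,), backward)


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                    eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalization over axes (0, 2, 3) with batch statistics.

    gamma/beta are shaped (1, C, 1, 1).  Returns the normalized output plus
    the (biased) batch mean and variance as plain (C,) arrays so the caller
    can maintain running statistics.
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data * xhat + beta.data

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=axes, keepdims=True), own=True)
        beta._accumulate(g.sum(axis=axes, keepdims=True), own=True)
        g_mean = g.mean(axis=axes, keepdims=True)
        gx_mean = (g * xhat).mean(axis=axes, keepdims=True)
        x._accumulate((gamma.data * inv) * (g - g_mean - xhat * gx_mean), own=True)

    return _make(out, (x, gamma, beta), backward), mu.reshape(-1), var.reshape(-1)


def batchnorm_infer(x: Tensor, gamma: Tensor, beta: Tensor,
                    running_mean: np.ndarray, running_var: np.ndarray,
                    eps: float) -> Tensor:
    """Batch normalization with stored running statistics (inference mode)."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    inv = (1.0 / np.sqrt(running_var + eps)).reshape(1, -1, 1, 1).astype(x.data.dtype)
    mean = running_mean.reshape(1, -1, 1, 1).astype(x.data.dtype)
    scale = gamma.data * inv
    shift = beta.data - gamma.data * mean * inv
    out = x.data * scale + shift

    def backward(g):
        axes = (0, 2, 3)
        gamma._accumulate(
            (g * (x.data - mean) * inv).sum(axis=axes, keepdims=True), own=True
        )
        beta._accumulate(g.sum(axis=axes, keepdims=True), own=True)
        x._accumulate(g * scale, own=True)

    return _make(out, (x, gamma, beta), backward)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean categorical cross-entropy over the batch, fused with softmax.

    Returns (scalar loss tensor, softmax probabilities as a plain array).
    """
    logits = _wrap(logits)
    z = logits.data
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    nbatch = z.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss_val = -(onehot * np.log(probs + eps)).sum() / nbatch

    def backward(g):
        logits._accumulate(g * (probs - onehot) / nbatch, own=True)

    return _make(np.asarray(loss_val), (logits,), backward), probs
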