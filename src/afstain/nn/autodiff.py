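"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for the virtual stainer: convolutions (im2col),
pooling/upsampling, pointwise nonlinearities, concatenation, rotations,
reductions and the loss arithmetic.  Arrays are NHWC.  Everything is
plain float64 NumPy, so training is bitwise-deterministic for a fixed
seed — there is no threading or fused-kernel nondeterminism to contend
with.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    # -- graph traversal ---------------------------------------------------

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.value + b.value, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.value.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g, b.value.shape)

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.value * b.value, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * b.value, a.value.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * a.value, b.value.shape)

    out._backward = backward
    return out


def square(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.value**2, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * 2.0 * a.value

    out._backward = backward
    return out


def absolute(a) -> Tensor:
    """|a| with the subgradient sign(a) (0 at 0)."""
    a = as_tensor(a)
    out = Tensor(np.abs(a.value), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * np.sign(a.value)

    out._backward = backward
    return out


def mean(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.value.mean(), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * np.ones_like(a.value) / a.value.size

    out._backward = backward
    return out


def total(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.value.sum(), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * np.ones_like(a.value)

    out._backward = backward
    return out


def leaky_relu(a, alpha: float = 0.2) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.where(a.value > 0, a.value, alpha * a.value), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * np.where(a.value > 0, 1.0, alpha)

    out._backward = backward
    return out


def softplus(a) -> Tensor:
    """log(1 + e^a), numerically stable."""
    a = as_tensor(a)
    v = a.value
    out = Tensor(np.maximum(v, 0.0) + np.log1p(np.exp(-np.abs(v))), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g / (1.0 + np.exp(-v))

    out._backward = backward
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.value for t in tensors], axis=axis), parents=tuple(tensors)
    )
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t.grad += part

    out._backward = backward
    return out


def crop(a, slices: tuple) -> Tensor:
    """Slice with gradient scatter-back."""
    a = as_tensor(a)
    out = Tensor(a.value[slices], parents=(a,))

    def backward(g):
        if a.requires_grad:
            buf = np.zeros_like(a.value)
            buf[slices] += g
            a.grad += buf

    out._backward = backward
    return out


def rot90(a, k: int) -> Tensor:
    """Rotate NHWC maps by k*90 degrees in the spatial plane."""
    a = as_tensor(a)
    out = Tensor(np.rot90(a.value, k, axes=(1, 2)).copy(), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += np.rot90(g, -k, axes=(1, 2))

    out._backward = backward
    return out


def avg_pool2(a) -> Tensor:
    """2x2 average pooling (NHWC, even spatial dims)."""
    a = as_tensor(a)
    n, h, w, c = a.value.shape
    v = a.value.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))
    out = Tensor(v, parents=(a,))

    def backward(g):
        if a.requires_grad:
            up = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0
            a.grad += up

    out._backward = backward
    return out


def upsample_nearest2(a) -> Tensor:
    """2x nearest-neighbour spatial upsampling (NHWC)."""
    a = as_tensor(a)
    v = np.repeat(np.repeat(a.value, 2, axis=1), 2, axis=2)
    out = Tensor(v, parents=(a,))

    def backward(g):
        if a.requires_grad:
            n, h2, w2, c = g.shape
            a.grad += g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))

    out._backward = backward
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, Ho, Wo, kh, kw, C) sliding-window view of a padded NHWC array."""
    n, h, w, c = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, ho, wo, kh, kw, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
        writeable=False,
    )
    return view, ho, wo


def conv2d(x, w, b, stride: int = 1, padding: str = "same") -> Tensor:
    """2-D convolution, NHWC input, (kh, kw, Cin, Cout) kernel."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    kh, kw, cin, cout = w.value.shape
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
    elif padding == "valid":
        ph = pw = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.value, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    view, ho, wo = _im2col(xp, kh, kw, stride)
    y = np.tensordot(view, w.value, axes=([3, 4, 5], [0, 1, 2])) + b.value
    out = Tensor(y, parents=(x, w, b))

    def backward(g):
        if b.requires_grad:
            b.grad += g.sum(axis=(0, 1, 2))
        if w.requires_grad:
            w.grad += np.tensordot(view, g, axes=([0, 1, 2], [0, 1, 2]))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            # scatter each kernel tap's contribution back to the input
            dpatch = np.tensordot(g, w.value, axes=([3], [3]))  # (N,Ho,Wo,kh,kw,Cin)
            for i in range(kh):
                for j in range(kw):
                    dxp[
                        :,
                        i : i + stride * ho : stride,
                        j : j + stride * wo : stride,
                        :,
                    ] += dpatch[:, :, :, i, j, :]
            if ph or pw:
                dxp = dxp[:, ph : ph + x.value.shape[1], pw : pw + x.value.shape[2], :]
            x.grad += dxp

    out._backward = backward
    return out


def glorot_uniform(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Glorot (Xavier) uniform init for a (kh, kw, Cin, Cout) kernel."""
    if len(shape) == 4:
        kh, kw, cin, cout = shape
        fan_in, fan_out = kh * kw * cin, kh * kw * cout
    else:
        fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
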