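"""A compact reverse-mode autodiff engine over numpy arrays.

Provides exactly the primitives the denoising U-Net needs: broadcast
arithmetic, (batched) matmul, 3x3 same-padding convolution, 2x2 average
pooling / nearest upsampling, SiLU, softmax, group normalization and
reductions.  Each op records its parents and a closure computing parent
gradients; ``Tensor.backward`` walks the graph in reverse topological
order.  Gradients accumulate by summation, broadcasting is undone by
summing over the broadcast axes.

This is deliberately minimal — no graph optimization, no in-place ops,
single-threaded numpy — and is validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "conv2d",
    "avgpool2",
    "upsample2",
    "silu",
    "softmax",
    "groupnorm",
    "tsum",
    "tmean",
    "Adam",
]


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "_parents", "_backward_fn")

    def __init__(self, data, parents=(), backward_fn=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = parents
        self._backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self) -> None:
        """Backpropagate from this node (seeded with ones)."""
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward_fn(node.grad)):
                if g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _wrap_pair(a, b) -> tuple[Tensor, Tensor]:
    """Wrap operands; bare python scalars adopt the other operand's dtype
    so float32 graphs are not silently upcast to float64."""
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(a, (int, float)) and isinstance(b, Tensor):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    return _wrap(a), _wrap(b)


def add(a, b) -> Tensor:
    a, b = _wrap_pair(a, b)
    out_data = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _wrap_pair(a, b)
    out_data = a.data * b.data

    def bwd(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor(out_data, (a, b), bwd)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bwd(g):
        if b.data.ndim == 1:
            ga = np.outer(g, b.data) if a.data.ndim > 1 else g * b.data
            gb = a.data.T @ g if a.data.ndim > 1 else a.data * g
            return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)
        ga = g @ b.data.swapaxes(-1, -2)
        gb = a.data.swapaxes(-1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return Tensor(out_data, (a, b), bwd)


def reshape(t: Tensor, shape) -> Tensor:
    t = _wrap(t)
    orig = t.data.shape

    def bwd(g):
        return (g.reshape(orig),)

    return Tensor(t.data.reshape(shape), (t,), bwd)


def transpose(t: Tensor, axes) -> Tensor:
    t = _wrap(t)
    inv = np.argsort(axes)

    def bwd(g):
        return (g.transpose(inv),)

    return Tensor(t.data.transpose(axes), (t,), bwd)


def tsum(t: Tensor, axis=None, keepdims=False) -> Tensor:
    t = _wrap(t)
    out_data = t.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            return (np.broadcast_to(g, t.data.shape).copy(),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, t.data.shape).copy(),)

    return Tensor(out_data, (t,), bwd)


def tmean(t: Tensor, axis=None, keepdims=False) -> Tensor:
    t = _wrap(t)
    n = t.data.size if axis is None else np.prod(
        [t.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(t, axis=axis, keepdims=keepdims), 1.0 / float(n))


def silu(t: Tensor) -> Tensor:
    t = _wrap(t)
    sig = 1.0 / (1.0 + np.exp(-t.data))
    out_data = t.data * sig

    def bwd(g):
        return (g * (sig * (1.0 + t.data * (1.0 - sig))),)

    return Tensor(out_data, (t,), bwd)


def softmax(t: Tensor, axis=-1) -> Tensor:
    t = _wrap(t)
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return Tensor(y, (t,), bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, zero-padded 'same' convolution.

    ``x``: (B, C, H, W); ``w``: (O, C, k, k) with odd k; ``b``: (O,).
    """
    x, w, b = _wrap(x), _wrap(w), _wrap(b)
    B, C, H, W = x.data.shape
    O, Cw, k, _ = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (B, C, H, W, k, k) -> cols: (B, H*W, C*k*k)
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * H * W, C * k * k
    )
    wmat = w.data.reshape(O, C * k * k)
    out = cols @ wmat.T + b.data
    out_data = out.reshape(B, H * W, O).transpose(0, 2, 1).reshape(B, O, H, W)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * H * W, O)
        gw = (gmat.T @ cols).reshape(w.data.shape)
        gb = g.sum(axis=(0, 2, 3))
        gcols = (gmat @ wmat).reshape(B, H, W, C, k, k)
        gx_pad = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gx_pad[:, :, i : i + H, j : j + W] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        gx = gx_pad[:, :, pad : pad + H, pad : pad + W]
        return gx, gw, gb

    return Tensor(out_data, (x, w, b), bwd)


def avgpool2(x: Tensor) -> Tensor:
    x = _wrap(x)
    B, C, H, W = x.data.shape
    out_data = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def bwd(g):
        g4 = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        return (g4,)

    return Tensor(out_data, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    x = _wrap(x)
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        B, C, H2, W2 = g.shape
        return (g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)),)

    return Tensor(out_data, (x,), bwd)


def groupnorm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization over (C/groups, H, W) with per-channel affine."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    B, C, H, W = x.data.shape
    if C % groups:
        raise ValueError(f"channels {C} not divisible by groups {groups}")
    xg = x.data.reshape(B, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat_g = (xg - mu) * inv_std
    xhat = xhat_g.reshape(B, C, H, W)
    gm = gamma.data.reshape(1, C, 1, 1)
    out_data = xhat * gm + beta.data.reshape(1, C, 1, 1)

    def bwd(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        dxhat = (g * gm).reshape(B, groups, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xhat_g).mean(axis=2, keepdims=True)
        dx = inv_std * (dxhat - m1 - xhat_g * m2)
        return dx.reshape(B, C, H, W), ggamma, gbeta

    return Tensor(out_data, (x, gamma, beta), bwd)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
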