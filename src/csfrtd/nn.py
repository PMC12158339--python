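"""Tape-based automatic differentiation and neural-network primitives on numpy.

This is the computational core behind the detection network: a small reverse-mode
autodiff engine (:class:`Tensor` plus a closed set of operations) together with
the layer, initialisation and optimiser machinery the architecture needs --
dilated/grouped 2-D convolution, 2x2 max pooling, nearest-neighbour upsampling,
channel-wise 1-D convolution (for channel attention), dropout, a masked softmax
cross-entropy, and Adam.

All arithmetic is float32 and single-threaded numpy, so results are bit-exact
reproducible for a fixed seed.  Convolutions are stride-1 with "same" padding
(output spatial size equals input spatial size); spatial resolution changes only
through explicit pooling/upsampling, which mirrors how the segmentation network
is laid out.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "Dropout",
    "Adam",
    "sigmoid",
    "tanh",
    "relu",
    "concat",
    "slice_channels",
    "mean",
    "conv2d",
    "conv1d_channels",
    "max_pool2d",
    "upsample2",
    "softmax_cross_entropy_masked",
    "softmax_probs",
]


# ---------------------------------------------------------------------------
# Autograd engine
# ---------------------------------------------------------------------------

class Tensor:
    """A numpy array with a gradient tape.

    Only the operations defined in this module are recorded; each op stores a
    closure that accumulates gradients into its parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (recurrent unroll)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def reshape(self, *shape):
        return reshape(self, shape)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Elementwise and shape ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g):
        x._accumulate(g * (1.0 - t * t))

    return Tensor._make(t, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape

    def backward(g):
        x._accumulate(g.reshape(old))

    return Tensor._make(x.data.reshape(shape), (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def slice_channels(x: Tensor, lo: int, hi: int) -> Tensor:
    """Slice along axis 1 (channels)."""

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[:, lo:hi] = g
        x._accumulate(gx)

    return Tensor._make(x.data[:, lo:hi], (x,), backward)


def mean(x: Tensor, axis=None) -> Tensor:
    out_data = x.data.mean(axis=axis)
    n = x.data.size if axis is None else np.prod([x.data.shape[a] for a in np.atleast_1d(axis)])

    def backward(g):
        g_full = np.asarray(g)
        if axis is not None:
            g_full = np.expand_dims(g_full, axis=tuple(np.atleast_1d(axis)))
        x._accumulate(np.broadcast_to(g_full, x.data.shape) / n)

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# Convolution and resampling
# ---------------------------------------------------------------------------

def _dilated_windows(xp: np.ndarray, k: int, d: int) -> np.ndarray:
    """View of all kxk dilated windows of a padded (B,C,Hp,Wp) array."""
    span = d * (k - 1) + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(2, 3))
    return win[..., ::d, ::d]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           dilation: int = 1, groups: int = 1) -> Tensor:
    """Stride-1 "same" 2-D convolution (cross-correlation) with dilation/groups.

    x: (B, Cin, H, W); w: (Cout, Cin//groups, k, k); b: (Cout,) or None.
    Output spatial size equals input spatial size for odd k.
    """
    B, Cin, H, W = x.data.shape
    Cout, Cg, k, _ = w.data.shape
    if Cin != Cg * groups:
        raise ValueError(f"channel mismatch: input {Cin}, weight expects {Cg * groups}")
    d = dilation
    pad = d * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = _dilated_windows(xp, k, d)                      # (B,Cin,H,W,k,k)
    G = groups
    Og = Cout // G
    wing = win.reshape(B, G, Cg, H, W, k, k)
    wg = w.data.reshape(G, Og, Cg, k, k)
    out = np.einsum("bgchwkl,gockl->bgohw", wing, wg, optimize=True)
    out = np.ascontiguousarray(out.reshape(B, Cout, H, W))
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gg = g.reshape(B, G, Og, H, W)
        if w.requires_grad:
            gw = np.einsum("bgchwkl,bgohw->gockl", wing, gg, optimize=True)
            w._accumulate(gw.reshape(Cout, Cg, k, k))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for l in range(k):
                for m in range(k):
                    contrib = np.einsum("bgohw,goc->bgchw", gg, wg[:, :, :, l, m],
                                        optimize=True)
                    gxp[:, :, l * d:l * d + H, m * d:m * d + W] += \
                        contrib.reshape(B, Cin, H, W)
            if pad:
                x._accumulate(gxp[:, :, pad:pad + H, pad:pad + W])
            else:
                x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def conv1d_channels(x: Tensor, w: Tensor) -> Tensor:
    """1-D convolution along the channel axis of a (B, C) descriptor.

    Used by channel attention: each channel interacts with its k neighbours,
    with one shared kernel w of odd length k ("same" zero padding).
    """
    (k,) = w.data.shape
    pad = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B,C,k)
    out = win @ w.data

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bck,bc->k", win, g))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            C = x.data.shape[1]
            for j in range(k):
                gxp[:, j:j + C] += g * w.data[j]
            gx = gxp[:, pad:pad + C] if pad else gxp
            x._accumulate(gx)

    return Tensor._make(out, (x, w), backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Ties break to the first (row-major) element."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2d needs even spatial dims, got {H}x{W}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(B, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gx.reshape(B, C, H, W))

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    B, C, H, W = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        x._accumulate(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Loss and inference heads
# ---------------------------------------------------------------------------

def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Class probabilities from a (B, K, H, W) logit array (no grad)."""
    return np.exp(_log_softmax(logits))


def softmax_cross_entropy_masked(logits: Tensor, labels: np.ndarray,
                                 valid: np.ndarray,
                                 class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted mean pixelwise cross-entropy over valid pixels.

    logits: (B, K, H, W); labels: (B, H, W) integer classes; valid: (B, H, W)
    boolean -- invalid pixels contribute nothing to the loss or its gradient.
    class_weights (K,) rescales each pixel's term by the weight of its true
    class (weighted-mean normalisation), the usual counter to class imbalance.
    """
    labels = np.asarray(labels)
    vmask = np.asarray(valid, dtype=bool)
    if not vmask.any():
        raise ValueError("loss undefined: no valid pixels")
    if class_weights is None:
        pix_w = vmask.astype(np.float32)
    else:
        cw = np.asarray(class_weights, dtype=np.float32)
        pix_w = cw[labels] * vmask
    total_w = float(pix_w.sum())
    logp = _log_softmax(logits.data)
    picked = np.take_along_axis(logp, labels[:, None], axis=1)[:, 0]
    loss = -(picked * pix_w).sum() / total_w

    def backward(g):
        probs = np.exp(logp)
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
        grad = (probs - onehot) * pix_w[:, None] / total_w
        logits._accumulate(np.float32(g) * grad)

    return Tensor._make(np.float32(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        seen = set()
        for mod in [self, *self.modules()]:
            for v in mod.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Parameter) and id(item) not in seen:
                            seen.add(id(item))
                            params.append(item)
        return params

    def train(self, flag: bool = True):
        self.training = flag
        for mod in self.modules():
            mod.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def buffers(self) -> list[tuple["Module", str]]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        out, seen = [], set()
        for mod in [self, *self.modules()]:
            for name in getattr(mod, "buffer_names", ()):
                key = (id(mod), name)
                if key not in seen:
                    seen.add(key)
                    out.append((mod, name))
        return out

    def state_dict(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.parameters()]
        arrays += [np.array(getattr(mod, name), copy=True)
                   for mod, name in self.buffers()]
        return arrays

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.parameters()
        buffers = self.buffers()
        if len(params) + len(buffers) != len(state):
            raise ValueError("state does not match model parameters/buffers")
        for p, s in zip(params, state):
            p.data = np.asarray(s, dtype=np.float32).reshape(p.data.shape)
        for (mod, name), s in zip(buffers, state[len(params):]):
            setattr(mod, name, np.asarray(s, dtype=np.float32))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 same-padding convolution layer with He initialisation."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, dilation: int = 1,
                 groups: int = 1, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = (c_in // groups) * k * k
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in // groups, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.dilation = dilation
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation,
                      groups=self.groups)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Owns a seeded generator so a
    fixed model seed gives a reproducible mask sequence."""

    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self._rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = (self._rng.random(x.data.shape) >= self.rate) / (1.0 - self.rate)
        return mul(x, Tensor(keep.astype(np.float32)))


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch statistics over (batch, H, W) with the
    standard backward; eval mode uses the running exponential averages.
    """

    buffer_names = ("running_mean", "running_var")

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        gshape = (1, -1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(gshape)) * ivar.reshape(gshape)
        out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)
        train_mode = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxh = g * gamma.data.reshape(gshape)
                if train_mode:
                    B, C, H, W = x.data.shape
                    n = B * H * W
                    s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    gx = (ivar.reshape(gshape) / n) * (n * gxh - s1 - xhat * s2)
                else:
                    gx = gxh * ivar.reshape(gshape)
                x._accumulate(gx.astype(np.float32))

        return Tensor._make(out, (x, gamma, beta), backward)


class Adam:
    """Adam optimiser (Kingma & Ba) over a parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
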