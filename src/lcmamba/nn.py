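"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network in this package is small enough that a compact
tape-based engine is sufficient: every :class:`Tensor` records the operation
that produced it, and :meth:`Tensor.backward` walks the tape in reverse
topological order.  All arithmetic is float32.  The module also provides the
layer classes the network is assembled from (convolution via im2col,
normalisation, bilinear resize), the Adam optimiser and a
reduce-on-plateau learning-rate schedule.

Layers implement ``profile(input_shape)`` returning ``(output_shape, macs)``
so that parameter/FLOP budgets can be computed by shape propagation without
running a numeric forward pass (1 multiply-accumulate counted as 1 FLOP).
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Tensor and tape
# ---------------------------------------------------------------------------

class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph bookkeeping --------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=DTYPE).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=DTYPE).copy()

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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operator sugar -----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other, dtype=DTYPE))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward(out)
    return out


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad, b.shape))
        return run

    return _make(data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad * a.data, b.shape))
        return run

    return _make(data, (a, b), bwd)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * p * a.data ** (p - 1.0))
        return run

    return _make(data, (a,), bwd)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def bwd(out):
        def run():
            if a.requires_grad:
                ga = out.grad @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ out.grad
                b._accumulate(_unbroadcast(gb, b.shape))
        return run

    return _make(data, (a, b), bwd)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * data)
        return run

    return _make(data, (a,), bwd)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad / a.data)
        return run

    return _make(data, (a,), bwd)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * mask)
        return run

    return _make(data, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = _sigmoid_np(a.data)

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * data * (1.0 - data))
        return run

    return _make(data, (a,), bwd)


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softplus(a) -> Tensor:
    a = as_tensor(a)
    data = np.logaddexp(0.0, a.data).astype(DTYPE)

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * _sigmoid_np(a.data))
        return run

    return _make(data, (a,), bwd)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp; gradient is passed only where the input is strictly inside."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * mask)
        return run

    return _make(data, (a,), bwd)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(out):
        def run():
            if not a.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape))
        return run

    return _make(data, (a,), bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod([a.shape[i] for i in np.atleast_1d(axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad.reshape(a.shape))
        return run

    return _make(data, (a,), bwd)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad.transpose(inv))
        return run

    return _make(data, (a,), bwd)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(out):
        def run():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * out.grad.ndim
                    idx[axis] = slice(lo, hi)
                    t._accumulate(out.grad[tuple(idx)])
        return run

    return _make(data, tensors, bwd)


def expm1_over_x(a) -> Tensor:
    """phi(z) = (exp(z) - 1) / z with the series limit phi(0) = 1.

    This is the scalar factor in the zero-order-hold discretisation of a
    diagonal state matrix; the derivative (exp(z)(z-1)+1)/z^2 -> 1/2 as z->0.
    """
    a = as_tensor(a)
    data = _phi_np(a.data)

    def bwd(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * _phi_prime_np(a.data))
        return run

    return _make(data, (a,), bwd)


def _phi_np(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=DTYPE)
    small = np.abs(z) < 1e-4
    safe = np.where(small, 1.0, z)
    out = np.where(small, 1.0 + z / 2.0 + z * z / 6.0, np.expm1(safe) / safe)
    return out.astype(DTYPE)


def _phi_prime_np(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=DTYPE)
    small = np.abs(z) < 1e-3
    safe = np.where(small, 1.0, z)
    out = np.where(
        small,
        0.5 + z / 3.0 + z * z / 8.0,
        (np.exp(safe) * (safe - 1.0) + 1.0) / (safe * safe),
    )
    return out.astype(DTYPE)


# ---------------------------------------------------------------------------
# Structured primitives: scan, convolution, resize
# ---------------------------------------------------------------------------

def linear_scan(a: Tensor, u: Tensor) -> Tensor:
    """Run h_t = a_t * h_{t-1} + u_t along axis -3 (the sequence axis).

    ``a`` and ``u`` have shape (..., L, E, N); the result stacks every h_t.
    The backward pass replays the recurrence in reverse:
    g_t = dh_t + a_{t+1} * g_{t+1}, da_t = g_t * h_{t-1}, du_t = g_t.
    """
    av, uv = a.data, u.data
    L = av.shape[-3]
    hs = np.empty_like(uv)
    h = np.zeros(av.shape[:-3] + av.shape[-2:], dtype=DTYPE)
    for t in range(L):
        h = av[..., t, :, :] * h + uv[..., t, :, :]
        hs[..., t, :, :] = h

    def bwd(out):
        def run():
            g = np.zeros(av.shape[:-3] + av.shape[-2:], dtype=DTYPE)
            da = np.empty_like(av) if a.requires_grad else None
            du = np.empty_like(uv) if u.requires_grad else None
            for t in range(L - 1, -1, -1):
                g = g + out.grad[..., t, :, :]
                if da is not None:
                    h_prev = hs[..., t - 1, :, :] if t > 0 else 0.0
                    da[..., t, :, :] = g * h_prev
                if du is not None:
                    du[..., t, :, :] = g
                g = g * av[..., t, :, :]
            if da is not None:
                a._accumulate(da)
            if du is not None:
                u._accumulate(du)
        return run

    return _make(hs, (a, u), bwd)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    OH = (H + 2 * pad - k) // stride + 1
    OW = (W + 2 * pad - k) // stride + 1
    cols = np.empty((B, C, k, k, OH, OW), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride]
    return cols.reshape(B, C * k * k, OH * OW), OH, OW


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    B, C, H, W = x_shape
    OH = (H + 2 * pad - k) // stride + 1
    OW = (W + 2 * pad - k) // stride + 1
    cols = cols.reshape(B, C, k, k, OH, OW)
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride] += cols[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, square kernel."""
    Cout, Cin, k, _ = w.shape
    cols, OH, OW = _im2col(x.data, k, stride, pad)
    B = x.shape[0]
    wmat = w.data.reshape(Cout, Cin * k * k)
    out_data = np.einsum("oc,bcp->bop", wmat, cols, optimize=True)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1)
    out_data = out_data.reshape(B, Cout, OH, OW)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(out):
        def run():
            go = out.grad.reshape(B, Cout, OH * OW)
            if b is not None and b.requires_grad:
                b._accumulate(go.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.einsum("bop,bcp->oc", go, cols, optimize=True)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                gcols = np.einsum("oc,bop->bcp", wmat, go, optimize=True)
                x._accumulate(_col2im(gcols, x.shape, k, stride, pad))
        return run

    return _make(out_data, parents, bwd)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    M = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    for o in range(n_out):
        pos = (o + 0.5) * scale - 0.5
        lo = int(math.floor(pos))
        frac = pos - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        M[o, lo_c] += 1.0 - frac
        M[o, hi_c] += frac
    return M


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = _interp_matrix(n_out, n_in)
    return _INTERP_CACHE[key]


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Separable bilinear resize of an NCHW tensor."""
    B, C, H, W = x.shape
    OH, OW = out_hw
    Mh, Mw = _interp(OH, H), _interp(OW, W)
    data = np.einsum("oh,bchw,pw->bcop", Mh, x.data, Mw, optimize=True)

    def bwd(out):
        def run():
            if x.requires_grad:
                g = np.einsum("oh,bcop,pw->bchw", Mh, out.grad, Mw, optimize=True)
                x._accumulate(g)
        return run

    return _make(data, (x,), bwd)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter registry, train/eval mode, shape profiling."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, t) for n, t in self._params.items()]
        for cname, child in self._children.values() if False else self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: t.data.copy() for n, t in self.named_parameters()}
        for name, buf in getattr(self, "_buffers", {}).items():
            out[name] = buf.copy()
        for cname, child in self._children.items():
            for k, v in child.state_dict().items():
                out[f"{cname}.{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> list[str]:
        """Load matching names; returns the list of names that did not match."""
        missing = []
        for name, tensor in self.named_parameters():
            if name in state and state[name].shape == tensor.data.shape:
                tensor.data = np.asarray(state[name], dtype=DTYPE).copy()
            else:
                missing.append(name)
        # buffers (running statistics) are stored flat alongside parameters
        stack: list[tuple[str, Module]] = [("", self)]
        while stack:
            prefix, mod = stack.pop()
            for bname, buf in getattr(mod, "_buffers", {}).items():
                full = prefix + bname
                if full in state and state[full].shape == buf.shape:
                    getattr(mod, "_buffers")[bname] = np.asarray(state[full], dtype=DTYPE).copy()
            for cname, child in mod._children.items():
                stack.append((prefix + cname + ".", child))
        if strict and missing:
            raise KeyError(f"missing/mismatched parameters: {missing}")
        return missing

    # profiling ------------------------------------------------------------

    def profile(self, input_shape):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(shape, fan_in, rng) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1, pad: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k // 2) if pad is None else pad
        self.add_param("weight", _kaiming((c_out, c_in, k, k), c_in * k * k, rng))
        self.bias = None
        if bias:
            self.add_param("bias", np.zeros(c_out, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)

    def profile(self, input_shape):
        B, C, H, W = input_shape
        OH = (H + 2 * self.pad - self.k) // self.stride + 1
        OW = (W + 2 * self.pad - self.k) // self.stride + 1
        macs = B * OH * OW * self.c_out * self.c_in * self.k * self.k
        return (B, self.c_out, OH, OW), macs


class Linear(Module):
    """Applied over the last axis."""

    def __init__(self, d_in: int, d_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.d_in, self.d_out = d_in, d_out
        self.add_param("weight", _kaiming((d_in, d_out), d_in, rng))
        self.bias = None
        if bias:
            self.add_param("bias", np.zeros(d_out, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = add(y, self.bias)
        return y

    def macs(self, n_positions: int) -> int:
        return n_positions * self.d_in * self.d_out


class LayerNorm(Module):
    """Normalisation over the channel axis (axis 1 of NCHW or last axis)."""

    def __init__(self, dim: int, axis: int = 1, eps: float = 1e-5):
        super().__init__()
        self.axis, self.eps, self.dim = axis, eps, dim
        self.add_param("gamma", np.ones(dim, dtype=DTYPE))
        self.add_param("beta", np.zeros(dim, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        ax = self.axis if self.axis >= 0 else x.ndim + self.axis
        mu = tmean(x, axis=ax, keepdims=True)
        xc = x - mu
        var = tmean(mul(xc, xc), axis=ax, keepdims=True)
        inv = power(add(var, self.eps), -0.5)
        shape = [1] * x.ndim
        shape[ax] = self.dim
        g = reshape(self.gamma, shape)
        b = reshape(self.beta, shape)
        return add(mul(mul(xc, inv), g), b)


class BatchNorm2d(Module):
    """Batch normalisation over (B, H, W) with running statistics for eval."""

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.dim, self.eps, self.momentum = dim, eps, momentum
        self.add_param("gamma", np.ones(dim, dtype=DTYPE))
        self.add_param("beta", np.zeros(dim, dtype=DTYPE))
        self._buffers = {
            "running_mean": np.zeros(dim, dtype=DTYPE),
            "running_var": np.ones(dim, dtype=DTYPE),
        }

    def __call__(self, x: Tensor) -> Tensor:
        g = reshape(self.gamma, (1, self.dim, 1, 1))
        b = reshape(self.beta, (1, self.dim, 1, 1))
        if self.training:
            mu = tmean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = tmean(mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.ravel()
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.ravel()
            inv = power(add(var, self.eps), -0.5)
            return add(mul(mul(xc, inv), g), b)
        mu = self._buffers["running_mean"].reshape(1, self.dim, 1, 1)
        sd = np.sqrt(self._buffers["running_var"] + self.eps).reshape(1, self.dim, 1, 1)
        return add(mul(mul(add(x, -mu), 1.0 / sd), g), b)


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Multiply lr by `factor` after `patience` epochs without improvement."""

    def __init__(self, optimizer: Adam, mode: str = "max", factor: float = 0.5,
                 patience: int = 5, min_lr: float = 1e-7):
        assert mode in ("min", "max")
        self.opt, self.mode = optimizer, mode
        self.factor, self.patience, self.min_lr = factor, patience, min_lr
        self.best: float | None = None
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Returns True when the learning rate was reduced this epoch."""
        improved = (
            self.best is None
            or (self.mode == "max" and metric > self.best)
            or (self.mode == "min" and metric < self.best)
        )
        if improved:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.bad_epochs = 0
            return True
        return False
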