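"""Minimal NumPy compute core: reverse-mode autodiff, layers, SGD.

Everything downstream (encoder, decoder, attention, graph blocks, the
training loop) is built on the :class:`Tensor` type defined here.  The
engine is deliberately small: dense arrays only, a flat tape built by
operator closures, and a topological backward sweep.  Gradients are checked
against central finite differences in the test suite.

Conventions
-----------
* default dtype is float32; gradient checks run the same ops in float64
* images are ``(B, C, H, W)``; token/node matrices are ``(B, N, C)``
* a single module-level RNG (see :func:`seed_all`) drives weight
  initialisation and stochastic layers so a run is reproducible from one
  integer seed
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor", "Parameter", "tensor", "no_grad", "seed_all", "get_rng",
    "cat", "relu", "gelu", "sigmoid", "softmax", "erf", "exp", "log",
    "sqrt", "maximum", "gather_nodes", "conv2d", "bilinear_resize",
    "Module", "ModuleList", "Linear", "Conv2d", "BatchNorm2d",
    "BatchNormNodes", "LayerNorm", "DropPath", "Identity", "SGD",
    "trunc_normal_",
]

_grad_enabled = True
_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the module RNG used for init, dropout and drop-path."""
    global _rng
    _rng = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _rng


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Dense array with an optional autograd tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        if not isinstance(data, np.ndarray):
            if isinstance(data, np.floating):      # keep reduction dtype
                data = np.asarray(data)
            elif isinstance(data, (int, float)):   # weak scalar: don't upcast f32
                data = np.asarray(data, dtype=np.float32)
            else:
                data = np.asarray(data)
                if not np.issubdtype(data.dtype, np.floating):
                    data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---- basic introspection -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- autograd -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free the tape as we go
            if node is not self:
                node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                              other.data.shape))
            out._backward = back
        return out

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = tensor(other)
        out = Tensor(np.matmul(self.data, other.data),
                     self.requires_grad or other.requires_grad, (self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accum(_unbroadcast(ga, self.data.shape))
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accum(_unbroadcast(gb, other.data.shape))
            out._backward = back
        return out

    # ---- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if out.requires_grad:
            parts = idx if isinstance(idx, tuple) else (idx,)
            basic = all(isinstance(p, (int, slice, type(None), type(Ellipsis)))
                        for p in parts)

            def back(g):
                gx = np.zeros_like(self.data)
                if basic:           # basic indexing selects distinct elements
                    gx[idx] += g
                else:
                    np.add.at(gx, idx, g)
                self._accum(gx)
            out._backward = back
        return out

    # ---- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:
            def back(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        m = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(m, self.requires_grad, (self,))
        if out.requires_grad:
            def back(g):
                mk = m if keepdims or axis is None else np.expand_dims(m, axis)
                gk = g if keepdims or axis is None else np.expand_dims(g, axis)
                mask = (self.data == mk)
                cnt = mask.sum(axis=axis, keepdims=True) if axis is not None \
                    else mask.sum()
                self._accum(mask * gk / cnt)
            out._backward = back
        return out


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# --------------------------------------------------------------------------
# elementwise / structural functions
# --------------------------------------------------------------------------

def _unary(x: Tensor, y: np.ndarray, dfun) -> Tensor:
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * dfun())
    return out


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    return _unary(x, y, lambda: y)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log(x.data), lambda: 1.0 / x.data)


def sqrt(x: Tensor) -> Tensor:
    y = np.sqrt(x.data)
    return _unary(x, y, lambda: 0.5 / y)


def erf(x: Tensor) -> Tensor:
    y = _sp.erf(x.data)
    c = 2.0 / math.sqrt(math.pi)
    return _unary(x, y, lambda: c * np.exp(-x.data ** 2))


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)
    return _unary(x, y, lambda: (x.data > 0).astype(x.data.dtype))


def sigmoid(x: Tensor) -> Tensor:
    y = _sp.expit(x.data)
    return _unary(x, y, lambda: y * (1 - y))


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-form) GELU."""
    phi = 0.5 * (1.0 + _sp.erf(x.data / _SQRT2))
    y = x.data * phi
    return _unary(x, y, lambda: phi + x.data * _INV_SQRT_2PI *
                  np.exp(-0.5 * x.data ** 2))


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = tensor(a), tensor(b)
    y = np.maximum(a.data, b.data)
    out = Tensor(y, a.requires_grad or b.requires_grad, (a, b))
    if out.requires_grad:
        def back(g):
            ma = (a.data >= b.data)
            if a.requires_grad:
                a._accum(_unbroadcast(g * ma, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~ma), b.data.shape))
        out._backward = back
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-subtraction)."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        def back(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum((g - dot) * y)
        out._backward = back
    return out


def cat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offs = np.cumsum([0] + sizes)

        def back(g):
            for t, a, b in zip(tensors, offs[:-1], offs[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])
        out._backward = back
    return out


def gather_nodes(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather neighbour features: ``x`` (B,N,D), ``idx`` (B,N,K) -> (B,N,K,D)."""
    B = x.data.shape[0]
    bi = np.arange(B)[:, None, None]
    y = x.data[bi, idx]
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        def back(g):
            gx = np.zeros_like(x.data)
            np.add.at(gx, (bi, idx), g)
            x._accum(gx)
        out._backward = back
    return out


# --------------------------------------------------------------------------
# conv2d and bilinear resize primitives
# --------------------------------------------------------------------------

_col2im_cache: dict = {}


def _col2im_matrix(Hp, Wp, Ho, Wo, kh, kw, s, dtype):
    """Cached sparse scatter matrix mapping flattened window entries
    (Ho*Wo*kh*kw) back onto the padded image plane (Hp*Wp)."""
    from scipy import sparse
    key = (Hp, Wp, Ho, Wo, kh, kw, s, np.dtype(dtype).str)
    if key not in _col2im_cache:
        i = np.arange(Ho)[:, None, None, None] * s + np.arange(kh)[None, None, :, None]
        j = np.arange(Wo)[None, :, None, None] * s + np.arange(kw)[None, None, None, :]
        flat = (i * Wp + j).reshape(-1)
        L = flat.size
        M = sparse.csr_matrix((np.ones(L, dtype=dtype),
                               (np.arange(L), flat)),
                              shape=(L, Hp * Wp))
        _col2im_cache[key] = M
    return _col2im_cache[key]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation; supports groups=1 and depthwise (groups=C)."""
    B, C, H, W = x.data.shape
    Co, Cig, kh, kw = w.data.shape
    s, p = stride, padding
    if kh == 1 and kw == 1 and groups == 1 and s == 1 and p == 0:
        # fast path: 1x1 conv is a channel matmul
        xm = x.reshape(B, C, H * W).transpose(0, 2, 1)          # B,HW,C
        wm = w.reshape(Co, C).transpose(1, 0)                   # C,Co
        y = xm @ wm                                             # B,HW,Co
        if b is not None:
            y = y + b.reshape(1, 1, Co)
        return y.transpose(0, 2, 1).reshape(B, Co, H, W)

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho, Wo = (Hp - kh) // s + 1, (Wp - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]                                   # B,C,Ho,Wo,kh,kw

    if groups == 1:
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
        Wmat = w.data.reshape(Co, C * kh * kw)
        y = cols @ Wmat.T
        ydata = y.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)
    elif groups == C and Cig == 1:
        ydata = np.einsum("bchwij,cij->bchw", win, w.data[:, 0], optimize=True)
    else:  # pragma: no cover - not used by the architecture
        raise NotImplementedError("only groups=1 or depthwise convs supported")

    if b is not None:
        ydata = ydata + b.data.reshape(1, Co, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(ydata), req, parents)
    if out.requires_grad:
        def back(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if groups == 1:
                gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, Co)
                if w.requires_grad:
                    w._accum((gmat.T @ cols).reshape(w.data.shape))
                if x.requires_grad:
                    gcols = gmat @ Wmat                          # BHoWo, C*kh*kw
                    gcols = gcols.reshape(B, Ho * Wo, C, kh * kw)
                    gcols = gcols.transpose(0, 2, 1, 3).reshape(B * C, -1)
                    M = _col2im_matrix(Hp, Wp, Ho, Wo, kh, kw, s, g.dtype)
                    gxp = (gcols @ M).reshape(B, C, Hp, Wp)
                    x._accum(gxp[:, :, p:Hp - p, p:Wp - p] if p else gxp)
            else:  # depthwise
                if w.requires_grad:
                    gw = np.einsum("bchwij,bchw->cij", win, g, optimize=True)
                    w._accum(gw[:, None, :, :])
                if x.requires_grad:
                    gwin = g[..., None, None] * w.data[:, 0][None, :, None, None]
                    gwin = gwin.reshape(B * C, Ho * Wo * kh * kw)
                    M = _col2im_matrix(Hp, Wp, Ho, Wo, kh, kw, s, g.dtype)
                    gxp = (gwin @ M).reshape(B, C, Hp, Wp)
                    x._accum(gxp[:, :, p:Hp - p, p:Wp - p] if p else gxp)
        out._backward = back
    return out


_resize_cache: dict = {}


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centres)."""
    key = (n_in, n_out, np.dtype(dtype).str)
    if key not in _resize_cache:
        M = np.zeros((n_out, n_in), dtype=dtype)
        if n_in == 1:
            M[:, 0] = 1.0
        else:
            scale = n_in / n_out
            src = (np.arange(n_out) + 0.5) * scale - 0.5
            src = np.clip(src, 0, n_in - 1)
            i0 = np.floor(src).astype(int)
            i1 = np.minimum(i0 + 1, n_in - 1)
            f = src - i0
            M[np.arange(n_out), i0] += 1 - f
            M[np.arange(n_out), i1] += f
        _resize_cache[key] = M
    return _resize_cache[key]


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of a (B,C,H,W) map (half-pixel convention)."""
    B, C, H, W = x.data.shape
    R = _resize_matrix(H, out_h, x.data.dtype)
    Cm = _resize_matrix(W, out_w, x.data.dtype)
    y = np.einsum("oh,bchw,pw->bcop", R, x.data, Cm, optimize=True)
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(
            np.einsum("oh,bcop,pw->bchw", R, g, Cm, optimize=True))
    return out


# --------------------------------------------------------------------------
# modules
# --------------------------------------------------------------------------

def trunc_normal_(arr: np.ndarray, std: float = 0.02) -> np.ndarray:
    """Fill with N(0, std) truncated at +/- 2 std (resampling)."""
    out = _rng.normal(0.0, std, size=arr.shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = _rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    arr[...] = out.astype(arr.dtype)
    return arr


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k in self._buffers:
            yield prefix + k, getattr(self, k)
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data for name, p in self.named_parameters()}
        d.update({name: b for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, arr in d.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{params[name].data.shape} vs {arr.shape}")
                params[name].data = arr.astype(params[name].data.dtype)
        # buffers (running stats) live on their owning module
        bufs = {}
        for m in self.modules():
            for k in m._buffers:
                bufs.setdefault(k, [])
        for name, arr in d.items():
            head = name.rsplit(".", 1)[-1]
            mod = self._resolve_buffer_owner(name)
            if mod is not None:
                mod.register_buffer(head, arr.copy())

    def _resolve_buffer_owner(self, name: str):
        parts = name.split(".")
        m = self
        for p in parts[:-1]:
            if p in m._modules:
                m = m._modules[p]
            else:
                return None
        return m if parts[-1] in m._buffers else None

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class ModuleList(Module):
    def __init__(self, mods: Iterable[Module] = ()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        w = np.empty((in_features, out_features), dtype=np.float32)
        self.weight = Parameter(trunc_normal_(w, 0.02))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_out = kernel * kernel * out_ch // groups
        std = math.sqrt(2.0 / fan_out)
        w = _rng.normal(0.0, std,
                        size=(out_ch, in_ch // groups, kernel, kernel))
        self.weight = Parameter(w.astype(np.float32))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)


class _BatchNormBase(Module):
    """Shared batch-norm logic; subclasses fix the reduction axes."""

    axes: tuple

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))

    def _norm(self, x: Tensor, shape: tuple) -> Tensor:
        if self.training:
            mu = x.mean(axis=self.axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=self.axes, keepdims=True)
            n = x.data.size / mu.data.size
            with np.errstate(all="ignore"):
                rm = self.running_mean
                rv = self.running_var
                rm *= (1 - self.momentum)
                rm += self.momentum * mu.data.reshape(-1)
                unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
                rv *= (1 - self.momentum)
                rv += self.momentum * unbiased
            xh = (x - mu) / sqrt(var + self.eps)
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xh = (x - Tensor(mu)) / Tensor(sd)
        return xh * self.weight.reshape(shape) + self.bias.reshape(shape)


class BatchNorm2d(_BatchNormBase):
    """Per-channel normalisation of (B, C, H, W) maps."""
    axes = (0, 2, 3)

    def forward(self, x: Tensor) -> Tensor:
        C = x.data.shape[1]
        return self._norm(x, (1, C, 1, 1))


class BatchNormNodes(_BatchNormBase):
    """Per-channel normalisation of flattened node features (B, N, C)."""
    axes = (0, 1)

    def forward(self, x: Tensor) -> Tensor:
        C = x.data.shape[2]
        return self._norm(x, (1, 1, C))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / sqrt(var + self.eps) * self.weight + self.bias


class DropPath(Module):
    """Per-sample stochastic depth; identity in evaluation mode."""

    def __init__(self, p: float = 0.0):
        super().__init__()
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        B = x.data.shape[0]
        keep = (_rng.random(B) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        keep = keep.reshape((B,) + (1,) * (x.data.ndim - 1))
        return x * Tensor(keep)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class SGD:
    """Stochastic gradient descent with momentum and decoupled-from-nothing
    (classic, loss-coupled) weight decay, matching the usual segmentation
    training recipe."""

    def __init__(self, params: Iterable[Parameter], momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
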